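"""Crude and directly standardized prevalence with gamma confidence limits.

Prevalence is carried internally as a proportion and rendered as a percent
at the reporting boundary.  Crude intervals are exact Poisson (chi-square)
limits; directly standardized rates get gamma (Fay-Feuer) limits built from
chi-square quantiles, the canonical interval for weighted sums of Poisson
counts with small numerators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: default stratification used for direct standardization
STRATUM_COLS = ["age_band", "sex"]


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A point prevalence on the percent scale with a 95% interval."""

    point: float
    ci_low: float
    ci_high: float
    method: str  # "crude" or "direct"
    n_cases: float
    n_pop: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point + 1e-9 and self.point <= self.ci_high + 1e-9):
            raise ValueError("interval must contain the point estimate")

    @property
    def width(self) -> float:
        """Interval width in percentage points."""
        return self.ci_high - self.ci_low


def format_pct(x: float, ndigits: int = 2) -> float:
    """Round a percent for reporting: 2 d.p., ties to even."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


def crude_prevalence(cases: float, population: float, level: float = 0.95) -> PrevalenceEstimate:
    """Crude prevalence with exact Poisson (chi-square) confidence limits.

    The limits are ``chi2.ppf(alpha/2, 2c) / 2`` and
    ``chi2.ppf(1 - alpha/2, 2c + 2) / 2`` scaled by the denominator; the
    lower limit is 0 when there are no cases.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if not 0 <= cases <= population:
        raise ValueError("cases must lie in [0, population]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if cases == 0 else stats.chi2.ppf(alpha / 2, 2 * cases) / 2 / population
    high = stats.chi2.ppf(1 - alpha / 2, 2 * cases + 2) / 2 / population
    return PrevalenceEstimate(
        point=100 * cases / population,
        ci_low=100 * low,
        ci_high=100 * min(high, 1.0),
        method="crude",
        n_cases=cases,
        n_pop=population,
    )


def _align(strata: pd.DataFrame, std: pd.DataFrame, stratum_cols: list[str] | None):
    """Merge stratum counts with standard weights; validate coverage."""
    cols = stratum_cols or [c for c in std.columns if c != "weight"]
    if (std["weight"] <= 0).any():
        raise ValueError("standard weights must be positive")
    if std.duplicated(cols).any():
        raise ValueError("standard population strata must be unique")
    merged = strata.merge(std, on=cols, how="left", validate="many_to_one")
    if merged["weight"].isna().any():
        missing = merged.loc[merged["weight"].isna(), cols].drop_duplicates()
        raise ValueError(f"data strata without a standard weight: {missing.to_dict('records')}")
    bad = (merged["population"] == 0) & (merged["cases"] > 0)
    if bad.any():
        raise ValueError("stratum with zero population but positive cases")
    empty = merged["population"] == 0
    if empty.any():
        logger.warning("dropping %d empty strata (zero population, zero cases)", int(empty.sum()))
        merged = merged[~empty]
    return merged


def direct_standardize(
    strata: pd.DataFrame,
    std: pd.DataFrame,
    level: float = 0.95,
    stratum_cols: list[str] | None = None,
) -> PrevalenceEstimate:
    """Directly standardized prevalence: ``sum(w_i r_i) / sum(w_i)``.

    Parameters
    ----------
    strata
        One row per stratum with ``cases`` and ``population`` columns plus
        the stratum key columns (default ``age_band``, ``sex``).
    std
        Standard population with the same key columns and a ``weight``
        column (person counts).
    """
    merged = _align(strata, std, stratum_cols)
    w = merged["weight"].to_numpy(float)
    r = merged["cases"].to_numpy(float) / merged["population"].to_numpy(float)
    point = float(np.sum(w * r) / np.sum(w))
    low, high = gamma_ci(strata, std, level=level, stratum_cols=stratum_cols)
    return PrevalenceEstimate(
        point=100 * point,
        ci_low=low,
        ci_high=high,
        method="direct",
        n_cases=float(merged["cases"].sum()),
        n_pop=float(merged["population"].sum()),
    )


def gamma_ci(
    strata: pd.DataFrame,
    std: pd.DataFrame,
    level: float = 0.95,
    stratum_cols: list[str] | None = None,
) -> tuple[float, float]:
    """Gamma (Fay-Feuer) limits for a directly standardized rate, in percent.

    With normalized per-capita weights ``w_i = (W_i / sum W) / n_i`` the
    standardized rate is ``y = sum w_i x_i`` with variance estimate
    ``v = sum w_i^2 x_i``.  The limits are::

        low  = v / (2 y) * chi2.ppf(alpha/2, 2 y^2 / v)
        high = (v + wm^2) / (2 (y + wm)) * chi2.ppf(1 - alpha/2,
                                                    2 (y + wm)^2 / (v + wm^2))

    where ``wm`` is the largest per-capita weight.  With zero total cases
    the lower limit is 0 and the upper limit follows from ``wm`` alone.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    merged = _align(strata, std, stratum_cols)
    alpha = 1.0 - level
    w = merged["weight"].to_numpy(float)
    w = w / w.sum() / merged["population"].to_numpy(float)
    x = merged["cases"].to_numpy(float)
    y = float(np.sum(w * x))
    v = float(np.sum(w**2 * x))
    wm = float(np.max(w))
    if y > 0:
        low = v / (2 * y) * stats.chi2.ppf(alpha / 2, 2 * y**2 / v)
    else:
        low = 0.0
    high = (v + wm**2) / (2 * (y + wm)) * stats.chi2.ppf(
        1 - alpha / 2, 2 * (y + wm) ** 2 / (v + wm**2)
    )
    return 100 * low, 100 * min(high, 1.0)


def stratum_counts(
    students: pd.DataFrame,
    case_col: str = "asd_flag",
    stratum_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse a registry table to per-stratum (cases, population) counts."""
    cols = stratum_cols or STRATUM_COLS
    g = students.groupby(cols, observed=True)[case_col]
    out = g.agg(cases="sum", population="size").reset_index()
    return out


def prevalence_table(
    students: pd.DataFrame,
    groupings: list[list[str]],
    std: pd.DataFrame,
    case_col: str = "asd_flag",
    level: float = 0.95,
) -> pd.DataFrame:
    """Crude and directly standardized prevalence per group.

    ``groupings`` is a list of column sets; the empty set yields a single
    overall row.  Output percentages are rounded at 2 d.p. (ties to even).
    """
    rows = []
    for cols in groupings:
        if cols:
            missing = set(cols) - set(students.columns)
            if missing:
                raise KeyError(f"grouping columns not in table: {sorted(missing)}")
            groups = students.groupby(list(cols), observed=True)
        else:
            groups = [((), students)]
        for key, df in groups:
            key = key if isinstance(key, tuple) else (key,)
            sc = stratum_counts(df, case_col=case_col)
            n_cases, n_pop = int(sc["cases"].sum()), int(sc["population"].sum())
            if n_pop == 0:
                rows.append(
                    {"grouping": "+".join(cols) or "overall",
                     "level": "/".join(map(str, key)) or "all",
                     "n_cases": 0, "n_pop": 0}
                )
                continue
            crude = crude_prevalence(n_cases, n_pop, level=level)
            direct = direct_standardize(sc, std, level=level)
            rows.append(
                {
                    "grouping": "+".join(cols) or "overall",
                    "level": "/".join(map(str, key)) or "all",
                    "n_cases": n_cases,
                    "n_pop": n_pop,
                    "crude_pct": format_pct(crude.point),
                    "crude_low": format_pct(crude.ci_low),
                    "crude_high": format_pct(crude.ci_high),
                    "direct_pct": format_pct(direct.point),
                    "direct_low": format_pct(direct.ci_low),
                    "direct_high": format_pct(direct.ci_high),
                }
            )
    return pd.DataFrame(rows)


def feature_counts(students: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Count/percentage report per variable (registry descriptive table)."""
    rows = []
    n = len(students)
    for col in columns:
        vc = students[col].value_counts(dropna=False)
        for value, count in vc.items():
            rows.append(
                {"variable": col, "value": value, "count": int(count),
                 "pct": format_pct(100 * count / n)}
            )
    return pd.DataFrame(rows)
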