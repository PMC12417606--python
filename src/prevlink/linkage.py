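"""Fellegi-Sunter probabilistic linkage of clinical patients to registry students.

Candidate pairs are blocked on sex and date of birth, scored per field with
similarity comparators, combined into a composite log2 likelihood-ratio
weight, and resolved into a one-to-one match set by greedy descent on
weight.  Field agreement probabilities m (given a true match) and u (given
a non-match) are user configuration; fractional similarities interpolate
linearly between the full-agreement and full-disagreement weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from datetime import date

import numpy as np
import pandas as pd

from .datasets import FEE_BANDS

logger = logging.getLogger(__name__)

_FEE_RANK = {b: i for i, b in enumerate(FEE_BANDS[:-1])}  # "Missing" has no rank
_MAX_RANK = len(FEE_BANDS) - 2  # 5 steps across 6 ranked bands


@dataclass(frozen=True)
class FieldSpec:
    """One comparison field with its comparator and m/u probabilities."""

    name: str
    comparator: str  # "exact" | "date_tolerant" | "ordinal"
    m: float
    u: float
    student_col: str = ""
    patient_col: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.u < self.m < 1:
            raise ValueError(f"field {self.name!r} requires 0 < u < m < 1")
        if self.comparator not in {"exact", "date_tolerant", "ordinal"}:
            raise ValueError(f"unknown comparator {self.comparator!r}")

    @property
    def agree_weight(self) -> float:
        return math.log2(self.m / self.u)

    @property
    def disagree_weight(self) -> float:
        return math.log2((1 - self.m) / (1 - self.u))


def default_field_specs(n_communes: int = 21) -> list[FieldSpec]:
    """Conventional m/u defaults for the four linkage fields."""
    return [
        FieldSpec("dob", "date_tolerant", m=0.95, u=0.001, student_col="dob", patient_col="dob"),
        FieldSpec("sex", "exact", m=0.98, u=0.5, student_col="sex", patient_col="sex"),
        FieldSpec("commune", "exact", m=0.90, u=1.0 / n_communes,
                  student_col="commune", patient_col="communes"),
        FieldSpec("ses_proxy", "ordinal", m=0.80, u=0.20,
                  student_col="school_fee_band", patient_col="fee_band_proxy"),
    ]


@dataclass
class LinkageConfig:
    field_specs: list[FieldSpec] = dc_field(default_factory=default_field_specs)
    threshold: float = 12.0  # bits
    grey_low: float = 8.0  # lower edge of the exported grey zone
    blocking: str = "exact"  # "exact" (sex + full dob) or "year_month"


@dataclass
class MatchSet:
    """Bijective match pairs plus unmatched residuals on either side."""

    pairs: pd.DataFrame  # student_id, patient_id, weight (+ per-field similarities)
    unmatched_students: list[str]
    unmatched_patients: list[str]
    threshold: float


# -- comparators ---------------------------------------------------------------

def _parse_date(v) -> date | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v)[:10])


def field_similarity(a, b, spec: FieldSpec) -> float:
    """Similarity in [0, 1] for one field value pair.

    exact -> {0, 1}; date_tolerant -> 1 on equality, 0.8 on a day/month
    transposition, 0 otherwise; ordinal -> 1 - |rank difference| / max rank.
    Missing values score 0 (logged by the caller).
    """
    if spec.comparator == "date_tolerant":
        da, db = _parse_date(a), _parse_date(b)
        if da is None or db is None:
            return 0.0
        if da == db:
            return 1.0
        if da.year == db.year and da.day == db.month and da.month == db.day:
            return 0.8
        return 0.0
    if spec.comparator == "ordinal":
        ra, rb = _FEE_RANK.get(a), _FEE_RANK.get(b)
        if ra is None or rb is None:
            return 0.0
        return 1.0 - abs(ra - rb) / _MAX_RANK
    # exact; the patient side may carry a set of values (multi-commune)
    if isinstance(b, (set, frozenset, tuple, list)):
        return max((field_similarity(a, bb, spec) for bb in b), default=0.0)
    if a is None or b is None or (isinstance(a, float) and math.isnan(a)) or (
        isinstance(b, float) and math.isnan(b)
    ):
        return 0.0
    return 1.0 if a == b else 0.0


def pair_weight(similarities: dict[str, float], specs: list[FieldSpec]) -> float:
    """Composite log2 weight: sum of s*log2(m/u) + (1-s)*log2((1-m)/(1-u))."""
    total = 0.0
    for spec in specs:
        s = similarities[spec.name]
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"similarity for {spec.name!r} outside [0, 1]")
        total += s * spec.agree_weight + (1 - s) * spec.disagree_weight
    return total


# -- pipeline steps ------------------------------------------------------------

def dedupe_patients(patients: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per patient_id; all recorded communes kept as a tuple.

    Patients recorded under several communes collapse to a single candidate
    whose best commune similarity is used during scoring.  Rows whose sex or
    dob conflict within a patient_id are reported (first value kept).
    """
    conflicts = []
    for pid, grp in patients.groupby("patient_id", sort=False):
        if grp["sex"].nunique() > 1 or grp["dob"].nunique() > 1:
            conflicts.append({"patient_id": pid, "reason": "conflicting sex/dob across rows"})
    agg = {c: "first" for c in patients.columns if c not in ("patient_id", "commune")}
    unique = patients.groupby("patient_id", as_index=False, sort=True).agg(
        {**agg, "commune": lambda s: tuple(sorted(set(s.dropna())))}
    )
    unique = unique.rename(columns={"commune": "communes"})
    return unique, pd.DataFrame(conflicts, columns=["patient_id", "reason"])


def block(students: pd.DataFrame, patients: pd.DataFrame, mode: str = "exact") -> pd.DataFrame:
    """Candidate pairs agreeing on sex and (full or year+month) date of birth."""
    s = students.copy()
    p = patients.copy()
    if mode == "exact":
        keys = ["sex", "dob"]
    elif mode == "year_month":
        for df in (s, p):
            df["_ym"] = df["dob"].astype(str).str[:7]
        keys = ["sex", "_ym"]
    else:
        raise ValueError(f"unknown blocking mode {mode!r}")
    cand = s.merge(p, on=keys, suffixes=("_s", "_p"))
    logger.info("blocking (%s): %d candidate pairs", mode, len(cand))
    return cand


def score_pairs(candidates: pd.DataFrame, specs: list[FieldSpec]) -> pd.DataFrame:
    """Per-field similarities and composite weight for each candidate pair."""
    out = candidates[["student_id", "patient_id"]].copy()
    n_missing = 0
    sims = {}
    for spec in specs:
        scol, pcol = spec.student_col, spec.patient_col
        sa = candidates[scol] if scol in candidates else candidates[scol + "_s"]
        pa = candidates[pcol] if pcol in candidates else candidates[pcol + "_p"]
        vals = np.array(
            [field_similarity(a, b, spec) for a, b in zip(sa, pa)], dtype=float
        )
        n_missing += int(np.sum(pd.isna(sa.to_numpy(object))))
        sims[spec.name] = vals
        out[f"sim_{spec.name}"] = vals
    if n_missing:
        logger.info("scoring: %d missing field values scored 0", n_missing)
    weight = np.zeros(len(candidates))
    for spec in specs:
        s = sims[spec.name]
        weight += s * spec.agree_weight + (1 - s) * spec.disagree_weight
    out["weight"] = weight
    return out


def assign_bijective(
    scored: pd.DataFrame,
    threshold: float,
    all_students: list[str] | None = None,
    all_patients: list[str] | None = None,
) -> MatchSet:
    """Greedy one-to-one assignment by descending weight.

    A pair is accepted iff its weight is at or above the threshold and
    neither side is already taken; ties are broken by (student_id,
    patient_id) lexicographic order, which makes the result invariant to
    input row order.
    """
    ordered = scored.sort_values(
        ["weight", "student_id", "patient_id"], ascending=[False, True, True], kind="mergesort"
    )
    taken_s: set[str] = set()
    taken_p: set[str] = set()
    rows = []
    for row in ordered.itertuples(index=False):
        if row.weight < threshold:
            break
        if row.student_id in taken_s or row.patient_id in taken_p:
            continue
        taken_s.add(row.student_id)
        taken_p.add(row.patient_id)
        rows.append(row._asdict())
    pairs = pd.DataFrame(rows, columns=list(scored.columns))
    students = list(all_students) if all_students is not None else sorted(
        scored["student_id"].unique()
    )
    patients = list(all_patients) if all_patients is not None else sorted(
        scored["patient_id"].unique()
    )
    return MatchSet(
        pairs=pairs,
        unmatched_students=sorted(set(students) - taken_s),
        unmatched_patients=sorted(set(patients) - taken_p),
        threshold=threshold,
    )


def link(
    students: pd.DataFrame, patients: pd.DataFrame, config: LinkageConfig | None = None
) -> tuple[MatchSet, pd.DataFrame, pd.DataFrame]:
    """Full linkage of ASD-flagged students to deduplicated patients.

    Returns the match set, a grey-zone table (scored pairs between
    ``grey_low`` and the acceptance threshold, exported for human review),
    and the within-patient conflicts report.
    """
    config = config or LinkageConfig()
    unique, conflicts = dedupe_patients(patients)
    cand = block(students, unique, mode=config.blocking)
    scored = score_pairs(cand, config.field_specs)
    ms = assign_bijective(
        scored,
        config.threshold,
        all_students=sorted(students["student_id"]),
        all_patients=sorted(unique["patient_id"]),
    )
    grey = scored[(scored["weight"] >= config.grey_low) & (scored["weight"] < config.threshold)]
    return ms, grey.sort_values("weight", ascending=False), conflicts


# -- validation statistics -----------------------------------------------------

def match_rates(
    n_matches: int, students_with_asd: int, patient_rows: int, unique_patients: int
) -> dict[str, float]:
    """Match percentages relative to school records, patient rows and unique patients."""
    if min(students_with_asd, patient_rows, unique_patients) <= 0:
        raise ValueError("denominators must be positive")
    return {
        "pct_school_records_matched": 100 * n_matches / students_with_asd,
        "pct_patient_rows_matched": 100 * n_matches / patient_rows,
        "pct_unique_patients_matched": 100 * n_matches / unique_patients,
    }


def cohens_kappa(table: np.ndarray) -> float:
    """Cohen's kappa for a 2x2 (or KxK) rater agreement table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    if (t < 0).any() or t.sum() == 0:
        raise ValueError("counts must be non-negative with a positive total")
    n = t.sum()
    po = np.trace(t) / n
    pe = float(np.sum(t.sum(axis=0) * t.sum(axis=1)) / n**2)
    if pe == 1.0:
        raise ZeroDivisionError("expected agreement is 1; kappa undefined")
    return (po - pe) / (1 - pe)


def linkage_accuracy(
    matchset: MatchSet, patients: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """Precision/recall against the synthetic truth table.

    A true link is a (student, patient) pair whose patient's latent person
    is that student and whose person is both ASD-flagged in the registry and
    present in the EHR.
    """
    linkable = truth[truth["in_school_registry_as_asd"] & truth["in_ehr"]]["person_id"]
    n_true = len(linkable)
    lat = patients[["patient_id", "latent_person_id"]].drop_duplicates("patient_id")
    merged = matchset.pairs.merge(lat, on="patient_id", how="left")
    correct = int((merged["student_id"] == merged["latent_person_id"]).sum())
    n_acc = len(matchset.pairs)
    return {
        "precision": correct / n_acc if n_acc else 1.0,
        "recall": correct / n_true if n_true else 1.0,
        "n_true_links": n_true,
        "n_accepted": n_acc,
    }
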