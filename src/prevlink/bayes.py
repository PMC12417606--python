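"""Bayesian projection of clinically corrected prevalence to all health services.

The clinical-validation service supplies an additive correction (the
"adjusted prevalence delta", in percentage points) between its
linkage-corrected and school-registry adjusted prevalences.  Every service
then gets a bounded uniform prior on true prevalence — lower bound its
school prevalence, upper bound school prevalence plus delta — combined with
a binomial likelihood on its adjusted school case count through a
logit-scale service random effect:

    p_s ~ Uniform(lower_s, upper_s)
    b_s ~ Normal(0, sigma^2),  sigma ~ Half-Normal(1)
    y_s ~ Binomial(n_s, logit^-1(logit p_s + b_s))

The posterior is explored with a Metropolis-within-Gibbs sampler:
random-walk updates of p_s on the logit of its rescaled position inside the
prior box (so support containment is structural), of b_s on the natural
scale, and of sigma on the log scale.  Step sizes are auto-tuned during
burn-in toward a 20-50% acceptance rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .prevalence import PrevalenceEstimate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeltaEstimate:
    """Clinical correction in percentage points, with a carried CI width."""

    delta: float
    source_school: PrevalenceEstimate
    source_updated: PrevalenceEstimate
    ci_width: float


@dataclass(frozen=True)
class ServicePrior:
    service: str
    lower: float  # proportion (school adjusted prevalence)
    upper: float  # proportion (lower + delta)
    n: float  # child population
    y: float | None  # adjusted case count from school data; None = prior only

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.upper <= 1:
            raise ValueError(f"{self.service}: prior bounds must satisfy 0<=l<=u<=1")
        if self.y is not None and self.y > self.n:
            raise ValueError(f"{self.service}: y must not exceed n")


@dataclass
class McmcConfig:
    burn_in: int = 2000
    kept: int = 2000
    thinning: int = 1
    chains: int = 4
    seed: int = 0
    proposal_sd: float = 0.8  # logit-scale step inside the prior box
    sigma_fixed: float | None = None  # fix the random-effect scale (oracle checks)
    tune: bool = True

    def validate(self) -> None:
        if self.burn_in <= 0 or self.kept <= 0 or self.thinning < 1 or self.chains < 1:
            raise ValueError("burn_in, kept > 0; thinning, chains >= 1")


@dataclass
class PosteriorSummary:
    service: str
    mean: float
    mode: float
    cri_low: float
    cri_high: float
    rhat: float
    n_kept: int
    converged: bool


@dataclass
class McmcResult:
    summaries: list[PosteriorSummary]
    samples: np.ndarray  # p draws, shape (chains, kept, services)
    sigma_samples: np.ndarray  # (chains, kept)
    services: list[str] = field(default_factory=list)
    converged: bool = True


def compute_delta(
    school_est: PrevalenceEstimate,
    updated_est: PrevalenceEstimate,
    service: str | None = None,
    updated_service: str | None = None,
) -> DeltaEstimate:
    """Adjusted prevalence delta: corrected minus school prevalence (points).

    The carried CI width is the maximum of the two source interval widths,
    which later bounds the credible bands built around projections.
    """
    if service is not None and updated_service is not None and service != updated_service:
        raise ValueError(f"estimates from different services: {service!r} vs {updated_service!r}")
    delta = updated_est.point - school_est.point
    if delta < 0:
        logger.warning("negative prevalence delta (%.3f points): corrected below school", delta)
    return DeltaEstimate(
        delta=delta,
        source_school=school_est,
        source_updated=updated_est,
        ci_width=max(school_est.width, updated_est.width),
    )


def build_priors(
    school_table: pd.DataFrame, delta: DeltaEstimate | float
) -> list[ServicePrior]:
    """Bounded uniform priors per service from school prevalence plus delta.

    ``school_table`` needs columns ``health_service``, ``population`` and
    ``school_adjusted_prev_pct``.  The adjusted case count ``y`` is the
    school prevalence applied to the population (adjusted expected count).
    """
    d = delta.delta if isinstance(delta, DeltaEstimate) else float(delta)
    priors = []
    for _, row in school_table.iterrows():
        lower = row["school_adjusted_prev_pct"] / 100
        upper = lower + d / 100
        if upper > 1:
            logger.warning("%s: prior upper bound capped at 1", row["health_service"])
            upper = 1.0
        n = float(row["population"])
        priors.append(
            ServicePrior(
                service=row["health_service"], lower=lower, upper=upper,
                n=n, y=round(lower * n),
            )
        )
    return priors


def _loglik(p, b, y, n, has_y):
    eta = logit(np.clip(p, 1e-12, 1 - 1e-12)) + b
    pi = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    ll = y * np.log(pi) + (n - y) * np.log1p(-pi)
    return np.where(has_y, ll, 0.0)


def run_mcmc(priors: list[ServicePrior], cfg: McmcConfig | None = None) -> McmcResult:
    """Metropolis-within-Gibbs sampling of the bounded-prior random-effects model.

    Returns posterior summaries (mean, KDE-free histogram mode, central 95%
    credible interval, split R-hat across chains) plus the raw kept draws.
    Services whose prior is degenerate (lower == upper) stay fixed at that
    point.
    """
    cfg = cfg or McmcConfig()
    cfg.validate()
    S, C = len(priors), cfg.chains
    l = np.array([pr.lower for pr in priors])
    u = np.array([pr.upper for pr in priors])
    n = np.array([pr.n for pr in priors])
    y = np.array([0.0 if pr.y is None else pr.y for pr in priors])
    has_y = np.array([pr.y is not None for pr in priors])
    live = u > l  # non-degenerate priors
    span = np.where(live, u - l, 1.0)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    z = rng.uniform(-1, 1, size=(C, S))  # logit position inside the box
    p = np.where(live, l + span * expit(z), l)
    b = np.zeros((C, S))
    sigma = np.full(C, cfg.sigma_fixed if cfg.sigma_fixed is not None else 0.5)

    step_z = np.full((C, S), cfg.proposal_sd)
    step_j = np.full((C, S), cfg.proposal_sd)
    step_b = np.full((C, S), 0.5)
    step_s = np.full(C, 0.4)
    acc_z = np.zeros((C, S))
    acc_j = np.zeros((C, S))
    acc_b = np.zeros((C, S))
    acc_s = np.zeros(C)
    TUNE_EVERY = 100

    def log_jac(zv):  # d p / d z up to the constant span factor
        return np.log(expit(zv)) + np.log1p(-expit(zv))

    n_iter = cfg.burn_in + cfg.kept * cfg.thinning
    keep_p = np.empty((C, cfg.kept, S))
    keep_sig = np.empty((C, cfg.kept))
    k = 0
    for it in range(n_iter):
        # p-update (via z inside the box; uniform prior is constant in p)
        z_prop = z + step_z * rng.standard_normal((C, S))
        p_prop = np.where(live, l + span * expit(z_prop), l)
        log_a = (
            _loglik(p_prop, b, y, n, has_y) - _loglik(p, b, y, n, has_y)
            + log_jac(z_prop) - log_jac(z)
        )
        accept = (np.log(rng.random((C, S))) < log_a) & live
        z = np.where(accept, z_prop, z)
        p = np.where(accept, p_prop, p)
        acc_z += accept

        # joint ridge move: shift p, compensate b so the likelihood is
        # unchanged; accepted on the b-prior and box-transform terms only.
        # The likelihood pins logit(p) + b, so single-site moves mix slowly
        # along this ridge without it.
        z_prop = z + step_j * rng.standard_normal((C, S))
        p_prop = np.where(live, l + span * expit(z_prop), l)
        eta_old = logit(np.clip(p, 1e-12, 1 - 1e-12))
        eta_new = logit(np.clip(p_prop, 1e-12, 1 - 1e-12))
        b_prop = b + eta_old - eta_new
        sig2 = (sigma**2)[:, None]
        log_a = (b**2 - b_prop**2) / (2 * sig2) + log_jac(z_prop) - log_jac(z)
        accept = (np.log(rng.random((C, S))) < log_a) & live
        z = np.where(accept, z_prop, z)
        p = np.where(accept, p_prop, p)
        b = np.where(accept, b_prop, b)
        acc_j += accept

        # b-update (normal prior with scale sigma)
        b_prop = b + step_b * rng.standard_normal((C, S))
        log_a = (
            _loglik(p, b_prop, y, n, has_y) - _loglik(p, b, y, n, has_y)
            + (b**2 - b_prop**2) / (2 * sig2)
        )
        accept = np.log(rng.random((C, S))) < log_a
        b = np.where(accept, b_prop, b)
        acc_b += accept

        # sigma-update on the log scale (half-normal(1) hyperprior)
        if cfg.sigma_fixed is None:
            ls_prop = np.log(sigma) + step_s * rng.standard_normal(C)
            sig_prop = np.exp(ls_prop)

            def sigma_logpost(s):
                return (
                    -S * np.log(s)
                    - np.sum(b**2, axis=1) / (2 * s**2)
                    - s**2 / 2
                    + np.log(s)  # jacobian of the log step
                )

            log_a = sigma_logpost(sig_prop) - sigma_logpost(sigma)
            accept = np.log(rng.random(C)) < log_a
            sigma = np.where(accept, sig_prop, sigma)
            acc_s += accept

        if cfg.tune and it < cfg.burn_in and (it + 1) % TUNE_EVERY == 0:
            for acc, step in ((acc_z, step_z), (acc_j, step_j), (acc_b, step_b),
                              (acc_s, step_s)):
                rate = acc / TUNE_EVERY
                step *= np.exp(np.clip(rate - 0.35, -0.5, 0.5))
                acc[...] = 0.0

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            keep_p[:, k, :] = p
            keep_sig[:, k] = sigma
            k += 1

    summaries = _summarize(priors, keep_p, live)
    converged = all(s.converged for s in summaries)
    if not converged:
        logger.warning("R-hat above 1.1 for at least one service; flagged non-converged")
    return McmcResult(
        summaries=summaries,
        samples=keep_p,
        sigma_samples=keep_sig,
        services=[pr.service for pr in priors],
        converged=converged,
    )


def _summarize(priors, keep_p, live) -> list[PosteriorSummary]:
    C, kept, S = keep_p.shape
    if C >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            rhats = az.rhat(az.convert_to_dataset(keep_p))["x"].to_numpy()
    else:
        rhats = np.full(S, np.nan)
    out = []
    for s, pr in enumerate(priors):
        draws = keep_p[:, :, s].ravel()
        if not live[s]:
            out.append(PosteriorSummary(pr.service, pr.lower, pr.lower, pr.lower,
                                        pr.lower, 1.0, C * kept, True))
            continue
        lo, hi = np.percentile(draws, [2.5, 97.5])
        counts, edges = np.histogram(draws, bins=50, range=(pr.lower, pr.upper))
        mode = float((edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2)
        r = float(rhats[s]) if np.isfinite(rhats[s]) else 1.0
        out.append(PosteriorSummary(
            service=pr.service, mean=float(draws.mean()), mode=mode,
            cri_low=float(lo), cri_high=float(hi), rhat=r,
            n_kept=C * kept, converged=r <= 1.1,
        ))
    return out


# -- report-scale arithmetic ---------------------------------------------------

def credible_band(
    projection_pct: float, school_ci_width: float, delta_ci_width: float
) -> tuple[float, float]:
    """Band centred on the projection, width the max of the two source widths.

    All quantities in percent; the band is truncated to [0, 100].
    """
    if school_ci_width < 0 or delta_ci_width < 0:
        raise ValueError("interval widths must be non-negative")
    half = max(school_ci_width, delta_ci_width) / 2
    return max(0.0, projection_pct - half), min(100.0, projection_pct + half)


def national_projection(
    school_national: PrevalenceEstimate,
    delta: DeltaEstimate,
    population: float,
    sen_accessors: float,
) -> dict:
    """National corrected prevalence, posited case count and unmet need.

    The corrected national prevalence is the school estimate plus the delta;
    the posited count applies it to the child population; unmet need is the
    posited count minus the children already accessing SEN support for ASD.
    """
    if population <= 0 or sen_accessors < 0:
        raise ValueError("population must be positive and accessors non-negative")
    updated = school_national.point + delta.delta
    band = credible_band(updated, school_national.width, delta.ci_width)
    posited = updated / 100 * population
    unmet = posited - sen_accessors
    if unmet < 0:
        logger.warning("negative unmet need: accessors exceed the posited case count")
    return {
        "school_prev_pct": school_national.point,
        "delta_points": delta.delta,
        "updated_prev_pct": updated,
        "cri_low_pct": band[0],
        "cri_high_pct": band[1],
        "posited_cases": posited,
        "sen_accessors": sen_accessors,
        "unmet_cases": unmet,
        "unmet_pct": 100 * unmet / posited if posited > 0 else 0.0,
        "access_pct": 100 * sen_accessors / posited if posited > 0 else 0.0,
    }
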