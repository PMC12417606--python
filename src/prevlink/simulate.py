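"""Synthetic school-registry and clinical-EHR generator with shared latent persons.

Every child in every health service gets one registry row; the single
clinical service additionally yields EHR patient rows for (a subset of) its
truly autistic children.  A truth table keyed by latent person id records
ASD status, registry ASD flagging and EHR presence, so linkage and
prevalence stages can be scored against ground truth.

Defaults reproduce the 2021 Chilean registry conditions: the published
per-service child populations and school-flag prevalences, a 6:1
male-to-female prevalence ratio, prevalence declining across the four age
bands, and clinical ascertainment that makes the clinical service's
corrected prevalence sit 0.85 percentage points above its school
prevalence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import AGE_BANDS, CLINICAL_SERVICE, FEE_BANDS, load_service_table

#: implied gap between corrected and school prevalence, percentage points
DELTA_POINTS = 0.85

_BAND_EDGES = {"6-8": (6, 8), "9-11": (9, 11), "12-14": (12, 14), "15-18": (15, 18)}
_ICD10 = ["F84.0", "F84.1", "F84.2", "F84.3", "F84.4", "F84.5", "F84.8", "F84.9"]
_ICD10_P = [0.62, 0.06, 0.02, 0.02, 0.02, 0.14, 0.06, 0.06]

UNKNOWN_COMMUNE = "<unknown>"


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions."""

    seed: int = 0
    services: Mapping[str, int] = field(default_factory=dict)  # name -> child population
    true_prevalence_by_service: Mapping[str, float] = field(default_factory=dict)
    clinical_service: str = CLINICAL_SERVICE
    # probability a truly autistic child carries the registry ASD flag
    school_detection_prob: float | Mapping[str, float] = 0.37 / 1.22
    # probability a truly autistic child in the clinical service has EHR rows
    clinical_capture_prob: float = 1.0
    field_error_rates: Mapping[str, float] = field(
        default_factory=lambda: {"dob": 0.02, "commune": 0.02, "ses": 0.05}
    )
    sex_ratio_mfr: float = 6.0
    age_band_gradient: tuple[float, ...] = (1.25, 1.09, 0.88, 0.78)
    multi_commune_prob: float = 0.02
    missing_commune_prob: float = 0.02
    sen_rate_non_asd: float = 0.1069  # brings overall SEN access to ~11.1%
    p_male: float = 0.51339
    age_band_probs: tuple[float, ...] = (0.24487, 0.25107, 0.24529, 0.25877)
    fee_band_probs: tuple[float, ...] = (0.7167, 0.0004, 0.0119, 0.0677, 0.0886, 0.0983, 0.0164)
    ethnicity_probs: tuple[float, ...] = (0.0577, 0.0069, 0.0071, 0.9284)  # Mapuche/Aymara/Other/None
    immigrant_prob: float = 0.03
    rural_prob: float = 0.0782
    n_communes: int = 21
    reference_date: date = date(2021, 6, 30)

    def detection(self, service: str) -> float:
        if isinstance(self.school_detection_prob, Mapping):
            return self.school_detection_prob[service]
        return self.school_detection_prob

    def validate(self) -> None:
        if not self.services:
            raise ValueError("at least one service is required")
        for name, n in self.services.items():
            if n <= 0:
                raise ValueError(f"population for service {name!r} must be positive")
            if name not in self.true_prevalence_by_service:
                raise ValueError(f"missing true prevalence for service {name!r}")
        probs = {
            "clinical_capture_prob": self.clinical_capture_prob,
            "multi_commune_prob": self.multi_commune_prob,
            "missing_commune_prob": self.missing_commune_prob,
            "sen_rate_non_asd": self.sen_rate_non_asd,
            "p_male": self.p_male,
            "immigrant_prob": self.immigrant_prob,
            "rural_prob": self.rural_prob,
            **{f"field_error_rates[{k}]": v for k, v in self.field_error_rates.items()},
            **{f"true_prevalence[{k}]": v for k, v in self.true_prevalence_by_service.items()},
        }
        dets = (
            dict(self.school_detection_prob)
            if isinstance(self.school_detection_prob, Mapping)
            else {"school_detection_prob": self.school_detection_prob}
        )
        probs.update({f"detection[{k}]": v for k, v in dets.items()})
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if self.clinical_service not in self.services:
            raise ValueError("clinical_service must be one of the configured services")
        if self.sex_ratio_mfr <= 0 or min(self.age_band_gradient) <= 0:
            raise ValueError("risk multipliers must be positive")


def default_config(scale: float = 1.0, seed: int = 0) -> SimConfig:
    """Study-condition config, optionally population-scaled for quick runs.

    True prevalence per service is the school prevalence plus the 0.85-point
    clinical correction; the school detection probability is then the ratio
    of the two, so the registry flag prevalence matches the published
    school prevalence in every service.
    """
    table = load_service_table()
    services, true_prev, detection = {}, {}, {}
    for _, row in table.iterrows():
        name = row["health_service"]
        services[name] = max(1, round(row["population"] * scale))
        school = row["school_adjusted_prev_pct"] / 100
        true_prev[name] = school + DELTA_POINTS / 100
        detection[name] = school / true_prev[name]
    return SimConfig(
        seed=seed,
        services=services,
        true_prevalence_by_service=true_prev,
        school_detection_prob=detection,
    )


def age_band_of(dob: date, reference: date, clamp: bool = False) -> str:
    """Age band at the reference date (years in 6-8, 9-11, 12-14, 15-18).

    With ``clamp=True`` out-of-range ages (e.g. from recording errors in
    clinical dates) map to the nearest band instead of raising.
    """
    age = (reference - dob).days / 365.25
    for band, (lo, hi) in _BAND_EDGES.items():
        if lo <= age < hi + 1:
            return band
    if clamp:
        return "6-8" if age < 6 else "15-18"
    raise ValueError(f"dob {dob} outside the 6-18 age range at {reference}")


def _communes(service: str, k: int) -> list[str]:
    return [f"{service}::C{i:02d}" for i in range(1, k + 1)]


def _swap_day_month(d: date) -> date:
    """Day/month transposition when valid, else a one-day perturbation."""
    if d.day <= 12 and d.day != d.month:
        return date(d.year, d.day, d.month)
    return d + timedelta(days=1 if d.day < 28 else -1)


def simulate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (students, patients, truth) tables.

    The registry covers every service; the EHR extract covers only the
    clinical service.  ``truth`` maps each latent person to ASD status,
    registry-flag status and EHR presence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ref = config.reference_date

    # per-sex / per-band risk multipliers normalized to preserve the marginal
    mfr = config.sex_ratio_mfr
    k_sex = 1.0 / (mfr * config.p_male + (1 - config.p_male))
    sex_mult = {"M": mfr * k_sex, "F": k_sex}
    bp = np.asarray(config.age_band_probs, float)
    bp = bp / bp.sum()
    g = np.asarray(config.age_band_gradient, float)
    band_mult = g / np.sum(bp * g)

    students, truth, patients = [], [], []
    pat_counter = 0
    for svc_idx, (service, n) in enumerate(sorted(config.services.items())):
        prev = config.true_prevalence_by_service[service]
        det = config.detection(service)
        sex = np.where(rng.random(n) < config.p_male, "M", "F")
        band_idx = rng.choice(len(AGE_BANDS), size=n, p=bp)
        # uniform age (in days) within the band -> dob consistent with the band
        lo = np.array([_BAND_EDGES[AGE_BANDS[i]][0] for i in band_idx])
        hi = np.array([_BAND_EDGES[AGE_BANDS[i]][1] for i in band_idx])
        age_days = rng.integers(np.ceil(lo * 365.25), np.floor((hi + 1) * 365.25) - 1)
        dob = np.array([ref - timedelta(days=int(d)) for d in age_days])

        risk = prev * np.where(sex == "M", sex_mult["M"], sex_mult["F"]) * band_mult[band_idx]
        risk = np.clip(risk, 0, 1)
        is_asd = rng.random(n) < risk
        asd_flag = is_asd & (rng.random(n) < det)
        sen_flag = asd_flag | (~asd_flag & (rng.random(n) < config.sen_rate_non_asd))

        communes = _communes(service, config.n_communes)
        cw = 1.0 / np.arange(1, config.n_communes + 1)  # a few large, many small
        cw = cw / cw.sum()
        commune_idx = rng.choice(config.n_communes, size=n, p=cw)
        commune = np.array(communes, dtype=object)[commune_idx]
        # roughly one school per 500 children within a commune
        n_schools = np.maximum(1, np.round(n * cw / 500).astype(int))
        school = np.array(
            [f"{communes[c]}::S{rng.integers(n_schools[c]) + 1:03d}" for c in commune_idx],
            dtype=object,
        )
        commune_missing = rng.random(n) < config.missing_commune_prob

        fee_idx = rng.choice(len(FEE_BANDS), size=n, p=np.asarray(config.fee_band_probs) /
                             np.sum(config.fee_band_probs))
        eth = rng.choice(["Mapuche", "Aymara", "Other", "NoNative"], size=n,
                         p=np.asarray(config.ethnicity_probs) / np.sum(config.ethnicity_probs))
        immigrant = rng.random(n) < config.immigrant_prob
        rural = rng.random(n) < config.rural_prob

        sid = np.array([f"S-{svc_idx:02d}-{i:06d}" for i in range(n)], dtype=object)
        students.append(pd.DataFrame({
            "student_id": sid,
            "sex": sex,
            "dob": [d.isoformat() for d in dob],
            "age_band": [AGE_BANDS[i] for i in band_idx],
            "health_service": service,
            "commune": np.where(commune_missing, None, commune),
            "school_id": school,
            "school_fee_band": [FEE_BANDS[i] for i in fee_idx],
            "ethnicity": eth,
            "immigrant": immigrant,
            "rural": rural,
            "sen_flag": sen_flag,
            "asd_flag": asd_flag,
        }))

        in_ehr = np.zeros(n, bool)
        if service == config.clinical_service:
            in_ehr = is_asd & (rng.random(n) < config.clinical_capture_prob)
            err = config.field_error_rates
            for i in np.flatnonzero(in_ehr):
                pdob = dob[i]
                if rng.random() < err.get("dob", 0.0):
                    pdob = _swap_day_month(pdob)
                pcomm = commune[i]
                if rng.random() < err.get("commune", 0.0):
                    others = [c for c in communes if c != pcomm]
                    pcomm = others[rng.integers(len(others))]
                fee = fee_idx[i]
                if rng.random() < err.get("ses", 0.0) and fee < 6:  # off-by-one rank
                    fee = min(5, fee + 1) if fee == 0 or rng.random() < 0.5 else fee - 1
                insurance = 1 + min(3, (fee if fee < 6 else 1))
                base = {
                    "patient_id": f"P-{pat_counter:06d}",
                    "dob": pdob.isoformat(),
                    "sex": sex[i],
                    "commune": pcomm,
                    "insurance_status": insurance,
                    "fee_band_proxy": FEE_BANDS[fee],
                    "icd10": rng.choice(_ICD10, p=_ICD10_P),
                    "latent_person_id": sid[i],
                }
                pat_counter += 1
                patients.append(base)
                if rng.random() < config.multi_commune_prob:
                    extra = dict(base)
                    others = [c for c in communes if c != pcomm]
                    extra["commune"] = others[rng.integers(len(others))]
                    patients.append(extra)

        truth.append(pd.DataFrame({
            "person_id": sid,
            "health_service": service,
            "is_asd": is_asd,
            "in_school_registry_as_asd": asd_flag,
            "in_ehr": in_ehr,
        }))

    students_df = pd.concat(students, ignore_index=True)
    patients_cols = ["patient_id", "dob", "sex", "commune", "insurance_status",
                     "fee_band_proxy", "icd10", "latent_person_id"]
    patients_df = pd.DataFrame(patients, columns=patients_cols)
    truth_df = pd.concat(truth, ignore_index=True)
    return students_df, patients_df, truth_df


def school_commune_map(students: pd.DataFrame) -> dict[str, str]:
    """Most frequent non-missing commune per school id."""
    ok = students.dropna(subset=["commune"])
    return ok.groupby("school_id")["commune"].agg(lambda s: s.mode().iloc[0]).to_dict()


def impute_commune(
    students: pd.DataFrame, school_map: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing communes from the school's commune.

    Returns the imputed table and a rejects report for rows whose school is
    not in the map; those rows are retained with an explicit
    ``<unknown>`` commune marker.
    """
    out = students.copy()
    missing = out["commune"].isna()
    mapped = out.loc[missing, "school_id"].map(school_map)
    out.loc[missing, "commune"] = mapped
    still = out["commune"].isna()
    rejects = out.loc[still, ["student_id", "school_id"]].copy()
    rejects["reason"] = "school_id not in school->commune map"
    out.loc[still, "commune"] = UNKNOWN_COMMUNE
    return out, rejects


# -- deterministic file output -------------------------------------------------

def write_tables(
    students: pd.DataFrame, patients: pd.DataFrame, truth: pd.DataFrame, outdir: str | Path
) -> dict[str, str]:
    """Write the three CSVs (UTF-8, ISO dates) and return their sha256 hashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "students.csv": students,
        "patients.csv": patients,
        "truth.csv": truth,
    }
    hashes = {}
    for name, df in paths.items():
        p = outdir / name
        df.to_csv(p, index=False, encoding="utf-8", lineterminator="\n")
        hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return hashes


def scaled(config: SimConfig, factor: float) -> SimConfig:
    """Population-scaled copy of a config (all rates unchanged)."""
    services = {k: max(1, round(v * factor)) for k, v in config.services.items()}
    return replace(config, services=services)
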