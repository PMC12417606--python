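"""End-to-end orchestration: simulate -> prevalence -> link -> delta -> bayes -> report.

Each stage reads the previous stage's CSV artifacts from the output
directory and writes its own, so stages can be rerun individually; a final
manifest lists the sha256 hash of every artifact.  One global seed cascades
to per-stage seeds through named spawns of a ``SeedSequence``, making the
whole run bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, determinants, linkage, prevalence, simulate
from .datasets import load_standard_population

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prevalence", "determinants", "link", "delta", "bayes", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: Path
    sim: simulate.SimConfig
    link: linkage.LinkageConfig = field(default_factory=linkage.LinkageConfig)
    mcmc: bayes.McmcConfig = field(default_factory=bayes.McmcConfig)
    std_pop: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.std_pop is None:
            self.std_pop = load_standard_population()
        # one global seed, cascaded deterministically per stage
        children = np.random.SeedSequence(self.seed).spawn(2)
        self.sim.seed = int(children[0].generate_state(1)[0] % (2**31))
        self.mcmc.seed = int(children[1].generate_state(1)[0] % (2**31))


def default_pipeline_config(outdir, seed: int = 0, scale: float = 1.0) -> PipelineConfig:
    return PipelineConfig(outdir=Path(outdir), sim=simulate.default_config(scale=scale), seed=seed)


def config_from_yaml(path, outdir=None) -> PipelineConfig:
    """Load a pipeline config from YAML (explicit seed required)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if "seed" not in raw:
        raise ValueError("config must carry an explicit seed")
    cfg = default_pipeline_config(
        outdir or raw.get("outdir", "prevlink_out"),
        seed=int(raw["seed"]),
        scale=float(raw.get("scale", 1.0)),
    )
    for key, val in raw.get("simulate", {}).items():
        setattr(cfg.sim, key, val)
    for key, val in raw.get("linkage", {}).items():
        setattr(cfg.link, key, val)
    for key, val in raw.get("mcmc", {}).items():
        setattr(cfg.mcmc, key, val)
    return cfg


def _need(outdir: Path, stage: str, *names: str) -> list[Path]:
    paths = [outdir / n for n in names]
    for p in paths:
        if not p.exists():
            raise PipelineError(stage, f"missing input artifact: {p.name}")
    return paths


def _counts_log(outdir: Path, stage: str, **counts) -> None:
    line = {"stage": stage, **{k: int(v) for k, v in counts.items()}}
    with open(outdir / "pipeline.log", "a", encoding="utf-8") as f:
        f.write(json.dumps(line) + "\n")
    logger.info("%s: %s", stage, counts)


def stage_simulate(cfg: PipelineConfig) -> None:
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    students, patients, truth = simulate.simulate(cfg.sim)
    smap = simulate.school_commune_map(students)
    students, rejects = simulate.impute_commune(students, smap)
    simulate.write_tables(students, patients, truth, cfg.outdir)
    rejects.to_csv(cfg.outdir / "commune_rejects.csv", index=False)
    _counts_log(cfg.outdir, "simulate", students=len(students), patients=len(patients),
                rejected_communes=len(rejects))


def stage_prevalence(cfg: PipelineConfig) -> None:
    (students_p,) = _need(cfg.outdir, "prevalence", "students.csv")
    students = pd.read_csv(students_p)
    table = prevalence.prevalence_table(
        students, [[], ["sex"], ["age_band"], ["health_service"], ["ethnicity"]], cfg.std_pop
    )
    table.to_csv(cfg.outdir / "prevalence_by_group.csv", index=False)
    feats = prevalence.feature_counts(
        students, ["sex", "age_band", "health_service", "school_fee_band",
                   "ethnicity", "rural", "sen_flag", "asd_flag"]
    )
    feats.to_csv(cfg.outdir / "feature_counts.csv", index=False)
    _counts_log(cfg.outdir, "prevalence", rows_in=len(students), report_rows=len(table))


def stage_determinants(cfg: PipelineConfig) -> None:
    (students_p,) = _need(cfg.outdir, "determinants", "students.csv")
    students = pd.read_csv(students_p)
    model = determinants.fit_poisson_robust(
        students, "asd_flag",
        ["sex", "age_band", "immigrant", "ethnicity", "school_fee_band", "rural"],
    )
    model.table.to_csv(cfg.outdir / "determinants.csv", index=False)
    _counts_log(cfg.outdir, "determinants", rows_in=len(students), terms=len(model.table))


def stage_link(cfg: PipelineConfig) -> None:
    students_p, patients_p, truth_p = _need(
        cfg.outdir, "link", "students.csv", "patients.csv", "truth.csv"
    )
    students = pd.read_csv(students_p)
    patients = pd.read_csv(patients_p)
    truth = pd.read_csv(truth_p)
    flagged = students[
        (students["health_service"] == cfg.sim.clinical_service) & students["asd_flag"]
    ]
    ms, grey, conflicts = linkage.link(flagged, patients, cfg.link)
    ms.pairs.to_csv(cfg.outdir / "matches.csv", index=False)
    pd.DataFrame({"patient_id": ms.unmatched_patients}).to_csv(
        cfg.outdir / "unmatched_patients.csv", index=False
    )
    grey.to_csv(cfg.outdir / "greyzone.csv", index=False)
    conflicts.to_csv(cfg.outdir / "patient_conflicts.csv", index=False)
    unique_n = patients["patient_id"].nunique()
    report = {
        "n_students_with_asd_flag": int(len(flagged)),
        "n_patient_rows": int(len(patients)),
        "n_unique_patients": int(unique_n),
        "n_matches": int(len(ms.pairs)),
        "n_unmatched_patients": int(len(ms.unmatched_patients)),
    }
    if len(ms.pairs) and unique_n:
        report.update(
            {k: round(v, 2) for k, v in linkage.match_rates(
                len(ms.pairs), len(flagged), len(patients), unique_n
            ).items()}
        )
        report.update(linkage.linkage_accuracy(ms, patients, truth))
    # validation agreement: registry flag vs EHR presence among true cases
    t = truth[truth["is_asd"] & (truth["health_service"] == cfg.sim.clinical_service)]
    if len(t):
        a = int((t["in_school_registry_as_asd"] & t["in_ehr"]).sum())
        b = int((t["in_school_registry_as_asd"] & ~t["in_ehr"]).sum())
        c = int((~t["in_school_registry_as_asd"] & t["in_ehr"]).sum())
        d = int((~t["in_school_registry_as_asd"] & ~t["in_ehr"]).sum())
        report["flag_vs_ehr_table"] = [[a, b], [c, d]]
    (cfg.outdir / "linkage_report.json").write_text(json.dumps(report, indent=2))
    _counts_log(cfg.outdir, "link", candidates_scored=len(grey) + len(ms.pairs),
                matches=len(ms.pairs), unmatched_patients=len(ms.unmatched_patients))


def stage_delta(cfg: PipelineConfig) -> None:
    students_p, patients_p, matches_p, unmatched_p = _need(
        cfg.outdir, "delta", "students.csv", "patients.csv", "matches.csv",
        "unmatched_patients.csv",
    )
    students = pd.read_csv(students_p)
    patients = pd.read_csv(patients_p)
    unmatched = pd.read_csv(unmatched_p)
    svc = cfg.sim.clinical_service
    in_svc = students[students["health_service"] == svc]
    school_sc = prevalence.stratum_counts(in_svc)
    school_est = prevalence.direct_standardize(school_sc, cfg.std_pop)

    # corrected cases: flagged students plus unmatched patients (clinical-only)
    pats = patients.drop_duplicates("patient_id")
    pats = pats[pats["patient_id"].isin(unmatched["patient_id"])].copy()
    ref = cfg.sim.reference_date
    pats["age_band"] = [
        simulate.age_band_of(pd.Timestamp(d).date(), ref, clamp=True) for d in pats["dob"]
    ]
    extra = pats.groupby(["age_band", "sex"], observed=True).size().rename("extra")
    updated_sc = school_sc.set_index(["age_band", "sex"])
    updated_sc["cases"] = updated_sc["cases"].add(extra, fill_value=0)
    updated_sc["cases"] = np.minimum(updated_sc["cases"], updated_sc["population"])
    updated_sc = updated_sc.reset_index()
    updated_est = prevalence.direct_standardize(updated_sc, cfg.std_pop)
    d = bayes.compute_delta(school_est, updated_est, service=svc, updated_service=svc)
    payload = {
        "clinical_service": svc,
        "school_prev_pct": school_est.point,
        "school_ci": [school_est.ci_low, school_est.ci_high],
        "updated_prev_pct": updated_est.point,
        "updated_ci": [updated_est.ci_low, updated_est.ci_high],
        "delta_points": d.delta,
        "delta_ci_width": d.ci_width,
    }
    (cfg.outdir / "delta.json").write_text(json.dumps(payload, indent=2))
    _counts_log(cfg.outdir, "delta", school_cases=school_sc["cases"].sum(),
                updated_cases=updated_sc["cases"].sum())


def stage_bayes(cfg: PipelineConfig) -> None:
    students_p, delta_p = _need(cfg.outdir, "bayes", "students.csv", "delta.json")
    students = pd.read_csv(students_p)
    payload = json.loads(delta_p.read_text())
    # per-service adjusted school prevalence recomputed from the registry table
    rows = []
    for svc, grp in students.groupby("health_service"):
        sc = prevalence.stratum_counts(grp)
        est = prevalence.direct_standardize(sc, cfg.std_pop)
        rows.append({"health_service": svc, "population": len(grp),
                     "school_adjusted_prev_pct": est.point,
                     "ci_low_pct": est.ci_low, "ci_high_pct": est.ci_high})
    school_table = pd.DataFrame(rows)
    school_table.to_csv(cfg.outdir / "school_prevalence_by_service.csv", index=False)
    priors = bayes.build_priors(school_table, payload["delta_points"])
    res = bayes.run_mcmc(priors, cfg.mcmc)
    pd.DataFrame([vars(s) for s in res.summaries]).to_csv(
        cfg.outdir / "posterior_summaries.csv", index=False
    )
    chains, kept, S = res.samples.shape
    flat = pd.DataFrame(res.samples.reshape(chains * kept, S), columns=res.services)
    flat.insert(0, "chain", np.repeat(np.arange(chains), kept))
    flat.insert(1, "draw", np.tile(np.arange(kept), chains))
    flat.to_csv(cfg.outdir / "samples.csv", index=False)
    pd.DataFrame([vars(p) for p in priors]).to_csv(cfg.outdir / "priors.csv", index=False)
    _counts_log(cfg.outdir, "bayes", services=S, kept_draws=chains * kept,
                converged=int(res.converged))


def stage_report(cfg: PipelineConfig) -> dict:
    school_p, delta_p, post_p, students_p = _need(
        cfg.outdir, "report", "school_prevalence_by_service.csv", "delta.json",
        "posterior_summaries.csv", "students.csv",
    )
    school = pd.read_csv(school_p)
    payload = json.loads(delta_p.read_text())
    post = pd.read_csv(post_p).set_index("service")
    rows = []
    fp = prevalence.format_pct
    for _, r in school.iterrows():
        svc = r["health_service"]
        proj = r["school_adjusted_prev_pct"] + payload["delta_points"]
        band = bayes.credible_band(
            proj, r["ci_high_pct"] - r["ci_low_pct"], payload["delta_ci_width"]
        )
        rows.append({
            "health_service": svc,
            "school_prev_pct": fp(r["school_adjusted_prev_pct"]),
            "school_ci_low": fp(r["ci_low_pct"]),
            "school_ci_high": fp(r["ci_high_pct"]),
            "updated_prev_pct": fp(proj),
            "band_low": fp(band[0]),
            "band_high": fp(band[1]),
            "posterior_mean_pct": fp(100 * post.loc[svc, "mean"]),
            "posterior_cri_low_pct": fp(100 * post.loc[svc, "cri_low"]),
            "posterior_cri_high_pct": fp(100 * post.loc[svc, "cri_high"]),
        })
    service_report = pd.DataFrame(rows)
    service_report.to_csv(cfg.outdir / "service_report.csv", index=False)

    students = pd.read_csv(students_p)
    national_sc = prevalence.stratum_counts(students)
    school_nat = prevalence.direct_standardize(national_sc, cfg.std_pop)
    d = bayes.DeltaEstimate(
        delta=payload["delta_points"],
        source_school=prevalence.PrevalenceEstimate(
            payload["school_prev_pct"], *payload["school_ci"], "direct", 0, 0),
        source_updated=prevalence.PrevalenceEstimate(
            payload["updated_prev_pct"], *payload["updated_ci"], "direct", 0, 0),
        ci_width=payload["delta_ci_width"],
    )
    accessors = int(students["asd_flag"].sum())
    nat = bayes.national_projection(school_nat, d, len(students), accessors)
    nat = {k: (fp(v) if isinstance(v, float) else v) for k, v in nat.items()}
    (cfg.outdir / "national_report.json").write_text(json.dumps(nat, indent=2))

    manifest = {"seed": cfg.seed, "artifacts": {}}
    for p in sorted(cfg.outdir.iterdir()):
        if p.name in ("manifest.json", "pipeline.log") or p.is_dir():
            continue
        manifest["artifacts"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _counts_log(cfg.outdir, "report", services=len(service_report),
                artifacts=len(manifest["artifacts"]))
    return manifest


def unmet_need_report(unmatched_patients: int, seed_accessors: int) -> dict:
    """Total cases and SEN-access shares from linkage residuals.

    Total ASD cases in the clinical service = clinical-only (unmatched)
    patients + children already accessing SEN support; percentages at 2 d.p.
    """
    if unmatched_patients < 0 or seed_accessors < 0:
        raise ValueError("counts must be non-negative")
    total = unmatched_patients + seed_accessors
    if total == 0:
        raise ValueError("no cases: report undefined")
    fp = prevalence.format_pct
    return {
        "total_cases": total,
        "seed_accessors": seed_accessors,
        "unmatched_patients": unmatched_patients,
        "access_pct": fp(100 * seed_accessors / total),
        "unmet_pct": fp(100 * unmatched_patients / total),
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "prevalence": stage_prevalence,
    "determinants": stage_determinants,
    "link": stage_link,
    "delta": stage_delta,
    "bayes": stage_bayes,
    "report": stage_report,
}


def run_stage(name: str, cfg: PipelineConfig):
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}")
    try:
        return _STAGE_FUNCS[name](cfg)
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(name, str(exc)) from exc


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order; returns the artifact manifest."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    (cfg.outdir / "pipeline.log").write_text("")
    manifest = None
    for name in STAGES:
        manifest = run_stage(name, cfg)
    return manifest
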