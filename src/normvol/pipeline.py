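"""End-to-end orchestration: simulate → correct → cap → norms → classify
→ curves → reduce → compare, with reproducible, hash-stamped artifacts."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cognition, synthetic
from .classify import classify_subject
from .norms import build_age_norms, cap_outliers, fit_age_curve, variance_components
from .phantom import correct_table, region_columns
from .report import render_report

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("normvol")


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of one full analysis run.

    All stage parameters live here so a run is reproducible from the
    config + seed alone; every artifact is stamped with the config hash.
    """

    out_dir: str = "normvol_out"
    seed: int = 0
    # simulate
    n_subjects: int = 1200
    noise_sd: float = 0.05
    n_patients: int = 10
    deficit_sd: float = 5.0
    deficit_region: str = "genu_corpus_callosum"
    # stages
    cap_threshold: float = 3.0
    min_bin_n: int = 45
    alpha: float = 0.05
    coverage_max: float = 0.9
    n_factors: int = 5
    loading_cutoff: float = 0.3
    # inputs (optional; simulated when absent)
    volumes_csv: str | None = None
    cognitive_csv: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (
            yaml.safe_load(text)
            if str(path).endswith((".yml", ".yaml"))
            else json.loads(text)
        )
        return cls(**data)

    def config_hash(self) -> str:
        # covers every parameter that affects results; output location and
        # logging verbosity do not
        payload = asdict(self)
        payload.pop("out_dir")
        payload.pop("log_level")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline halted at stage {name!r}: {exc} "
                    f"(check the {name} parameters in the config)"
                ) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write artifacts under ``config.out_dir``.

    Returns a name -> path map of artifacts.  Deterministic: rerunning
    an identical config produces byte-identical tables.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    # -- simulate / load ----------------------------------------------------
    @_stage("simulate")
    def simulate():
        presets = synthetic.default_presets(config.noise_sd)
        gen_cfg = synthetic.GeneratorConfig(
            n_subjects=config.n_subjects,
            min_bin_n=config.min_bin_n,
            seed=config.seed,
        )
        if config.volumes_csv:
            cohort = pd.read_csv(config.volumes_csv)
            patients, truth = pd.DataFrame(), pd.DataFrame()
        else:
            cohort = synthetic.generate_normative_cohort(gen_cfg, presets)
            rng = np.random.default_rng(config.seed + 1)
            deficits = [
                synthetic.DeficitSpec(
                    deficits={config.deficit_region: config.deficit_sd},
                    age=float(rng.uniform(9, 21)),
                )
                for _ in range(config.n_patients)
            ]
            patients, truth = synthetic.generate_patient_cohort(
                replace(gen_cfg, seed=config.seed + 2), presets, deficits
            )
        return presets, cohort, patients, truth

    presets, cohort, patients, truth = simulate()
    cohort.to_csv(out / "cohort.csv", index=False)
    artifacts["cohort"] = out / "cohort.csv"
    if len(patients):
        patients.to_csv(out / "patients.csv", index=False)
        truth.to_csv(out / "ground_truth.csv", index=False)
        artifacts["patients"] = out / "patients.csv"

    # -- correct + cap + norms ---------------------------------------------
    @_stage("norms")
    def norms_stage():
        corrected = correct_table(cohort)
        capped, removal = cap_outliers(corrected, threshold=config.cap_threshold)
        norms = build_age_norms(
            capped,
            min_bin_n=config.min_bin_n,
            metadata={"cap_threshold": config.cap_threshold, **stamp},
        )
        return corrected, capped, removal, norms

    corrected, capped, removal, norms = norms_stage()
    removal.to_csv(out / "capping_report.csv", index=False)
    norms.to_json(out / "norms.json")
    artifacts["capping_report"] = out / "capping_report.csv"
    artifacts["norms"] = out / "norms.json"

    # -- age curves + variance ---------------------------------------------
    @_stage("curves")
    def curves_stage():
        curves = {r: fit_age_curve(capped, r) for r in region_columns(cohort)}
        classes = {p.region: p.tissue_class for p in presets}
        decomp = [
            variance_components(capped, cls, classes)
            for cls in ("grey", "white")
        ]
        return curves, decomp

    curves, decomp = curves_stage()
    pd.DataFrame(
        [
            {
                "region": c.region,
                "intercept": c.intercept,
                "slope": c.slope,
                "apr_pct_per_year": c.apr,
                "n": c.n,
                "resid_sd": c.resid_sd,
            }
            for c in curves.values()
        ]
    ).to_csv(out / "age_curves.csv", index=False)
    pd.DataFrame([vars(d) for d in decomp]).to_csv(
        out / "variance_components.csv", index=False
    )
    artifacts["age_curves"] = out / "age_curves.csv"
    artifacts["variance_components"] = out / "variance_components.csv"

    # -- classify patients --------------------------------------------------
    labels: dict[str, str] = {}
    if len(patients):

        @_stage("classify")
        def classify_stage():
            pt_corr = correct_table(patients)
            regions = region_columns(patients)
            rows = []
            results = {}
            for _, row in pt_corr.iterrows():
                res = classify_subject(
                    row[regions],
                    norms,
                    float(row["age_years"]),
                    alpha=config.alpha,
                    provenance=stamp,
                )
                results[row["subject_id"]] = res
                t = res.table.copy()
                t.insert(0, "subject_id", row["subject_id"])
                rows.append(t)
                labels[row["subject_id"]] = res.label
            return pd.concat(rows, ignore_index=True), results

        classification, results = classify_stage()
        classification.to_csv(out / "classification.csv", index=False)
        (out / "subject_labels.json").write_text(
            json.dumps({"labels": labels, **stamp}, indent=1, sort_keys=True)
        )
        artifacts["classification"] = out / "classification.csv"
        artifacts["subject_labels"] = out / "subject_labels.json"

        @_stage("report")
        def report_stage():
            rep_dir = out / "reports"
            for _, row in patients.iterrows():
                render_report(
                    results[row["subject_id"]], norms, curves, row, rep_dir
                )
            return rep_dir

        artifacts["reports"] = report_stage()

    # -- cognition ----------------------------------------------------------
    @_stage("cognition")
    def cognition_stage():
        if config.cognitive_csv:
            battery = pd.read_csv(config.cognitive_csv)
        else:
            model = synthetic.FactorModel(
                blocks={
                    f"factor{k + 1}": [f"measure_{k}_{i}" for i in range(3)]
                    for k in range(config.n_factors)
                }
            )
            battery = synthetic.generate_cognitive_battery(
                {"control": 40, "tbi_low": 20, "tbi_normal": 20},
                model,
                group_effects={"tbi_low": {"factor1": -1.0}},
                seed=config.seed + 3,
            )
        reduction = cognition.reduce_battery(
            battery, n_factors=config.n_factors, cutoff=config.loading_cutoff
        )
        stats = cognition.compare_groups(
            battery, sorted(set(reduction.selected.values()))
        )
        return battery, reduction, stats

    battery, reduction, stats = cognition_stage()
    battery.to_csv(out / "cognitive_battery.csv", index=False)
    reduction.loadings.to_csv(out / "factor_loadings.csv")
    stats.to_csv(out / "group_comparisons.csv", index=False)
    artifacts["cognitive_battery"] = out / "cognitive_battery.csv"
    artifacts["factor_loadings"] = out / "factor_loadings.csv"
    artifacts["group_comparisons"] = out / "group_comparisons.csv"

    manifest = {
        **stamp,
        "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
        "subject_labels": labels,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
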