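"""Reference evaluation protocols on synthetic cohorts.

Standardized experiments used to validate the pipeline end to end:
trajectory parameter recovery from a default-size cohort, the null
false-positive (specificity) rate of the individual classifier, and its
power against large injected deficits.  Each takes a seed and runs the
full generate → correct → cap → model path.
"""

from __future__ import annotations

import numpy as np

from . import synthetic
from .classify import classify_subject
from .norms import build_age_norms, cap_outliers, fit_age_curve, percent_change_between
from .phantom import correct_table, region_columns

__all__ = ["age_curve_recovery", "specificity_rate", "power_rate"]


def age_curve_recovery(
    seed: int, n_subjects: int = 1200, noise_sd: float = 0.05
) -> dict[str, dict[str, float]]:
    """Recover every default preset's APR and 8→20 percent change.

    Generates a default cohort, TICV-corrects, caps at ±3 SD, fits the
    OLS age curve per region and returns
    ``{region: {"apr": ..., "pct_change_8_20": ..., "n": ...}}``.
    """
    presets = synthetic.default_presets(noise_sd)
    cfg = synthetic.GeneratorConfig(n_subjects=n_subjects, seed=seed)
    table = synthetic.generate_normative_cohort(cfg, presets)
    capped, _ = cap_outliers(correct_table(table))
    out = {}
    for region in region_columns(table):
        curve = fit_age_curve(capped, region)
        out[region] = {
            "apr": curve.apr,
            "pct_change_8_20": percent_change_between(curve, 8, 20),
            "n": curve.n,
        }
    return out


def _norms_from_seed(seed: int, n_subjects: int = 1200):
    cfg = synthetic.GeneratorConfig(n_subjects=n_subjects, seed=seed)
    table = synthetic.generate_normative_cohort(cfg)
    capped, _ = cap_outliers(correct_table(table))
    return build_age_norms(capped)


def specificity_rate(
    seed: int, n_subjects: int = 600, alpha: float = 0.05
) -> dict[str, float]:
    """Per-subject false "low volume" rate of healthy subjects.

    Healthy subjects (no deficits, no gross-outlier contamination — that
    mechanism models population QC failures removed by capping, not a
    healthy subject's biology) are classified against norms built from
    an independent same-generator cohort.  Returns the observed flag
    rate, its Monte-Carlo SE and the subject count.
    """
    norms = _norms_from_seed(seed)
    test_cfg = synthetic.GeneratorConfig(
        n_subjects=n_subjects,
        outlier_fraction=0.0,
        min_bin_n=1,
        seed=seed + 104729,
    )
    table = synthetic.generate_normative_cohort(test_cfg)
    corrected = correct_table(table)
    regions = region_columns(table)
    flagged = 0
    for _, row in corrected.iterrows():
        res = classify_subject(row[regions], norms, float(row["age_years"]),
                               alpha=alpha)
        flagged += res.label == "low volume"
    rate = flagged / n_subjects
    return {
        "rate": rate,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_subjects)),
        "n": n_subjects,
    }


def power_rate(
    seed: int,
    n_replicates: int = 200,
    deficit_sd: float = 5.0,
    region: str = "genu_corpus_callosum",
    alpha: float = 0.05,
) -> dict[str, float]:
    """Fraction of large injected deficits the classifier flags.

    Each replicate is one synthetic patient carrying a ``deficit_sd``
    deficit in ``region``, classified against independently generated
    default norms; the hit requires the deficit region itself to be
    flagged after FDR correction.
    """
    norms = _norms_from_seed(seed)
    rng = np.random.default_rng(seed + 15485863)
    specs = [
        synthetic.DeficitSpec(
            deficits={region: deficit_sd}, age=float(rng.uniform(8.5, 22.5))
        )
        for _ in range(n_replicates)
    ]
    pt_cfg = synthetic.GeneratorConfig(seed=seed + 32452843)
    patients, _ = synthetic.generate_patient_cohort(pt_cfg, None, specs)
    corrected = correct_table(patients)
    regions = region_columns(patients)
    hits = 0
    for _, row in corrected.iterrows():
        res = classify_subject(row[regions], norms, float(row["age_years"]),
                               alpha=alpha)
        hits += region in res.flagged_regions
    return {"rate": hits / n_replicates, "n": n_replicates}
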