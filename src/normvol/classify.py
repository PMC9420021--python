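"""Individual-level abnormality detection against age-matched norms.

The headline procedure: each patient's TICV-corrected regional volumes
are turned into Z-scores against the mean and SD of age-matched healthy
references, converted to one-sided (lower-tail) p-values, corrected for
the number of regions tested with Benjamini–Hochberg FDR, and the
subject is labelled "low volume" if any region survives at the chosen
alpha.  For patients with focal lesions, a lesion-matched reference is
built by re-extracting every control's volumes under the patient's own
lesion mask, so patient and norms share the same missing tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .norms import AgeNorms, build_age_norms, cap_outliers
from .phantom import (
    Phantom,
    VOLUME_SUFFIX,
    correct_table,
    extract_roi_volumes,
)

__all__ = [
    "ClassificationResult",
    "zscore_subject",
    "z_to_p",
    "fdr_adjust",
    "classify_regions",
    "classify_subject",
    "lesion_matched_norms",
]

LABEL_LOW = "low volume"
LABEL_NORMAL = "normal volume"
LABEL_UNTESTABLE = "untestable"


@dataclass
class ClassificationResult:
    """Per-region test table + subject-level label.

    ``table`` columns: region, z, p, q, flag, excluded_reason (empty
    string for tested regions).  ``label`` is "low volume" iff at least
    one region is flagged, "untestable" if nothing could be tested.
    """

    table: pd.DataFrame
    label: str
    alpha: float
    provenance: dict = field(default_factory=dict)

    @property
    def flagged_regions(self) -> list[str]:
        t = self.table
        return t.loc[t["flag"].fillna(False).astype(bool), "region"].tolist()


def zscore_subject(
    volumes: pd.Series | dict,
    norms: AgeNorms,
    age: float,
    allow_nearest_bin: bool = False,
) -> tuple[pd.Series, list[str]]:
    """Z-score corrected volumes against the (region, age-year) norms.

    ``volumes`` maps region -> TICV-corrected value.  Returns
    ``(z, excluded)`` where ``z`` is indexed by tested region and
    ``excluded`` lists regions missing from the norms.  An unusable age
    bin raises unless ``allow_nearest_bin`` redirects to the nearest
    usable year (off by default).
    """
    volumes = pd.Series(volumes, dtype=np.float64)
    z = {}
    excluded = []
    for region, v in volumes.items():
        if region not in norms.regions:
            excluded.append(region)
            continue
        use_age = age
        if not norms.usable(region, age):
            if allow_nearest_bin:
                nearest = norms.nearest_usable_age(region, age)
                if nearest is None:
                    excluded.append(region)
                    continue
                use_age = nearest
            else:
                nearest = norms.nearest_usable_age(region, age)
                raise ValueError(
                    f"age bin {int(np.floor(age))} unusable for region "
                    f"{region!r}; nearest usable bin is {nearest} "
                    "(pass allow_nearest_bin=True to use it)"
                )
        cell = norms.get(region, use_age)
        if cell["sd"] <= 0:
            raise ValueError(
                f"degenerate (zero-SD) norm cell for region {region!r}, "
                f"age bin {int(np.floor(use_age))}"
            )
        z[region] = (v - cell["mean"]) / cell["sd"]
    if not z and not excluded:
        raise ValueError("no regions supplied")
    return pd.Series(z, dtype=np.float64), excluded


def z_to_p(z, side: str = "lower"):
    """Standard-normal tail probability for a Z deviation.

    ``side="lower"`` (default) gives the one-sided lower-tail
    probability — small for strongly negative Z, so high-volume regions
    are never flagged as low.  ``side="two"`` gives the two-sided value.
    """
    z = np.asarray(z, dtype=np.float64)
    if not np.isfinite(z).all():
        raise ValueError("Z must be finite")
    if side == "lower":
        return sps.norm.cdf(z)
    if side == "two":
        return 2.0 * sps.norm.sf(np.abs(z))
    raise ValueError(f"unknown side {side!r}")


def fdr_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_regions(
    z: pd.Series,
    alpha: float = 0.05,
    side: str = "lower",
    families: dict[str, list[str]] | None = None,
    excluded: list[str] | None = None,
    provenance: dict | None = None,
) -> ClassificationResult:
    """Flag low-volume regions at FDR level alpha and label the subject.

    By default all tested regions form a single FDR family (the number
    of regions of interest included); ``families`` may split them, e.g.
    into grey and white matter sets, each corrected separately.
    """
    z = pd.Series(z, dtype=np.float64)
    if len(z) == 0 and not excluded:
        raise ValueError("no testable regions")
    rows = []
    if len(z) > 0:
        p = pd.Series(z_to_p(z.to_numpy(), side=side), index=z.index)
        q = pd.Series(np.nan, index=z.index)
        if families is None:
            q[:] = fdr_adjust(p.to_numpy())
        else:
            covered = [r for members in families.values() for r in members]
            leftover = [r for r in z.index if r not in covered]
            groups = dict(families)
            if leftover:
                groups["_other"] = leftover
            for members in groups.values():
                members = [r for r in members if r in z.index]
                if members:
                    q[members] = fdr_adjust(p[members].to_numpy())
        for region in z.index:
            rows.append(
                {
                    "region": region,
                    "z": z[region],
                    "p": p[region],
                    "q": q[region],
                    "flag": bool(q[region] < alpha),
                    "excluded_reason": "",
                }
            )
    for region in excluded or []:
        rows.append(
            {
                "region": region,
                "z": np.nan,
                "p": np.nan,
                "q": np.nan,
                "flag": False,
                "excluded_reason": "not covered by norms",
            }
        )
    table = pd.DataFrame(
        rows, columns=["region", "z", "p", "q", "flag", "excluded_reason"]
    )
    if len(z) == 0:
        label = LABEL_UNTESTABLE
    elif table["flag"].any():
        label = LABEL_LOW
    else:
        label = LABEL_NORMAL
    return ClassificationResult(
        table=table, label=label, alpha=alpha, provenance=provenance or {}
    )


def classify_subject(
    volumes: pd.Series | dict,
    norms: AgeNorms,
    age: float,
    alpha: float = 0.05,
    side: str = "lower",
    families: dict[str, list[str]] | None = None,
    allow_nearest_bin: bool = False,
    provenance: dict | None = None,
) -> ClassificationResult:
    """Z-score + FDR + labelling in one call (the per-patient pipeline)."""
    z, excluded = zscore_subject(volumes, norms, age, allow_nearest_bin)
    prov = {"norms": "standard", "age_bin": int(np.floor(age))}
    prov.update(provenance or {})
    return classify_regions(
        z, alpha=alpha, side=side, families=families, excluded=excluded,
        provenance=prov,
    )


def lesion_matched_norms(
    lesion: np.ndarray,
    control_phantoms: list[Phantom],
    control_meta: pd.DataFrame,
    cap_threshold: float = 3.0,
    min_bin_n: int = 45,
    coverage_max: float = 0.9,
) -> tuple[AgeNorms, list[str]]:
    """Norms rebuilt with the patient's lesion applied to every control.

    Each control phantom's ROI volumes are re-extracted under the
    patient's lesion mask, TICV-corrected with that control's TICV, then
    capped and normed exactly as the standard pipeline.  Returns
    ``(norms, untestable_regions)`` where untestable regions have lesion
    voxel coverage >= ``coverage_max`` and must be excluded from testing.

    ``control_meta`` needs columns subject_id, age_years, ticv_mm3 in
    the same order as ``control_phantoms``.
    """
    if len(control_phantoms) != len(control_meta):
        raise ValueError("control_meta rows must match control_phantoms")
    if len(control_phantoms) == 0:
        raise ValueError("no control phantoms supplied")
    lesion = np.asarray(lesion)
    ref = control_phantoms[0]
    if lesion.shape != ref.tissue.shape:
        raise ValueError(
            f"lesion grid {lesion.shape} does not match control grid "
            f"{ref.tissue.shape}"
        )
    for ph in control_phantoms[1:]:
        if not ph.same_grid_as(ref):
            raise ValueError("control phantoms disagree in grid geometry")

    regions = list(ref.labels)
    rows = []
    coverage = {r: 0.0 for r in regions}
    for ph, (_, meta) in zip(control_phantoms, control_meta.iterrows()):
        lesioned = ph.with_lesion(lesion)
        vols = extract_roi_volumes(lesioned, regions, lesion_policy="mask")
        row = {
            "subject_id": meta["subject_id"],
            "age_years": float(meta["age_years"]),
            "ticv_mm3": float(meta["ticv_mm3"]),
        }
        for rv in vols:
            row[rv.region + VOLUME_SUFFIX] = rv.volume_mm3
            coverage[rv.region] = max(coverage[rv.region], rv.masked_fraction)
        rows.append(row)
    wide = pd.DataFrame(rows)
    untestable = [r for r in regions if coverage[r] >= coverage_max]

    corrected = correct_table(wide)
    capped, _ = cap_outliers(corrected, threshold=cap_threshold)
    norms = build_age_norms(
        capped,
        min_bin_n=min_bin_n,
        metadata={
            "norms": "lesion-matched",
            "cap_threshold": cap_threshold,
            "untestable_regions": untestable,
        },
    )
    return norms, untestable
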