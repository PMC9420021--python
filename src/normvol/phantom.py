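"""Voxel-phantom ROI volumetry with lesion masking and TICV correction.

A :class:`Phantom` bundles the three grids a volumetric analysis needs:
a modulated tissue-density map (each voxel holds the tissue density
contributing ``density * voxel_volume`` mm³), an integer parcellation
assigning voxels to named regions of interest, and an optional binary
lesion mask.  ROI volumes are obtained by integrating the density map
over the region's voxels, excluding any voxel under the lesion — the
quantitative step a morphometry pipeline performs after segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

TISSUE_CLASSES = ("grey", "white")

__all__ = [
    "Phantom",
    "RegionVolume",
    "extract_roi_volumes",
    "correct_ticv",
    "correct_table",
    "total_tissue_volume",
    "region_columns",
    "VOLUME_SUFFIX",
]

#: suffix used for raw per-region volume columns in wide tables
VOLUME_SUFFIX = "_mm3"

#: wide-table demographic columns that are not region volumes
TABLE_META_COLUMNS = ("subject_id", "group", "site", "sex", "age_years", "ticv_mm3")


def region_columns(table: pd.DataFrame) -> list[str]:
    """Region names encoded as ``<region>_mm3`` columns of a wide volume table."""
    return [
        c[: -len(VOLUME_SUFFIX)]
        for c in table.columns
        if c.endswith(VOLUME_SUFFIX) and c != "ticv_mm3"
    ]


@dataclass
class Phantom:
    """Tissue-density map + parcellation (+ optional lesion) on one grid.

    Parameters
    ----------
    tissue
        3D float array, non-negative; voxel value is the tissue density so
        that ``density * voxel_volume`` is that voxel's volume contribution.
    parcellation
        3D integer array of region labels, 0 = background.
    labels
        Mapping region name -> parcellation label.
    lesion
        Optional 3D binary array, 1 = lesioned voxel, same grid.
    voxel_volume
        Volume of one voxel in mm³.
    affine
        NIfTI affine (4x4).  Grids being compared must share it.
    tissue_classes
        Optional mapping region name -> {"grey", "white"}.
    """

    tissue: np.ndarray
    parcellation: np.ndarray
    labels: dict[str, int]
    lesion: np.ndarray | None = None
    voxel_volume: float = 1.0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tissue_classes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.tissue = np.asarray(self.tissue, dtype=np.float64)
        self.parcellation = np.asarray(self.parcellation)
        if self.tissue.shape != self.parcellation.shape:
            raise ValueError(
                f"tissue {self.tissue.shape} and parcellation "
                f"{self.parcellation.shape} grids differ in shape"
            )
        if self.lesion is not None:
            self.lesion = np.asarray(self.lesion)
            if self.lesion.shape != self.tissue.shape:
                raise ValueError(
                    f"lesion {self.lesion.shape} grid does not match "
                    f"tissue {self.tissue.shape}"
                )
            if not np.isin(self.lesion, (0, 1)).all():
                raise ValueError("lesion mask must be binary {0,1}")
        if (self.tissue < 0).any():
            raise ValueError("tissue density map has negative voxels")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    # -- geometry -----------------------------------------------------------

    def same_grid_as(self, other: "Phantom") -> bool:
        return self.tissue.shape == other.tissue.shape and np.allclose(
            self.affine, other.affine
        )

    def with_lesion(self, lesion: np.ndarray | None) -> "Phantom":
        """Copy of this phantom carrying a different (or no) lesion mask."""
        return Phantom(
            tissue=self.tissue,
            parcellation=self.parcellation,
            labels=dict(self.labels),
            lesion=lesion,
            voxel_volume=self.voxel_volume,
            affine=self.affine,
            tissue_classes=dict(self.tissue_classes) if self.tissue_classes else None,
        )

    # -- NIfTI round trip ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write tissue/parcellation/lesion NIfTI images + JSON metadata."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        nib.save(
            nib.Nifti1Image(self.tissue.astype(np.float32), self.affine),
            d / "tissue.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(self.parcellation.astype(np.int16), self.affine),
            d / "parcellation.nii.gz",
        )
        if self.lesion is not None:
            nib.save(
                nib.Nifti1Image(self.lesion.astype(np.uint8), self.affine),
                d / "lesion.nii.gz",
            )
        meta = {
            "labels": self.labels,
            "voxel_volume": self.voxel_volume,
            "tissue_classes": self.tissue_classes,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "Phantom":
        d = Path(directory)
        tissue_img = nib.load(d / "tissue.nii.gz")
        parc_img = nib.load(d / "parcellation.nii.gz")
        lesion = None
        if (d / "lesion.nii.gz").exists():
            lesion = np.asarray(nib.load(d / "lesion.nii.gz").dataobj)
        meta = json.loads((d / "meta.json").read_text())
        return cls(
            tissue=np.asarray(tissue_img.dataobj, dtype=np.float64),
            parcellation=np.asarray(parc_img.dataobj),
            labels={k: int(v) for k, v in meta["labels"].items()},
            lesion=lesion,
            voxel_volume=float(meta["voxel_volume"]),
            affine=tissue_img.affine,
            tissue_classes=meta.get("tissue_classes"),
        )


@dataclass(frozen=True)
class RegionVolume:
    """Lesion-aware volume of one region of interest."""

    region: str
    volume_mm3: float
    masked_fraction: float

    def __post_init__(self) -> None:
        if self.volume_mm3 < 0:
            raise ValueError("volume must be non-negative")
        if not 0.0 <= self.masked_fraction <= 1.0:
            raise ValueError("masked_fraction must lie in [0, 1]")


def extract_roi_volumes(
    phantom: Phantom,
    regions: list[str] | None = None,
    lesion_policy: str = "mask",
) -> list[RegionVolume]:
    """Integrate tissue density over each ROI, excluding lesioned voxels.

    ``volume_j = voxel_volume * sum_{v: P(v)=j, L(v)=0} T(v)``.  The
    ``masked_fraction`` is the proportion of the ROI's voxels under the
    lesion.  With ``lesion_policy="ignore"`` (or no lesion present) the
    unmasked integral is returned and masked_fraction is 0.
    """
    if lesion_policy not in ("mask", "ignore"):
        raise ValueError(f"unknown lesion_policy {lesion_policy!r}")
    if regions is None:
        regions = list(phantom.labels)
    missing = [r for r in regions if r not in phantom.labels]
    if missing:
        raise KeyError(f"regions absent from parcellation labels: {missing}")

    lesion = phantom.lesion if lesion_policy == "mask" else None
    out: list[RegionVolume] = []
    for region in regions:
        roi = phantom.parcellation == phantom.labels[region]
        n_vox = int(roi.sum())
        if n_vox == 0:
            raise ValueError(f"region {region!r} has zero voxels in parcellation")
        if lesion is None:
            keep = roi
            masked_fraction = 0.0
        else:
            hit = roi & (lesion > 0)
            keep = roi & ~hit
            masked_fraction = hit.sum() / n_vox
        volume = phantom.voxel_volume * float(phantom.tissue[keep].sum())
        out.append(RegionVolume(region, volume, float(masked_fraction)))
    return out


def roi_table(volumes: list[RegionVolume]) -> pd.DataFrame:
    """RegionVolume list as a CSV-ready table."""
    return pd.DataFrame(
        {
            "region": [v.region for v in volumes],
            "volume_mm3": [v.volume_mm3 for v in volumes],
            "masked_fraction": [v.masked_fraction for v in volumes],
        }
    )


def correct_ticv(raw_volume, ticv):
    """Head-size correction: raw volume divided by total intracranial volume.

    Returns the unitless ratio ``raw_volume / ticv``; scale-invariant in
    the sense that (v, t) and (c·v, c·t) give the same output.
    """
    ticv_arr = np.asarray(ticv, dtype=np.float64)
    if (ticv_arr <= 0).any():
        raise ValueError("TICV must be positive")
    return np.asarray(raw_volume, dtype=np.float64) / ticv_arr


def correct_table(table: pd.DataFrame, method: str = "ratio") -> pd.DataFrame:
    """TICV-correct a wide volume table.

    Region columns ``<region>_mm3`` are replaced by unitless ``<region>``
    columns.  ``method="ratio"`` divides by TICV (default, the proportional
    method); ``method="residual"`` removes the cohort-level linear TICV
    effect instead (opt-in alternative), returning
    ``v - b*(ticv - mean(ticv))`` rescaled by the cohort mean TICV so both
    methods live on a comparable ratio scale.
    """
    if method not in ("ratio", "residual"):
        raise ValueError(f"unknown TICV correction method {method!r}")
    regions = region_columns(table)
    out = table[[c for c in TABLE_META_COLUMNS if c in table.columns]].copy()
    ticv = table["ticv_mm3"].to_numpy(dtype=np.float64)
    if (ticv <= 0).any():
        raise ValueError("TICV must be positive")
    for region in regions:
        v = table[region + VOLUME_SUFFIX].to_numpy(dtype=np.float64)
        if method == "ratio":
            out[region] = v / ticv
        else:
            b = np.polyfit(ticv, v, 1)[0]
            out[region] = (v - b * (ticv - ticv.mean())) / ticv.mean()
    return out


def total_tissue_volume(
    phantom: Phantom,
    tissue_class: str,
    lesion_policy: str = "mask",
) -> float:
    """Total lesion-masked volume of one tissue class (grey or white).

    Sums the extraction over every region mapped to the class, i.e. the
    integral of the density map over the class's voxels under the same
    lesion policy as per-ROI extraction.  A valid class with no mapped
    regions yields 0.
    """
    if tissue_class not in TISSUE_CLASSES:
        raise ValueError(
            f"unknown tissue class {tissue_class!r}; expected one of {TISSUE_CLASSES}"
        )
    if phantom.tissue_classes is None:
        raise ValueError("phantom carries no region->tissue-class mapping")
    regions = [r for r, c in phantom.tissue_classes.items() if c == tissue_class]
    if not regions:
        return 0.0
    return float(
        sum(v.volume_mm3 for v in extract_roi_volumes(phantom, regions, lesion_policy))
    )
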