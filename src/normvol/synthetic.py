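"""Synthetic normative and patient cohorts with known ground truth.

The study population this emulates is a large multi-site healthy
adolescent cohort (ages 8–22) whose regional brain volumes, after
head-size (TICV) correction, follow approximately linear developmental
trajectories: grey matter fractions decline through adolescence while
white matter fractions rise.  The generative model for subject *i*,
region *j* is

    V_ij = TICV_i * site_offset_i * base_j * (1 + APR_j/100 * (age_i - 8)) * exp(eps_ij)

with eps_ij ~ N(0, noise_sd_j²), so the TICV-corrected value
``V_ij / TICV_i`` sits on the region's preset line up to multiplicative
log-normal noise and a site factor.  A small fraction of cells is
replaced by gross outliers (≥6 log-SD) that the ±3 SD QC stage must
remove.  Patient cohorts carry injected regional deficits expressed in
population SD units, with the ground-truth abnormal set returned for
recovery testing, plus optional focal spherical lesions for the
lesion-masking pathway.

Everything is deterministic given a seed; identical seed + config gives
byte-identical tables and phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phantom import Phantom, VOLUME_SUFFIX

__all__ = [
    "TrajectoryPreset",
    "GeneratorConfig",
    "LesionSpec",
    "DeficitSpec",
    "FactorModel",
    "DEFAULT_PRESETS",
    "default_presets",
    "generate_normative_cohort",
    "generate_patient_cohort",
    "generate_phantom",
    "cuboid_layout",
    "generate_cognitive_battery",
    "corrected_moments",
]

AGE_BASELINE = 8.0  # youngest population age; trajectory anchor


@dataclass(frozen=True)
class TrajectoryPreset:
    """Linear developmental trajectory of one region's TICV-corrected volume.

    ``base_fraction`` is the region's fraction of TICV at age 8 and ``apr``
    the annual percent rate of change relative to that age-8 value, so the
    trajectory is ``base_fraction * (1 + apr/100 * (age - 8))``.
    ``noise_sd`` is the log-scale SD of the multiplicative subject noise.
    """

    region: str
    tissue_class: str
    base_fraction: float
    apr: float
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.tissue_class not in ("grey", "white"):
            raise ValueError(f"tissue_class must be grey/white, got {self.tissue_class!r}")
        if self.base_fraction <= 0:
            raise ValueError("base_fraction must be positive")
        if abs(self.apr) >= 10:
            raise ValueError("|apr| must be < 10 %/yr")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # trajectory must stay positive across the population age span
        if self.line(22.0) <= 0 or self.line(8.0) <= 0:
            raise ValueError(
                f"trajectory for {self.region!r} is non-positive within ages 8-22"
            )

    def line(self, age) -> np.ndarray | float:
        """Noise-free TICV-corrected trajectory value at ``age``."""
        return self.base_fraction * (1.0 + self.apr / 100.0 * (np.asarray(age) - AGE_BASELINE))


def default_presets(noise_sd: float = 0.05) -> list[TrajectoryPreset]:
    """Presets calibrated to the published adolescent trajectories.

    Regional annual percent rates: posterior cingulate −1.9, amygdala
    −0.8, corticospinal tract +0.8, body of corpus callosum +0.5, genu
    +0.1 %/yr.  Global aggregates are set so the fitted 8→20 change is
    −17% (grey) and +9% (white), i.e. APR = −17/12 and +9/12 under the
    linear model.  Base fractions are realistic shares of TICV; noise_sd
    is a free parameter of the emulation (default 5% CV).
    """
    rows = [
        ("global_grey", "grey", 0.45, -17.0 / 12.0),
        ("global_white", "white", 0.30, 9.0 / 12.0),
        ("posterior_cingulate", "grey", 0.006, -1.9),
        ("amygdala", "grey", 0.0025, -0.8),
        ("corticospinal_tract", "white", 0.008, 0.8),
        ("body_corpus_callosum", "white", 0.004, 0.5),
        ("genu_corpus_callosum", "white", 0.003, 0.1),
    ]
    return [
        TrajectoryPreset(region, cls, base, apr, noise_sd)
        for region, cls, base, apr in rows
    ]


DEFAULT_PRESETS: list[TrajectoryPreset] = default_presets()


@dataclass(frozen=True)
class GeneratorConfig:
    """Population-level parameters of the synthetic cohort.

    Ages are stratified over integer year bins ``age_range[0]..age_range[1]``
    (inclusive), uniform within each bin, guaranteeing every bin at least
    ``n_subjects // n_bins`` subjects.  TICV grows linearly with age from
    ``ticv_base_mm3`` (female, age 8) and males carry the multiplicative
    ``sex_ticv_ratio``.  Site membership is uniform; each site applies a
    multiplicative offset to all regional volumes.
    """

    n_subjects: int = 1200
    age_range: tuple[int, int] = (8, 22)
    n_sites: int = 3
    site_offsets: tuple[float, ...] = (0.98, 1.00, 1.02)
    sex_ticv_ratio: float = 1.10
    ticv_base_mm3: float = 1.35e6
    ticv_growth_per_year: float = 0.004
    ticv_noise_sd: float = 0.03
    male_fraction: float = 852 / 1232
    outlier_fraction: float = 0.01
    outlier_log_sd_range: tuple[float, float] = (6.0, 8.0)
    min_bin_n: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if len(self.site_offsets) != self.n_sites:
            raise ValueError("site_offsets length must equal n_sites")
        if not 0.0 <= self.outlier_fraction < 0.05:
            raise ValueError("outlier_fraction must lie in [0, 0.05)")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        lo, hi = self.outlier_log_sd_range
        if not (lo >= 6.0 and hi >= lo):
            raise ValueError("outlier shifts must be >= 6 log-SD")

    @property
    def age_bins(self) -> np.ndarray:
        return np.arange(self.age_range[0], self.age_range[1] + 1)


@dataclass(frozen=True)
class LesionSpec:
    """Spherical focal lesion on the phantom grid (voxel units)."""

    centre: tuple[int, int, int]
    radius: float
    target_regions: tuple[str, ...] = ()

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(shape)
        d2 = sum((idx[k] - self.centre[k]) ** 2 for k in range(3))
        m = (d2 <= self.radius**2).astype(np.uint8)
        if not m.any():
            raise ValueError("lesion sphere lies outside the grid")
        return m


@dataclass(frozen=True)
class DeficitSpec:
    """Ground-truth regional deficits for one synthetic patient.

    ``deficits`` maps region name to a non-negative deficit magnitude in
    population SD units of the TICV-corrected volume at the patient's
    age.  ``age`` may be fixed or left None to be sampled like a healthy
    subject.  An optional focal lesion is attached for phantom builds.
    """

    deficits: dict[str, float] = field(default_factory=dict)
    age: float | None = None
    lesion: LesionSpec | None = None

    def __post_init__(self) -> None:
        for region, d in self.deficits.items():
            if d < 0:
                raise ValueError(f"deficit for {region!r} must be >= 0 SD")


# -- generative helpers ------------------------------------------------------


def corrected_moments(
    preset: TrajectoryPreset, config: GeneratorConfig, age: float
) -> tuple[float, float]:
    """Analytic mean and SD of the TICV-corrected value at an exact age.

    Marginalizes over the uniform site assignment and the log-normal
    noise: with line value L, offsets o_k and s = noise_sd,
    E[v] = mean(o)·L·e^{s²/2} and E[v²] = mean(o²)·L²·e^{2s²}.
    """
    line = float(preset.line(age))
    o = np.asarray(config.site_offsets, dtype=np.float64)
    s2 = preset.noise_sd**2
    m1 = o.mean() * line * np.exp(s2 / 2.0)
    m2 = (o**2).mean() * line**2 * np.exp(2.0 * s2)
    var = max(m2 - m1**2, 0.0)
    return float(m1), float(np.sqrt(var))


def _check_presets(presets: list[TrajectoryPreset]) -> dict[str, TrajectoryPreset]:
    by_name = {p.region: p for p in presets}
    if len(by_name) != len(presets):
        raise ValueError("duplicate region names in presets")
    return by_name


def _sample_demographics(
    config: GeneratorConfig,
    rng: np.random.Generator,
    n: int,
    enforce_min_bin: bool = True,
):
    bins = config.age_bins
    n_bins = len(bins)
    per_bin = np.full(n_bins, n // n_bins)
    per_bin[: n % n_bins] += 1
    if enforce_min_bin and (per_bin < config.min_bin_n).any():
        bad = bins[per_bin < config.min_bin_n]
        raise ValueError(
            f"age bin(s) {bad.tolist()} receive fewer than min_bin_n="
            f"{config.min_bin_n} subjects at n_subjects={n}"
        )
    age_bin = np.repeat(bins, per_bin)
    ages = age_bin + rng.uniform(0.0, 1.0, size=n)
    order = rng.permutation(n)
    ages = ages[order]
    sex = np.where(rng.uniform(size=n) < config.male_fraction, "M", "F")
    site = rng.integers(0, config.n_sites, size=n)
    ticv = (
        config.ticv_base_mm3
        * (1.0 + config.ticv_growth_per_year * (ages - AGE_BASELINE))
        * np.where(sex == "M", config.sex_ticv_ratio, 1.0)
        * np.exp(rng.normal(0.0, config.ticv_noise_sd, size=n))
    )
    return ages, sex, site, ticv


def _healthy_volumes(
    presets: dict[str, TrajectoryPreset],
    config: GeneratorConfig,
    rng: np.random.Generator,
    ages: np.ndarray,
    site: np.ndarray,
    ticv: np.ndarray,
    inject_outliers: bool,
) -> dict[str, np.ndarray]:
    n = len(ages)
    offsets = np.asarray(config.site_offsets)[site]
    volumes: dict[str, np.ndarray] = {}
    for region, p in presets.items():
        eps = rng.normal(0.0, p.noise_sd, size=n) if p.noise_sd > 0 else np.zeros(n)
        v = ticv * offsets * p.line(ages) * np.exp(eps)
        if inject_outliers and config.outlier_fraction > 0:
            hit = rng.uniform(size=n) < config.outlier_fraction
            k = int(hit.sum())
            if k:
                lo, hi = config.outlier_log_sd_range
                shift = rng.uniform(lo, hi, size=k) * p.noise_sd
                sign = rng.choice([-1.0, 1.0], size=k)
                v[hit] = v[hit] * np.exp(sign * shift)
        volumes[region] = v
    return volumes


def generate_normative_cohort(
    config: GeneratorConfig,
    presets: list[TrajectoryPreset] | None = None,
) -> pd.DataFrame:
    """Healthy multi-site cohort as a wide volume table.

    Columns: subject_id, group, site, sex, age_years, ticv_mm3 and one
    ``<region>_mm3`` column per preset.  Deterministic for a fixed
    ``config.seed``.
    """
    presets = presets if presets is not None else DEFAULT_PRESETS
    by_name = _check_presets(presets)
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ages, sex, site, ticv = _sample_demographics(config, rng, n)
    volumes = _healthy_volumes(by_name, config, rng, ages, site, ticv, True)

    table = pd.DataFrame(
        {
            "subject_id": [f"ctrl{i:05d}" for i in range(n)],
            "group": "control",
            "site": [f"site{s}" for s in site],
            "sex": sex,
            "age_years": ages,
            "ticv_mm3": ticv,
        }
    )
    for region, v in volumes.items():
        table[region + VOLUME_SUFFIX] = v
    return table


def generate_patient_cohort(
    config: GeneratorConfig,
    presets: list[TrajectoryPreset] | None = None,
    deficits: list[DeficitSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient cohort with injected regional deficits + ground truth.

    One patient per :class:`DeficitSpec`.  Each patient's volumes are the
    healthy generative values shifted down, per affected region, by
    ``deficit_SD * sigma_{j,a}`` where sigma is the analytic population
    SD of the TICV-corrected value at the patient's age (times TICV on
    the raw scale).  Returns ``(table, ground_truth)`` where ground_truth
    has one row per (subject, region) injected deficit.
    """
    presets = presets if presets is not None else DEFAULT_PRESETS
    by_name = _check_presets(presets)
    if deficits is None:
        deficits = []
    for spec in deficits:
        unknown = [r for r in spec.deficits if r not in by_name]
        if unknown:
            raise KeyError(f"deficit regions absent from presets: {unknown}")

    rng = np.random.default_rng(config.seed)
    n = len(deficits)
    cfg_n = replace(config, n_subjects=max(n, 1))
    ages, sex, site, ticv = _sample_demographics(
        cfg_n, rng, max(n, 1), enforce_min_bin=False
    )
    ages = ages[:n]
    for i, spec in enumerate(deficits):
        if spec.age is not None:
            ages[i] = spec.age
    volumes = _healthy_volumes(by_name, config, rng, ages, site[:n], ticv[:n], False)

    truth_rows = []
    for i, spec in enumerate(deficits):
        for region, d_sd in spec.deficits.items():
            if d_sd == 0:
                continue
            _, sigma = corrected_moments(by_name[region], config, ages[i])
            new = volumes[region][i] - d_sd * sigma * ticv[i]
            if new <= 0:
                raise ValueError(
                    f"deficit of {d_sd} SD drives {region!r} volume negative "
                    f"for patient {i}"
                )
            volumes[region][i] = new
            truth_rows.append(
                {"subject_id": f"tbi{i:04d}", "region": region, "deficit_sd": d_sd}
            )

    table = pd.DataFrame(
        {
            "subject_id": [f"tbi{i:04d}" for i in range(n)],
            "group": "tbi",
            "site": [f"site{s}" for s in site[:n]],
            "sex": sex[:n],
            "age_years": ages,
            "ticv_mm3": ticv[:n],
        }
    )
    for region, v in volumes.items():
        table[region + VOLUME_SUFFIX] = v
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "region", "deficit_sd"])
    return table, truth


# -- voxel phantoms ----------------------------------------------------------


def cuboid_layout(
    regions: list[str], shape: tuple[int, int, int] = (32, 32, 32)
) -> dict[str, np.ndarray]:
    """Assign each region a disjoint slab of z-planes on the grid.

    Returns region -> boolean voxel mask.  Raises if the grid is too
    small to give every region at least one plane.
    """
    nz = shape[2]
    k = len(regions)
    if k == 0:
        raise ValueError("no regions to lay out")
    if k > nz:
        raise ValueError(f"grid depth {nz} cannot host {k} disjoint regions")
    per = nz // k
    layout: dict[str, np.ndarray] = {}
    for i, region in enumerate(regions):
        mask = np.zeros(shape, dtype=bool)
        mask[:, :, i * per : (i + 1) * per] = True
        layout[region] = mask
    return layout


def generate_phantom(
    subject: pd.Series,
    layout: dict[str, np.ndarray],
    lesion: LesionSpec | None = None,
    voxel_volume: float = 1.0,
    tissue_classes: dict[str, str] | None = None,
) -> Phantom:
    """Voxel phantom whose unmasked ROI integrals reproduce the table row.

    Each ROI is filled with a uniform density ``volume / (n_vox * voxel_volume)``
    so unmasked extraction returns the subject's tabular volume exactly
    (well within the 0.1% contract).  The lesion, if given, is rendered
    as a binary sphere on the same grid.
    """
    shapes = {m.shape for m in layout.values()}
    if len(shapes) != 1:
        raise ValueError("layout masks disagree in shape")
    shape = shapes.pop()
    occupancy = np.zeros(shape, dtype=np.int64)
    for m in layout.values():
        occupancy += m.astype(np.int64)
    if (occupancy > 1).any():
        raise ValueError("layout regions overlap")

    tissue = np.zeros(shape, dtype=np.float64)
    parcellation = np.zeros(shape, dtype=np.int16)
    labels: dict[str, int] = {}
    for label, (region, mask) in enumerate(layout.items(), start=1):
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise ValueError(f"region {region!r} has zero voxels in layout")
        volume = float(subject[region + VOLUME_SUFFIX])
        tissue[mask] = volume / (n_vox * voxel_volume)
        parcellation[mask] = label
        labels[region] = label
    lesion_grid = lesion.mask(shape) if lesion is not None else None
    return Phantom(
        tissue=tissue,
        parcellation=parcellation,
        labels=labels,
        lesion=lesion_grid,
        voxel_volume=voxel_volume,
        tissue_classes=tissue_classes,
    )


# -- cognitive battery -------------------------------------------------------


@dataclass(frozen=True)
class FactorModel:
    """Block factor model for a synthetic neuropsychological battery.

    ``blocks`` maps each latent factor to the disjoint list of measures
    it loads on; every measure in a block carries the same ``loading``.
    """

    blocks: dict[str, list[str]]
    loading: float = 0.8

    def __post_init__(self) -> None:
        measures = [m for ms in self.blocks.values() for m in ms]
        if len(set(measures)) != len(measures):
            raise ValueError("factor blocks must be disjoint")
        if len(self.blocks) > len(measures):
            raise ValueError("more factors than measures")
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError("loading must lie in [0, 1]")

    @property
    def measures(self) -> list[str]:
        return [m for ms in self.blocks.values() for m in ms]


def generate_cognitive_battery(
    n_per_group: dict[str, int],
    factor_model: FactorModel,
    group_effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    scale: str = "standard",
) -> pd.DataFrame:
    """Standardized cognitive scores with known latent block structure.

    Each subject draws one latent value per factor; a measure in factor
    k's block is ``loading*z_k + sqrt(1-loading²)*noise`` plus that
    group's shift on factor k (in SD units, scaled by the loading).
    ``scale="standard"`` reports mean-100/SD-15 scores, ``scale="z"``
    raw z-units.
    """
    if scale not in ("standard", "z"):
        raise ValueError(f"unknown scale {scale!r}")
    group_effects = group_effects or {}
    for g, eff in group_effects.items():
        unknown = [f for f in eff if f not in factor_model.blocks]
        if unknown:
            raise KeyError(f"group {g!r} shifts unknown factors {unknown}")

    rng = np.random.default_rng(seed)
    lam = factor_model.loading
    uniq = np.sqrt(1.0 - lam**2)
    rows = []
    sid = 0
    for group, n in n_per_group.items():
        shifts = group_effects.get(group, {})
        for _ in range(n):
            latent = {f: rng.normal() for f in factor_model.blocks}
            row = {"subject_id": f"s{sid:04d}", "group": group}
            for f, measures in factor_model.blocks.items():
                shifted = latent[f] + shifts.get(f, 0.0)
                for m in measures:
                    z = lam * shifted + uniq * rng.normal()
                    row[m] = 100.0 + 15.0 * z if scale == "standard" else z
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)
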