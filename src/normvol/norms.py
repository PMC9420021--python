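"""Age-matched normative modelling of TICV-corrected regional volumes.

Builds the reference a single patient is later compared against:

1. QC capping — within each (region, age-year) cell, observations more
   than ``threshold`` cell SDs from the cell mean are *excluded* (a
   single pass, not winsorized).  Under normality a ±3 SD threshold
   retains over 99% of the data.
2. Per-age-year norms — mean, SD and n of the corrected volume for every
   region and integer age bin; bins with fewer than ``min_bin_n``
   subjects are flagged unusable.
3. Developmental age curves — an ordinary least-squares line of
   corrected volume on continuous age, summarized as the annual percent
   rate of change (APR) relative to the fitted value at the youngest
   population age (8 years), so that the fitted percent change between
   ages 8 and 20 equals 12·APR.
4. Variance decomposition — sequential (type-I) sums of squares of the
   linear model value ~ age + sex + site, in that fixed order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .phantom import TABLE_META_COLUMNS

__all__ = [
    "AgeNorms",
    "AgeCurve",
    "VarianceDecomposition",
    "cap_outliers",
    "build_age_norms",
    "fit_age_curve",
    "percent_change_between",
    "variance_components",
    "age_bin",
]


def age_bin(age_years) -> np.ndarray:
    """Integer age-year bin: floor of the age in years."""
    return np.floor(np.asarray(age_years)).astype(int)


def _region_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in TABLE_META_COLUMNS]


def _to_long(table: pd.DataFrame, regions: list[str]) -> pd.DataFrame:
    long = table.melt(
        id_vars=["subject_id", "age_years"],
        value_vars=regions,
        var_name="region",
        value_name="value",
    )
    long["age_bin"] = age_bin(long["age_years"])
    return long


def cap_outliers(
    table: pd.DataFrame, threshold: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass ±threshold SD exclusion within (region, age-year) cells.

    ``table`` is a TICV-corrected wide table (region columns are the
    unitless corrected values).  Excluded cells are set to NaN in the
    returned copy; the report lists subject_id, region, age_bin, value
    and the cell Z-score of every removed observation.  Cells with zero
    SD remove nothing (a warning is emitted); cells with fewer than 3
    observations are an error.
    """
    regions = _region_cols(table)
    if not regions:
        raise ValueError("table has no region columns to cap")
    out = table.copy()
    bins = age_bin(table["age_years"])
    removed = []
    zero_sd_cells = []
    for b in np.unique(bins):
        in_bin = bins == b
        if in_bin.sum() < 3:
            raise ValueError(
                f"age bin {b} holds only {int(in_bin.sum())} observations; "
                "need >= 3 per cell for capping"
            )
        for region in regions:
            v = table.loc[in_bin, region].to_numpy(dtype=np.float64)
            mean = v.mean()
            sd = v.std(ddof=1)
            if sd == 0:
                zero_sd_cells.append((region, int(b)))
                continue
            z = (v - mean) / sd
            bad = np.abs(z) > threshold
            if bad.any():
                idx = table.index[in_bin][bad]
                out.loc[idx, region] = np.nan
                for i, zi in zip(idx, z[bad]):
                    removed.append(
                        {
                            "subject_id": table.at[i, "subject_id"],
                            "region": region,
                            "age_bin": int(b),
                            "value": table.at[i, region],
                            "z": float(zi),
                        }
                    )
    if zero_sd_cells:
        warnings.warn(
            f"zero-SD cells skipped during capping: {zero_sd_cells[:5]}"
            + ("..." if len(zero_sd_cells) > 5 else ""),
            stacklevel=2,
        )
    report = pd.DataFrame(
        removed, columns=["subject_id", "region", "age_bin", "value", "z"]
    )
    return out, report


@dataclass
class AgeNorms:
    """Per-region, per-age-year reference: mean, SD and n.

    ``stats`` is indexed by (region, age) with columns mean/sd/n/usable.
    A bin is usable when ``n >= min_bin_n`` and its SD is positive.
    """

    stats: pd.DataFrame
    min_bin_n: int
    metadata: dict = field(default_factory=dict)

    @property
    def regions(self) -> list[str]:
        return sorted(self.stats.index.get_level_values("region").unique())

    def get(self, region: str, age: float) -> pd.Series:
        """Stats of the (region, floor(age)) cell; KeyError if absent."""
        return self.stats.loc[(region, int(np.floor(age)))]

    def usable(self, region: str, age: float) -> bool:
        try:
            return bool(self.get(region, age)["usable"])
        except KeyError:
            return False

    def nearest_usable_age(self, region: str, age: float) -> int | None:
        sub = self.stats.loc[region]
        ok = sub.index[sub["usable"].astype(bool)]
        if len(ok) == 0:
            return None
        return int(ok[np.argmin(np.abs(ok - int(np.floor(age))))])

    # -- JSON serialization: {region: {age: {mean, sd, n}}, "_meta": ...} ----

    def to_json(self, path: str | Path | None = None) -> str:
        payload: dict = {"_meta": {"min_bin_n": self.min_bin_n, **self.metadata}}
        for (region, a), row in self.stats.iterrows():
            payload.setdefault(region, {})[str(int(a))] = {
                "mean": float(row["mean"]),
                "sd": float(row["sd"]),
                "n": int(row["n"]),
            }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AgeNorms":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(s).read_text()
        payload = json.loads(text)
        meta = payload.pop("_meta", {})
        min_bin_n = int(meta.pop("min_bin_n", 1))
        rows = []
        for region, by_age in payload.items():
            for a, cell in by_age.items():
                rows.append(
                    {
                        "region": region,
                        "age": int(a),
                        "mean": cell["mean"],
                        "sd": cell["sd"],
                        "n": cell["n"],
                    }
                )
        stats = pd.DataFrame(rows).set_index(["region", "age"]).sort_index()
        stats["usable"] = stats["n"] >= min_bin_n
        return cls(stats=stats, min_bin_n=min_bin_n, metadata=meta)


def build_age_norms(
    table: pd.DataFrame,
    min_bin_n: int = 45,
    regions: list[str] | None = None,
    metadata: dict | None = None,
) -> AgeNorms:
    """Per-cell mean/SD/n from a corrected (and already capped) table.

    NaN cells (capped observations) are excluded from each cell's
    statistics.  Raises if a requested region is absent or if no bin of
    any region is usable.
    """
    available = _region_cols(table)
    if regions is None:
        regions = available
    missing = [r for r in regions if r not in available]
    if missing:
        raise KeyError(f"regions absent from table: {missing}")
    long = _to_long(table, regions).dropna(subset=["value"])
    grouped = long.groupby(["region", "age_bin"])["value"]
    stats = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    stats.index = stats.index.set_names(["region", "age"])
    stats["sd"] = stats["sd"].fillna(0.0)
    # usable = enough subjects in the bin; degenerate SD is warned here and
    # rejected at Z-scoring time, so zero-noise reference tables still build
    stats["usable"] = stats["n"] >= min_bin_n
    if (stats.loc[stats["n"] >= 2, "sd"] <= 0).any():
        warnings.warn("degenerate (zero-SD) norm cells present", stacklevel=2)
    if not stats["usable"].any():
        raise ValueError(
            f"no usable age bin in any region at min_bin_n={min_bin_n}"
        )
    return AgeNorms(
        stats=stats.sort_index(),
        min_bin_n=min_bin_n,
        metadata=metadata or {},
    )


@dataclass(frozen=True)
class AgeCurve:
    """OLS line of TICV-corrected volume on age, with its APR summary.

    APR = 100·slope / fitted value at ``baseline_age`` (% per year), so
    the modelled percent change between the baseline age and age a is
    APR·(a − baseline_age).
    """

    region: str
    intercept: float
    slope: float
    apr: float
    baseline_age: float
    n: int
    resid_sd: float

    def predict(self, age) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(age, dtype=np.float64)


def fit_age_curve(
    table: pd.DataFrame, region: str, baseline_age: float = 8.0
) -> AgeCurve:
    """Fit the developmental age curve for one region.

    Uses continuous age, drops NaN (capped) cells, and anchors the APR
    at ``baseline_age`` — the youngest population age by default.
    """
    if region not in table.columns:
        raise KeyError(f"region {region!r} absent from table")
    sub = table[["age_years", region]].dropna()
    ages = sub["age_years"].to_numpy(dtype=np.float64)
    if len(np.unique(ages)) < 2:
        raise ValueError("need >= 2 distinct ages to fit an age curve")
    X = sm.add_constant(ages)
    fit = sm.OLS(sub[region].to_numpy(dtype=np.float64), X).fit()
    intercept, slope = fit.params
    v8 = intercept + slope * baseline_age
    if v8 <= 0:
        raise ValueError(
            f"fitted value at baseline age {baseline_age} is non-positive"
        )
    return AgeCurve(
        region=region,
        intercept=float(intercept),
        slope=float(slope),
        apr=float(100.0 * slope / v8),
        baseline_age=float(baseline_age),
        n=int(fit.nobs),
        resid_sd=float(np.sqrt(fit.scale)),
    )


def percent_change_between(curve: AgeCurve, a1: float, a2: float) -> float:
    """Fitted percent change 100·(V̂(a2) − V̂(a1)) / V̂(a1)."""
    if not a1 < a2:
        raise ValueError("need a1 < a2")
    v1 = float(curve.predict(a1))
    if v1 <= 0:
        raise ValueError(f"fitted value at age {a1} is non-positive")
    return 100.0 * (float(curve.predict(a2)) - v1) / v1


@dataclass(frozen=True)
class VarianceDecomposition:
    """Percent of variance attributed to age, sex and site (sequential SS)."""

    tissue_class: str
    age_pct: float
    sex_pct: float
    site_pct: float

    def __post_init__(self) -> None:
        for v in (self.age_pct, self.sex_pct, self.site_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError("variance fractions must lie in [0, 100]")
        if self.age_pct + self.sex_pct + self.site_pct > 100.0 + 1e-9:
            raise ValueError("variance fractions exceed 100%")


def variance_components(
    table: pd.DataFrame,
    tissue_class: str,
    region_classes: dict[str, str],
) -> VarianceDecomposition:
    """Sequential type-I variance shares for one tissue class.

    The response is the per-subject sum of corrected volumes over the
    class's regions (its global aggregate).  Predictors enter the linear
    model in the fixed order age, sex, site; each share is that term's
    sequential sum of squares over the total SS, in percent.  Constant
    predictors contribute 0 with a warning.
    """
    regions = [
        r for r, c in region_classes.items()
        if c == tissue_class and r in table.columns
    ]
    if not regions:
        raise ValueError(f"no regions of class {tissue_class!r} in table")
    df = table[["age_years", "sex", "site"]].copy()
    df["value"] = table[regions].sum(axis=1, skipna=False)
    df = df.dropna(subset=["value"])

    terms = []
    for term, formula_term in (
        ("age", "age_years"),
        ("sex", "C(sex)"),
        ("site", "C(site)"),
    ):
        if df[{"age": "age_years", "sex": "sex", "site": "site"}[term]].nunique() < 2:
            warnings.warn(f"constant predictor {term!r}; its share set to 0",
                          stacklevel=2)
        else:
            terms.append((term, formula_term))

    total_ss = float(((df["value"] - df["value"].mean()) ** 2).sum())
    shares = {"age": 0.0, "sex": 0.0, "site": 0.0}
    prev_rss = total_ss
    rhs: list[str] = []
    for term, formula_term in terms:
        rhs.append(formula_term)
        fit = smf.ols("value ~ " + " + ".join(rhs), data=df).fit()
        rss = float(fit.ssr)
        shares[term] = 100.0 * (prev_rss - rss) / total_ss
        prev_rss = rss
    return VarianceDecomposition(
        tissue_class=tissue_class,
        age_pct=max(shares["age"], 0.0),
        sex_pct=max(shares["sex"], 0.0),
        site_pct=max(shares["site"], 0.0),
    )
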