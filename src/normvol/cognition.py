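"""Neuropsychological battery reduction and group outcome comparison.

A comprehensive cognitive battery produces far more measures than a
small clinical sample can support in group comparisons.  The two-step
reduction used here: (1) exploratory factor analysis (maximum-likelihood
extraction, varimax rotation) of the standardized scores, reporting
loadings with a cut-off (default 0.3) below which loadings are zeroed;
(2) for each factor, the measure attaining the highest absolute loading
is selected as that cognitive domain's representative for group
analysis.  The comparison stage runs one-way ANOVA (three groups:
control, TBI low volume, TBI normal volume) or two-sample t-tests per
selected measure, with pairwise follow-ups and Benjamini–Hochberg FDR
across the measure family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import FactorAnalysis

from .classify import fdr_adjust

__all__ = [
    "ReductionResult",
    "reduce_battery",
    "compare_groups",
    "eigenvalue_scree",
]

META_COLUMNS = ("subject_id", "group")


def _measure_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass
class ReductionResult:
    """EFA loadings and the selected representative measure per factor."""

    loadings: pd.DataFrame          # measure x factor, full
    retained: pd.DataFrame          # |loading| < cutoff zeroed
    selected: dict[str, str]        # factor -> measure
    explained_variance: float       # fraction of total variance
    cutoff: float
    ties: list[str] = field(default_factory=list)


def eigenvalue_scree(table: pd.DataFrame) -> np.ndarray:
    """Eigenvalues of the measure correlation matrix, descending.

    Helper for choosing the factor count (scree / eigenvalue->=1 rules);
    it informs the user's choice rather than making it.
    """
    x = table[_measure_cols(table)].to_numpy(dtype=np.float64)
    corr = np.corrcoef(x, rowvar=False)
    return np.sort(np.linalg.eigvalsh(corr))[::-1]


def reduce_battery(
    table: pd.DataFrame,
    n_factors: int = 5,
    cutoff: float = 0.3,
    rotation: str = "varimax",
) -> ReductionResult:
    """Two-step battery reduction: EFA then highest-loading selection.

    Scores are standardized per measure before the factor analysis so
    loadings are on the correlation scale.  Loadings below ``cutoff`` in
    absolute value are zeroed in the retained matrix; each factor's
    representative is its max-|loading| retained measure, ties broken by
    measure-name order (recorded in ``ties``).
    """
    measures = _measure_cols(table)
    if n_factors > len(measures):
        raise ValueError(
            f"n_factors={n_factors} exceeds the {len(measures)} measures"
        )
    x = table[measures].to_numpy(dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("scores must be finite")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [m for m, s in zip(measures, sd) if s == 0]
        raise ValueError(
            f"constant measure columns make the correlation matrix singular: "
            f"{bad}; prune them before reduction"
        )
    if x.shape[0] <= len(measures):
        warnings.warn(
            f"only {x.shape[0]} subjects for {len(measures)} measures; "
            "loadings will be unstable",
            stacklevel=2,
        )
    z = (x - x.mean(axis=0)) / sd

    fa = FactorAnalysis(n_components=n_factors, rotation=rotation, random_state=0)
    fa.fit(z)
    lam = fa.components_.T  # measure x factor
    # orient each factor so its dominant loading is positive (sign is
    # arbitrary in EFA; a fixed orientation makes reports reproducible)
    for k in range(lam.shape[1]):
        if lam[np.argmax(np.abs(lam[:, k])), k] < 0:
            lam[:, k] = -lam[:, k]
    factors = [f"factor{k + 1}" for k in range(n_factors)]
    loadings = pd.DataFrame(lam, index=measures, columns=factors)
    retained = loadings.where(loadings.abs() >= cutoff, 0.0)

    selected: dict[str, str] = {}
    ties: list[str] = []
    for f in factors:
        col = retained[f].abs()
        if (col == 0).all():
            raise ValueError(
                f"no loading on {f} survives the {cutoff} cut-off; "
                "lower the cut-off or drop the factor"
            )
        best = col.max()
        candidates = sorted(col.index[col == best])
        if len(candidates) > 1:
            ties.append(
                f"{f}: tie between {candidates}, keeping {candidates[0]}"
            )
        selected[f] = candidates[0]

    communality = float((lam**2).sum())
    explained = communality / len(measures)
    return ReductionResult(
        loadings=loadings,
        retained=retained,
        selected=selected,
        explained_variance=explained,
        cutoff=cutoff,
        ties=ties,
    )


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return np.nan
    return float((a.mean() - b.mean()) / pooled)


def compare_groups(
    table: pd.DataFrame,
    measures: list[str] | None = None,
    design: str = "3-group",
) -> pd.DataFrame:
    """Per-measure group comparison with FDR over the measure family.

    ``design="3-group"``: one-way ANOVA (F, eta² effect size) plus all
    pairwise Welch-free two-sample t-tests as follow-ups.
    ``design="2-group"``: two-sample t-test (Cohen's d).  Omnibus
    q-values are BH-adjusted across measures; pairwise q-values across
    all pairwise tests.  Returns a long table with columns measure,
    test, statistic, p, q, effect_size.
    """
    if design not in ("3-group", "2-group"):
        raise ValueError(f"unknown design {design!r}")
    measures = measures if measures is not None else _measure_cols(table)
    groups = sorted(table["group"].unique())
    expected = 3 if design == "3-group" else 2
    if len(groups) != expected:
        raise ValueError(
            f"{design} design needs {expected} groups, found {groups}"
        )
    sizes = table.groupby("group").size()
    if (sizes < 2).any():
        raise ValueError(f"every group needs >= 2 subjects, got {dict(sizes)}")

    omnibus_rows, pairwise_rows = [], []
    for m in measures:
        samples = [
            table.loc[table["group"] == g, m].to_numpy(dtype=np.float64)
            for g in groups
        ]
        if all(s.var(ddof=1) == 0 for s in samples):
            raise ValueError(
                f"measure {m!r} has zero variance in every group; "
                "the test statistic is undefined"
            )
        if design == "3-group":
            f_stat, p = sps.f_oneway(*samples)
            grand = np.concatenate(samples)
            ss_total = ((grand - grand.mean()) ** 2).sum()
            ss_between = sum(
                len(s) * (s.mean() - grand.mean()) ** 2 for s in samples
            )
            eta2 = float(ss_between / ss_total) if ss_total > 0 else np.nan
            omnibus_rows.append(
                {
                    "measure": m,
                    "test": "anova",
                    "statistic": float(f_stat),
                    "p": float(p),
                    "effect_size": eta2,
                }
            )
            for (ga, a), (gb, b) in combinations(zip(groups, samples), 2):
                t, tp = sps.ttest_ind(a, b)
                pairwise_rows.append(
                    {
                        "measure": m,
                        "test": f"t:{ga}-vs-{gb}",
                        "statistic": float(t),
                        "p": float(tp),
                        "effect_size": _cohens_d(a, b),
                    }
                )
        else:
            a, b = samples
            t, tp = sps.ttest_ind(a, b)
            omnibus_rows.append(
                {
                    "measure": m,
                    "test": f"t:{groups[0]}-vs-{groups[1]}",
                    "statistic": float(t),
                    "p": float(tp),
                    "effect_size": _cohens_d(a, b),
                }
            )

    omnibus = pd.DataFrame(omnibus_rows)
    omnibus["q"] = fdr_adjust(omnibus["p"].to_numpy())
    frames = [omnibus]
    if pairwise_rows:
        pairwise = pd.DataFrame(pairwise_rows)
        pairwise["q"] = fdr_adjust(pairwise["p"].to_numpy())
        frames.append(pairwise)
    out = pd.concat(frames, ignore_index=True)
    return out[["measure", "test", "statistic", "p", "q", "effect_size"]]
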