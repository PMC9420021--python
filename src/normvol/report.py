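"""Per-subject Markdown reports with a regional deviation panel."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import ClassificationResult
from .norms import AgeCurve, AgeNorms

__all__ = ["render_report"]


def _zscore_panel(result: ClassificationResult, path: Path) -> None:
    t = result.table.dropna(subset=["z"])
    if t.empty:
        return
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(t) + 1.2))
    colors = ["#c0392b" if f else "#5b7fa6" for f in t["flag"]]
    ax.barh(t["region"], t["z"], color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Z vs age-matched norms")
    ax.set_title("Regional deviation (red = flagged low volume)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_report(
    result: ClassificationResult,
    norms: AgeNorms,
    curves: dict[str, AgeCurve] | None,
    subject: pd.Series | dict,
    out_dir: str | Path,
    plot: bool = True,
) -> Path:
    """Write ``<subject_id>.md`` (+ PNG panel) summarizing one subject.

    The report shows demographics, the per-region Z/p/q/flag table
    against the age-matched norms (missing regions annotated
    untestable), the norms provenance (standard or lesion-matched) and,
    when curves are given, each region's fitted annual percent rate.
    """
    subject = pd.Series(subject)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = str(subject.get("subject_id", "subject"))
    md = out_dir / f"{sid}.md"

    lines = [f"# Volume report — {sid}", ""]
    age = float(subject.get("age_years", np.nan))
    lines += [
        f"- age: {age:.1f} y (norm bin {int(np.floor(age))})"
        if np.isfinite(age)
        else "- age: unknown",
        f"- sex: {subject.get('sex', '?')}   group: {subject.get('group', '?')}",
        f"- classification: **{result.label}** (alpha={result.alpha})",
        f"- norms: {result.provenance.get('norms', 'standard')}",
        "",
        "| region | Z | p | q | flag | note |",
        "|---|---|---|---|---|---|",
    ]
    for _, row in result.table.iterrows():
        if row["excluded_reason"]:
            lines.append(
                f"| {row['region']} | – | – | – | – | "
                f"untestable: {row['excluded_reason']} |"
            )
        else:
            mark = "LOW" if row["flag"] else ""
            lines.append(
                f"| {row['region']} | {row['z']:+.2f} | {row['p']:.4g} "
                f"| {row['q']:.4g} | {mark} | |"
            )
    if curves:
        lines += ["", "## Developmental context (population age curves)", ""]
        for region, c in sorted(curves.items()):
            lines.append(f"- {region}: APR {c.apr:+.2f} %/yr (n={c.n})")
    if plot:
        png = out_dir / f"{sid}_zpanel.png"
        _zscore_panel(result, png)
        if png.exists():
            lines += ["", f"![z panel]({png.name})"]
    md.write_text("\n".join(lines) + "\n")
    return md
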