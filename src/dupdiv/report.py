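"""Static report generation from a completed run's output TSVs.

The report echoes the three analysis views: windowed pi-ratio tracks with
dashed top-1%/top-5% threshold lines and gene-position markers, per-gene
expression-vs-trait scatter plots with the fitted line, and a bar chart of
LMG variance contributions.  Everything is regenerated from the TSVs only.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .sweep import outlier_thresholds

__all__ = ["render_report"]


def _pi_ratio_figure(windows: pd.DataFrame, genes: pd.DataFrame | None, path: Path) -> None:
    fig, axes = plt.subplots(2, 1, figsize=(9, 5), sharex=True)
    mids = (windows["start"] + windows["end"]) / 2.0
    for ax, col, title in zip(
        axes, ("ratio_dom", "ratio_imp"),
        ("domestication contrast (wild vs landrace)",
         "improvement contrast (landrace vs improved)"),
    ):
        ev = windows["evaluated"].astype(bool)
        ax.plot(mids[ev], windows.loc[ev, col], lw=0.8, color="0.3")
        values = windows.loc[ev, col]
        if len(values) >= 20:
            thr = outlier_thresholds(values, (0.95, 0.99))
            ax.axhline(thr.cutoffs[0.99], color="red", ls="--", lw=0.8, label="top 1%")
            ax.axhline(thr.cutoffs[0.95], color="blue", ls="--", lw=0.8, label="top 5%")
        if genes is not None:
            for _, g in genes.iterrows():
                ax.axvline((g["start"] + g["end"]) / 2.0, color="0.6", lw=1.0)
        ax.set_ylabel("pi ratio")
        ax.set_title(title, fontsize=9)
        ax.legend(fontsize=7, loc="upper right")
    axes[-1].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _expression_figure(traits: pd.DataFrame, genes: list[str], trait_col: str, path: Path) -> None:
    means = traits.groupby("cultivar")[[trait_col, *genes]].mean()
    fig, axes = plt.subplots(1, len(genes), figsize=(3.2 * len(genes), 3.2), sharey=True)
    if len(genes) == 1:
        axes = [axes]
    for ax, g in zip(axes, genes):
        x = means[g].to_numpy()
        y = means[trait_col].to_numpy()
        ax.scatter(x, y, s=12)
        if np.ptp(x) > 0:
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, a + b * xs, color="red", lw=1)
        ax.set_xlabel(f"{g} expression")
    axes[0].set_ylabel(trait_col)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _contribution_figure(contrib: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(contrib["gene"], contrib["contribution_pct"], color="0.4")
    ax.set_ylabel("trait variance explained (%)")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(outdir: str | Path) -> dict[str, str]:
    """Render report.md (+ PNG figures) from a run directory's TSVs."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {outdir}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    written: dict[str, str] = {}
    lines = ["# dupdiv run report", "",
             f"Software version: {manifest.get('version', '?')}  ",
             f"Global seed: {manifest.get('seed', '?')}", ""]

    windows_path = outdir / "window_stats.tsv"
    if windows_path.exists():
        windows = pd.read_csv(windows_path, sep="\t")
        lines.append("## Selective-sweep scan")
        lines.append("")
        evaluated = windows[windows["evaluated"].astype(bool)]
        if evaluated.empty:
            lines.append("No evaluated windows (all windows below the SNP-count cutoff).")
        else:
            lines.append(f"{len(windows)} windows ({len(evaluated)} evaluated). "
                         f"Mean pi per population:")
            lines.append("")
            for col in [c for c in windows.columns if c.startswith("pi_")]:
                lines.append(f"- {col}: {evaluated[col].mean():.6f}")
            genes_path = outdir / "genes.bed"
            genes_df = None
            if genes_path.exists():
                genes_df = pd.read_csv(genes_path, sep="\t", header=None,
                                       names=["chrom", "start", "end", "name"])
            fig = outdir / "pi_ratio_tracks.png"
            _pi_ratio_figure(windows, genes_df, fig)
            written["fig_pi_ratio"] = str(fig)
            lines.append("")
            lines.append("![pi-ratio tracks](pi_ratio_tracks.png)")
        calls_path = outdir / "sweep_calls.tsv"
        if calls_path.exists():
            calls = pd.read_csv(calls_path, sep="\t")
            if not calls.empty:
                lines.append("")
                lines.append("### Gene classifications")
                lines.append("")
                lines.append(calls.to_markdown(index=False))
        lines.append("")

    kaks_path = outdir / "kaks.tsv"
    if kaks_path.exists():
        lines.append("## Ka/Ks estimate")
        lines.append("")
        lines.append(pd.read_csv(kaks_path, sep="\t").to_markdown(index=False))
        lines.append("")
    dating_path = outdir / "dating.tsv"
    if dating_path.exists():
        lines.append("## Duplication dating (T = Ks / 2 lambda)")
        lines.append("")
        lines.append(pd.read_csv(dating_path, sep="\t").to_markdown(index=False))
        lines.append("")

    corr_path = outdir / "correlations.tsv"
    if corr_path.exists():
        lines.append("## Expression-trait correlations")
        lines.append("")
        corrs = pd.read_csv(corr_path, sep="\t")
        lines.append(corrs.to_markdown(index=False))
        traits_path = outdir / "traits.tsv"
        if traits_path.exists():
            traits = pd.read_csv(traits_path, sep="\t")
            genes = [g for g in corrs["gene"] if g in traits.columns]
            fig = outdir / "expression_scatter.png"
            _expression_figure(traits, genes, "trait", fig)
            written["fig_expression"] = str(fig)
            lines.append("")
            lines.append("![expression scatter](expression_scatter.png)")
        lines.append("")
    contrib_path = outdir / "contributions.tsv"
    if contrib_path.exists():
        lines.append("## Variance contributions (LMG)")
        lines.append("")
        contrib = pd.read_csv(contrib_path, sep="\t")
        lines.append(contrib.to_markdown(index=False))
        fig = outdir / "contributions.png"
        _contribution_figure(contrib, fig)
        written["fig_contributions"] = str(fig)
        lines.append("")
        lines.append("![contributions](contributions.png)")
        lines.append("")

    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines) + "\n")
    written["report"] = str(report_path)
    return written
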