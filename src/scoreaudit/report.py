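"""Static report rendering: figures (SVG) and a navigable markdown index
over a completed audit bundle.

Each paired-curve figure has the two groups' curves with shaded 95%
bands in an upper panel and their difference in a lower sub-panel;
CDF figures use a log-scaled x-axis. Decomposition figures plot each
admission type's overall share (A) against its over-representation among
low-score events (B - A) with vertical interval bars and a y = 0
reference line. Missing bundle members render as placeholders with a
warning, never as a hard failure.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .runner import ReportBundle

logger = logging.getLogger(__name__)

_SVG_KW = dict(format="svg", metadata={"Date": None})  # reproducible output


def _paired_curve_figure(
    files: list[Path], diff_file: Path | None, out_path: Path,
    title: str, *, logx: bool = False, ylabel: str = "",
) -> None:
    n_rows = 2 if diff_file is not None and diff_file.exists() else 1
    fig, axes = plt.subplots(
        n_rows, 1, figsize=(5.5, 4.2 if n_rows == 2 else 3.0),
        sharex=True, height_ratios=[2, 1] if n_rows == 2 else [1],
    )
    axes = [axes] if n_rows == 1 else list(axes)
    for f in files:
        df = pd.read_csv(f)
        lab = str(df["group"].iloc[0]) if "group" in df else f.stem
        axes[0].plot(df["cutoff"], df["estimate"], label=lab, lw=1.2)
        axes[0].fill_between(df["cutoff"], df["lower"], df["upper"], alpha=0.25)
    axes[0].set_ylabel(ylabel)
    axes[0].set_title(title, fontsize=10)
    axes[0].legend(fontsize=8)
    if n_rows == 2:
        df = pd.read_csv(diff_file)
        axes[1].plot(df["cutoff"], df["estimate"], color="k", lw=1.0)
        axes[1].fill_between(
            df["cutoff"], df["lower"], df["upper"], alpha=0.25, color="k"
        )
        axes[1].axhline(0.0, color="r", ls="--", lw=0.7)
        axes[1].set_ylabel("difference")
    axes[-1].set_xlabel("score cutoff")
    if logx:
        for ax in axes:
            ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(out_path, **_SVG_KW)
    plt.close(fig)


def _decomposition_figure(file: Path, out_path: Path, title: str) -> None:
    df = pd.read_csv(file)
    kinds = df["event_kind"].unique()
    fig, axes = plt.subplots(
        len(kinds), 1, figsize=(5.5, 3.0 * len(kinds)), squeeze=False
    )
    for ax, kind in zip(axes[:, 0], kinds):
        sub = df[df["event_kind"] == kind]
        ax.axhline(0.0, color="k", lw=0.7)
        ax.vlines(sub["A"], sub["lower"], sub["upper"], color="tab:blue", lw=1.2)
        ax.scatter(sub["A"], sub["B_minus_A"], s=12, color="tab:blue")
        for _, row in sub.iterrows():
            if abs(row["B_minus_A"]) > 0.02:
                ax.annotate(
                    row["category"], (row["A"], row["B_minus_A"]),
                    fontsize=7, xytext=(2, 2), textcoords="offset points",
                )
        ax.set_title(f"{title} — {kind}", fontsize=9)
        ax.set_xlabel("share of all events (A)")
        ax.set_ylabel("B − A")
    fig.tight_layout()
    fig.savefig(out_path, **_SVG_KW)
    plt.close(fig)


def render_report(bundle: ReportBundle) -> Path:
    """Render every figure and a markdown index; returns the index path."""
    out = bundle.out_dir
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    lines = ["# Risk-score audit report", ""]
    comparisons = sorted(
        p.name for p in out.iterdir() if p.is_dir() and p.name != "figures"
    )
    for comp in comparisons:
        cdir = out / comp
        lines += [f"## Comparison: {comp}", ""]
        menus = [
            ("cdf", "cdf_difference.csv", "Score CDF (demographic parity)",
             True, "P(score < c)"),
            ("counterfactual_cdf", None, "Counterfactual score CDF",
             True, "P(score < c)"),
            ("calibration", None, "Calibration", False, "observed event rate"),
            ("for", "for_difference.csv", "False omission rate", True, "FOR"),
            ("for_adjusted", "for_adjusted_difference.csv",
             "FOR (standardised)", True, "adjusted FOR"),
            ("fdr", "fdr_difference.csv", "False discovery rate", True, "FDR"),
            ("fdr_adjusted", "fdr_adjusted_difference.csv",
             "FDR (standardised)", True, "adjusted FDR"),
        ]
        for prefix, diff_name, title, logx, ylabel in menus:
            files = sorted(
                f for f in cdir.glob(f"{prefix}_*.csv")
                if "difference" not in f.name
                and not (prefix in ("cdf", "for", "fdr")
                         and "adjusted" in f.name)
                and not (prefix == "cdf" and "counterfactual" in f.name)
            )
            fig_path = fig_dir / f"{comp}_{prefix}.svg"
            if not files:
                logger.warning("missing bundle member: %s/%s_*", comp, prefix)
                lines.append(f"*Missing: {title}*\n")
                continue
            diff = cdir / diff_name if diff_name else None
            _paired_curve_figure(
                files, diff, fig_path, f"{comp}: {title}", logx=logx, ylabel=ylabel
            )
            lines.append(f"![{comp} {title}](figures/{fig_path.name})\n")
        dec_files = sorted(cdir.glob("decomposition_*.csv"))
        if not dec_files:
            logger.warning("missing bundle member: %s/decomposition_*", comp)
            lines.append("*Missing: false-negative decomposition*\n")
        for f in dec_files:
            lab = f.stem.replace("decomposition_", "")
            fig_path = fig_dir / f"{comp}_decomposition_{lab}.svg"
            _decomposition_figure(f, fig_path, f"{comp}: {lab}")
            lines.append(f"![{comp} decomposition {lab}](figures/{fig_path.name})\n")
    index = out / "report.md"
    index.write_text("\n".join(lines))
    return index
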