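"""Diagnostic figures for a completed analysis results directory."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats


def _load(results_dir: Path, name: str) -> pd.DataFrame:
    path = results_dir / name
    if not path.exists():
        raise FileNotFoundError(f"results bundle incomplete: missing {name}")
    return pd.read_csv(path, sep="\t")


def run_report(results_dir: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Render the three diagnostic figures from a results directory.

    1. niche-position histogram with the fitted bimodal (real) and
       unimodal (null) densities;
    2. width-vs-position scatter with quantile curves and the null band;
    3. residual-width boxplots and the extremity-residual scatter.
    """
    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_path = results_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError("results bundle incomplete: missing summary.json")
    summary = json.loads(summary_path.read_text())
    estimates = _load(results_dir, "niche_estimates.tsv")
    band = _load(results_dir, "null_band.tsv")
    fits = _load(results_dir, "quantreg_fits.tsv")
    written = []

    # 1: position histogram + fitted densities
    mod = summary["modality"]
    pos = estimates["position"].to_numpy()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    n_bins = int(np.ceil(np.log2(pos.size))) + 1
    ax.hist(pos, bins=n_bins, density=True, color="steelblue", alpha=0.6, label="species")
    xs = np.linspace(pos.min() - 0.05, pos.max() + 0.05, 400)
    w = mod["bimodal_weights"]
    ax.plot(
        xs,
        w[0] * stats.norm.pdf(xs, mod["bimodal_means"][0], mod["bimodal_sds"][0])
        + w[1] * stats.norm.pdf(xs, mod["bimodal_means"][1], mod["bimodal_sds"][1]),
        "r-", label="bimodal fit (real)",
    )
    ax.plot(
        xs, stats.norm.pdf(xs, mod["unimodal_mean"], mod["unimodal_sd"]),
        "g--", label="unimodal fit",
    )
    ax.set_xlabel("niche position (log10 N:P)")
    ax.set_ylabel("density")
    ax.legend()
    path = out_dir / "fig_niche_positions.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    # 2: trade-off scatter + quantile curves + null band
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.scatter(estimates["position"], estimates["width"], s=12, color="steelblue", alpha=0.6)
    grid = band["position"].to_numpy()
    for row in fits.itertuples():
        curve = row.intercept + row.linear * grid + row.quadratic * grid**2
        ax.plot(grid, curve, "r-", lw=1, alpha=0.8)
        ax.annotate(f"{row.tau:g}", (grid[-1], curve[-1]), fontsize=7, color="darkred")
    ax.fill_between(grid, band["null_lower"], band["null_upper"], color="grey", alpha=0.4,
                    label="null 95% band")
    ax.plot(grid, band["null_mean"], "g--", label="null mean")
    ax.set_xlabel("niche position (log10 N:P)")
    ax.set_ylabel("niche width (2 SD of log10 N:P)")
    ax.legend()
    path = out_dir / "fig_tradeoff.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    # 3: residual widths by endangered status + extremity scatter
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.5))
    groups = [
        estimates.loc[~estimates["endangered"], "residual_width"],
        estimates.loc[estimates["endangered"], "residual_width"],
    ]
    ax1.boxplot(groups, tick_labels=["non-endangered", "endangered"])
    ax1.axhline(0, color="grey", lw=0.8)
    ax1.set_ylabel("residual niche width")
    for flag, color, label in ((False, "steelblue", "non-endangered"), (True, "firebrick", "endangered")):
        sub = estimates[estimates["endangered"] == flag]
        ax2.scatter(sub["extremity"], sub["residual_width"], s=12, color=color, alpha=0.7,
                    label=label)
    ax2.axhline(0, color="grey", lw=0.8)
    ax2.set_xlabel("niche position extremity")
    ax2.set_ylabel("residual niche width")
    ax2.legend()
    path = out_dir / "fig_endangered.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
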