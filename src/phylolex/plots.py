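"""Diagnostic figures: coverage, ECDF difference, reliability, adequacy."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diagnostics import ECDFResult, ReliabilityResult, hpd_interval
from .pipeline import SBCResult


def plot_coverage(result: SBCResult, path: str | Path, mass: float = 0.95) -> None:
    """True value vs HPD interval per replicate, one panel per parameter."""
    params = result.config.parameter_names()
    ncol = 4
    nrow = int(np.ceil(len(params) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.8 * nrow))
    for ax, p in zip(np.ravel(axes), params):
        hits = 0
        for rep in result.replicates:
            t = rep.true_values[p]
            lo, hi = hpd_interval(rep.draws[p].to_numpy(), mass)
            ok = lo <= t <= hi
            hits += ok
            ax.plot([t, t], [lo, hi], color="tab:blue" if ok else "tab:red", lw=1)
        lims = ax.get_xlim()
        ax.plot(lims, lims, ls=":", color="grey")
        ax.set_title(f"{p} ({100*hits/len(result.replicates):.0f}%)", fontsize=9)
    for ax in np.ravel(axes)[len(params):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ecdf_differences(
    ecdfs: dict[str, ECDFResult], path: str | Path
) -> None:
    ncol = 4
    nrow = int(np.ceil(len(ecdfs) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow))
    for ax, (p, r) in zip(np.ravel(axes), ecdfs.items()):
        ax.fill_between(r.grid, r.lower, r.upper, color="lightblue", alpha=0.6)
        ax.plot(r.grid, r.diff, color="tab:blue" if r.passed else "tab:red")
        ax.axhline(0, ls=":", color="grey", lw=0.8)
        ax.set_title(f"{p} ({'pass' if r.passed else 'FAIL'})", fontsize=9)
    for ax in np.ravel(axes)[len(ecdfs):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_reliability(rel: ReliabilityResult, path: str | Path) -> None:
    fig, (ax, axh) = plt.subplots(
        2, 1, figsize=(4.5, 5.5), height_ratios=[3, 1], sharex=True
    )
    ax.fill_between(rel.support_grid, rel.lower, rel.upper, color="plum", alpha=0.5)
    ax.step(rel.support_grid, rel.cep, color="purple", where="mid")
    ax.plot([0, 1], [0, 1], ls=":", color="grey")
    ax.set_ylabel("conditional event probability")
    centers = (rel.bin_edges[:-1] + rel.bin_edges[1:]) / 2
    axh.bar(centers, rel.bin_counts, width=np.diff(rel.bin_edges) * 0.9, color="grey")
    axh.set_xlabel("posterior clade probability")
    axh.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_adequacy(
    predictive: pd.DataFrame, report: pd.DataFrame, path: str | Path
) -> None:
    metrics = report["metric"].tolist()
    ncol = 4
    nrow = int(np.ceil(len(metrics) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow))
    for ax, (_, row) in zip(np.ravel(axes), report.iterrows()):
        ax.hist(predictive[row["metric"]], bins=30, color="tab:blue", alpha=0.7)
        ax.axvline(row["observed"], color="red")
        ax.set_title(f"{row['metric']}\n$p_B$={row['p_B']:.3f}", fontsize=8)
    for ax in np.ravel(axes)[len(metrics):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
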