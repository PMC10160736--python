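"""Mean-variance and MDS diagnostic plots.

Matplotlib is used with the Agg backend so plotting is a pure side effect
of the numerical pipeline.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pseudobulk import LogCPM
from .voom_by_group import GroupTrendSet
from .voom_core import MeanVarianceTrend

__all__ = ["plot_mean_variance", "mds_distances", "plot_mds"]


def _plot_one(ax, trend: MeanVarianceTrend, label: str, color=None) -> None:
    ax.scatter(trend.train_x, trend.train_y, s=2, alpha=0.2, color="black")
    ax.plot(trend.fit_x, trend.fit_y, color=color or "red", lw=2, label=label)
    ax.set_xlabel("average log2 count")
    ax.set_ylabel(r"sqrt(residual SD)")


def plot_mean_variance(
    trends: GroupTrendSet | MeanVarianceTrend,
    out: str | Path,
    mode: str = "combine",
) -> list:
    """Write mean-variance plot file(s); returns the paths written.

    ``separate``: one panel per group (its own scatter and curve).
    ``combine``: all group curves overlaid, legend annotated with each
    group's common BCV to 3 decimals.
    """
    out = Path(out)
    if isinstance(trends, MeanVarianceTrend):
        fig, ax = plt.subplots(figsize=(5, 4))
        _plot_one(ax, trends, "voom trend")
        ax.legend()
        fig.savefig(out, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return [out]
    items = [
        (g, trends.trends[g] if not trends.dynamic.get(g) else trends.overall)
        for g in trends.dynamic
    ]
    if not items:
        raise ValueError("no trends to plot")
    if mode == "separate":
        paths = []
        for g, tr in items:
            fig, ax = plt.subplots(figsize=(5, 4))
            label = f"{g} (BCV {trends.group_bcv.get(g, float('nan')):.3f})"
            _plot_one(ax, tr, label)
            ax.set_title(label + ("  [overall trend]" if trends.dynamic.get(g) else ""))
            p = out.with_name(f"{out.stem}_{g}{out.suffix}")
            fig.savefig(p, dpi=120, bbox_inches="tight")
            plt.close(fig)
            paths.append(p)
        return paths
    if mode == "combine":
        fig, ax = plt.subplots(figsize=(5.5, 4))
        colors = plt.cm.tab10(np.linspace(0, 1, 10))
        for k, (g, tr) in enumerate(items):
            label = f"{g} (BCV {trends.group_bcv.get(g, float('nan')):.3f})"
            ax.plot(tr.fit_x, tr.fit_y, lw=2, color=colors[k % 10], label=label)
        ax.set_xlabel("average log2 count")
        ax.set_ylabel(r"sqrt(residual SD)")
        ax.legend(fontsize=8)
        fig.savefig(out, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return [out]
    raise ValueError(f"unknown plot mode {mode!r}")


def mds_distances(E: np.ndarray, top: int = 500) -> np.ndarray:
    """Pairwise sample distances: root-mean-square of the ``top`` largest
    absolute log-FCs between each pair of samples (leading-logFC)."""
    n = E.shape[1]
    top = min(top, E.shape[0])
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = np.abs(E[:, i] - E[:, j])
        sel = np.partition(d, len(d) - top)[len(d) - top :]
        D[i, j] = D[j, i] = np.sqrt(np.mean(sel**2))
    return D


def plot_mds(
    lc: LogCPM, group: np.ndarray, out: str | Path, top: int = 500
) -> Path:
    """Classical MDS of leading-logFC distances, samples colored by group."""
    E = lc.values
    n = E.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for a 2-D MDS plot")
    D = mds_distances(E, top=top)
    # classical (Torgerson) scaling of the squared distances
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:2]
    coords = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    fig, ax = plt.subplots(figsize=(5, 4.5))
    group = np.asarray(group)
    for k, lv in enumerate(pd.unique(group)):
        m = group == lv
        ax.scatter(coords[m, 0], coords[m, 1], label=str(lv))
        for s, (x, y) in zip(np.asarray(lc.sample_ids)[m], coords[m]):
            ax.annotate(str(s), (x, y), fontsize=6)
    ax.set_xlabel("MDS dim 1 (leading logFC)")
    ax.set_ylabel("MDS dim 2 (leading logFC)")
    ax.legend(fontsize=8)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(out)
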