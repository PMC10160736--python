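"""voomByGroup: group-specific mean-variance trends and precision weights.

Rather than one global mean-variance curve, the expression matrix and the
design are subset to each experimental group and a separate LOWESS trend is
fitted per group, so groups with more biological variation get flatter,
higher curves and correspondingly smaller precision weights. The per-group
weights w_gic are then reassembled into a single gene-by-sample matrix
w#_gi that replaces the plain voom weights in the weighted-LS pipeline.

Groups with too few samples to support their own trend can be flagged
``dynamic``, in which case the overall voom trend (and weights) are used
for their columns instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .bcv import estimate_common_dispersion
from .pseudobulk import PseudoBulkCounts, log_cpm
from .voom_core import (
    DesignMatrix,
    MeanVarianceTrend,
    WeightedLogExpression,
    _avg_log_count,
    _fitted_log_count,
    fit_gene_lms,
    fit_trend,
    voom,
)

__all__ = ["GroupTrendSet", "voom_by_group", "combine_group_weights"]


@dataclass
class GroupTrendSet:
    """Per-group mean-variance trends plus the overall fallback trend."""

    trends: dict  # group -> MeanVarianceTrend (own trend, non-dynamic groups)
    dynamic: dict  # group -> bool
    overall: MeanVarianceTrend
    group_bcv: dict  # group -> common BCV


def _subset_design(design: DesignMatrix, rows: np.ndarray, n_sub: int) -> DesignMatrix:
    """Design for one group's samples: drop all-zero columns, fall back to
    intercept-only when rank-deficient or out of residual df."""
    Xs = design.X[rows]
    nonzero = ~np.all(Xs == 0, axis=0)
    Xs = Xs[:, nonzero]
    names = [nm for nm, keep in zip(design.column_names, nonzero) if keep]
    rank = np.linalg.matrix_rank(Xs) if Xs.size else 0
    if Xs.size == 0 or rank < Xs.shape[1] or n_sub - rank < 1:
        return DesignMatrix(np.ones((n_sub, 1)), ["(Intercept)"])
    return DesignMatrix(Xs, names)


def combine_group_weights(
    per_group: Mapping, group: np.ndarray
) -> np.ndarray:
    """Reassemble per-group weight submatrices into one gene-by-sample matrix.

    ``per_group[c]`` holds the columns for the samples of group c, in their
    original relative order. Coverage must be exact and disjoint.
    """
    group = np.asarray(group)
    levels = list(pd.unique(group))
    if set(per_group) != set(levels):
        raise ValueError("per_group keys must cover every group exactly")
    n = len(group)
    G = next(iter(per_group.values())).shape[0]
    out = np.empty((G, n))
    seen = np.zeros(n, dtype=bool)
    for lv in levels:
        cols = np.flatnonzero(group == lv)
        sub = np.asarray(per_group[lv])
        if sub.shape != (G, len(cols)):
            raise ValueError(f"submatrix for group {lv!r} has wrong shape")
        if seen[cols].any():
            raise ValueError("overlapping sample coverage")
        out[:, cols] = sub
        seen[cols] = True
    if not seen.all():
        raise ValueError("samples not covered by any group submatrix")
    return out


def voom_by_group(
    pb: PseudoBulkCounts,
    design: DesignMatrix,
    group: np.ndarray | None = None,
    dynamic: Optional[Mapping | list | np.ndarray] = None,
    span: float = 0.5,
) -> WeightedLogExpression:
    """Group-wise voom weights on a shared global normalization.

    log-CPM, library sizes and TMM factors come from the full data once;
    only the trend fitting is per group. ``dynamic`` may be a mapping
    group -> bool or a vector over groups (in first-appearance order); by
    default groups with <= 2 samples are dynamic.
    """
    if group is None:
        group = pb.group_labels
    group = np.asarray(group)
    if len(group) != pb.n_samples:
        raise ValueError("group must cover all samples")
    levels = list(pd.unique(group))

    if dynamic is None:
        dyn = {lv: int((group == lv).sum()) <= 2 for lv in levels}
    elif isinstance(dynamic, Mapping):
        dyn = {lv: bool(dynamic.get(lv, False)) for lv in levels}
    else:
        dynamic = list(dynamic)
        if len(dynamic) != len(levels):
            raise ValueError("dynamic vector must have one entry per group")
        dyn = dict(zip(levels, map(bool, dynamic)))

    for lv in levels:
        if not dyn[lv] and (group == lv).sum() < 2:
            raise ValueError(
                f"group {lv!r} has fewer than 2 samples; set dynamic=True for it"
            )

    overall = voom(pb, design, span=span)
    lc = log_cpm(pb)
    eff = lc.effective_lib_size

    per_group: dict = {}
    trends: dict = {}
    bcvs: dict = {}
    for lv in levels:
        cols = group == lv
        bcvs[lv] = (
            estimate_common_dispersion(pb, samples=cols).bcv
            if cols.sum() >= 2
            else float("nan")
        )
        if dyn[lv]:
            per_group[lv] = overall.weights[:, cols]
            continue
        if cols.all():
            # single group spanning all samples: subsetting is the identity,
            # reuse the full arrays so the result matches plain voom exactly
            sub_design, Es = design, lc.values
        else:
            sub_design = _subset_design(design, cols, int(cols.sum()))
            Es = lc.values[:, cols]
        _, sigma, _, fitted = fit_gene_lms(Es, sub_design)
        sx = _avg_log_count(Es.mean(axis=1), eff[cols])
        trend = fit_trend(sx, np.sqrt(sigma), span=span)
        lam = _fitted_log_count(fitted, eff[cols])
        per_group[lv] = trend(lam) ** -4.0
        trends[lv] = trend

    weights = combine_group_weights(per_group, group)
    return WeightedLogExpression(
        E=lc.values,
        weights=weights,
        design=design,
        gene_ids=pb.gene_ids,
        sample_ids=pb.sample_ids,
        method_tag="voomByGroup",
        effective_lib_size=eff,
        trend=overall.trend,
        group_trends=GroupTrendSet(
            trends=trends, dynamic=dyn, overall=overall.trend, group_bcv=bcvs
        ),
        group_bcv=bcvs,
    )
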