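"""Standard voom: gene-wise linear models, the mean-variance LOWESS trend,
and observation-level precision weights.

The method fits E(y_g) = X b_g per gene on log-CPM values y_g, plots the
square-root residual standard deviation sqrt(s_g) against each gene's
average log count, smooths that scatter with LOWESS, and converts the
predicted sqrt-SD at each observation's fitted log-count lambda-hat into a
precision weight w_gi = lo(lambda-hat_gi)^-4 for weighted least squares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .pseudobulk import PseudoBulkCounts, log_cpm

__all__ = [
    "DesignMatrix",
    "MeanVarianceTrend",
    "WeightedLogExpression",
    "fit_gene_lms",
    "fit_trend",
    "voom",
]

_SD_FLOOR = 1e-4


@dataclass
class DesignMatrix:
    """A full-column-rank sample-by-parameter design matrix."""

    X: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match design columns")
        if self.rank != self.X.shape[1]:
            raise ValueError("design matrix is not of full column rank")

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_groups(cls, group: np.ndarray, coding: str = "means") -> "DesignMatrix":
        """One-factor design. ``means`` gives one indicator column per group
        (R's ``~0+group``); ``treatment`` an intercept plus contrasts
        (R's ``~group``). Group level order follows first appearance."""
        group = np.asarray(group)
        levels = list(pd.unique(group))
        ind = np.column_stack([(group == lv).astype(float) for lv in levels])
        if coding == "means":
            return cls(ind, [f"group{lv}" for lv in levels])
        if coding == "treatment":
            X = np.column_stack([np.ones(len(group)), ind[:, 1:]])
            return cls(X, ["(Intercept)"] + [f"group{lv}" for lv in levels[1:]])
        raise ValueError(f"unknown coding: {coding}")


@dataclass
class MeanVarianceTrend:
    """LOWESS smooth of sqrt residual SD against average log-count.

    Prediction interpolates linearly between the fitted LOWESS points and is
    constant beyond the training range, with a small positive floor so
    weights stay finite.
    """

    train_x: np.ndarray
    train_y: np.ndarray
    fit_x: np.ndarray  # sorted x at which LOWESS was evaluated
    fit_y: np.ndarray
    span: float

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        pred = np.interp(np.asarray(x, dtype=float), self.fit_x, self.fit_y)
        return np.maximum(pred, _SD_FLOOR)


@dataclass
class WeightedLogExpression:
    """An EList-like bundle: log-CPM matrix E plus observation weights."""

    E: np.ndarray
    weights: np.ndarray
    design: DesignMatrix
    gene_ids: pd.Index
    sample_ids: pd.Index
    method_tag: str  # voom | voomQWB | voomByGroup
    effective_lib_size: np.ndarray
    trend: Optional[MeanVarianceTrend] = None
    sample_weights: Optional[np.ndarray] = None
    group_trends: Optional[dict] = None
    group_bcv: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.E.shape != self.weights.shape:
            raise ValueError("E and weights must have congruent shapes")
        if not np.isfinite(self.weights).all() or (self.weights <= 0).any():
            raise ValueError("weights must be finite and positive")

    def to_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        pd.DataFrame(self.E, index=self.gene_ids, columns=self.sample_ids).to_csv(
            prefix.with_suffix(".E.tsv"), sep="\t"
        )
        pd.DataFrame(self.weights, index=self.gene_ids, columns=self.sample_ids).to_csv(
            prefix.with_suffix(".weights.tsv"), sep="\t"
        )
        meta = {"method": self.method_tag}
        if self.sample_weights is not None:
            meta["sample_weights"] = dict(
                zip(map(str, self.sample_ids), self.sample_weights.tolist())
            )
        if self.group_bcv is not None:
            meta["group_bcv"] = {str(k): v for k, v in self.group_bcv.items()}
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def fit_gene_lms(
    E: np.ndarray, design: DesignMatrix, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Per-gene (weighted) least squares of each row of E on the design.

    Returns (coef, sigma, df_resid, fitted): coefficients (genes x params),
    residual SDs s_g on df = n - rank, and fitted values on the log-CPM
    scale. Vectorized over genes via stacked normal equations; with 10-20k
    genes and a handful of samples this is the profile that matters.
    """
    X = design.X
    n, p = X.shape
    df_resid = n - design.rank
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    E = np.asarray(E, dtype=float)
    # one code path for both cases so unit weights reproduce the unweighted
    # fit bit-for-bit
    W = np.ones_like(E) if weights is None else np.asarray(weights, dtype=float)
    if (W <= 0).any():
        raise ValueError("weights must be positive")
    xtwx = np.einsum("ip,gi,iq->gpq", X, W, X)
    xtwy = np.einsum("ip,gi->gp", X, W * E)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    fitted = beta @ X.T
    resid = E - fitted
    sigma = np.sqrt((W * resid**2).sum(axis=1) / df_resid)
    return beta, sigma, df_resid, fitted


def fit_trend(
    avg_log_count: np.ndarray, sqrt_sd: np.ndarray, span: float = 0.5
) -> MeanVarianceTrend:
    """LOWESS fit of sqrt residual SD on average log-count.

    Genes with (near-)zero residual SD are excluded from training; at least
    10 usable points are required.
    """
    x = np.asarray(avg_log_count, dtype=float)
    y = np.asarray(sqrt_sd, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (y > np.sqrt(_SD_FLOOR))
    if ok.sum() < 10:
        raise ValueError(
            "fewer than 10 usable mean-variance points; "
            "use the overall trend (dynamic) for this group"
        )
    xr = x[ok].max() - x[ok].min()
    out = _sm_lowess(y[ok], x[ok], frac=span, it=2, delta=0.01 * xr)
    fx, fy = out[:, 0], out[:, 1]
    fx, idx = np.unique(fx, return_index=True)
    return MeanVarianceTrend(
        train_x=x[ok], train_y=y[ok], fit_x=fx, fit_y=fy[idx], span=span
    )


def _avg_log_count(E_mean: np.ndarray, eff_lib: np.ndarray) -> np.ndarray:
    # mean log-CPM shifted back to the count scale at the geometric-mean library
    return E_mean + np.mean(np.log2(eff_lib + 1.0)) - np.log2(1e6)


def _fitted_log_count(fitted_logcpm: np.ndarray, eff_lib: np.ndarray) -> np.ndarray:
    return fitted_logcpm + np.log2(eff_lib + 1.0)[None, :] - np.log2(1e6)


def voom(
    pb: PseudoBulkCounts,
    design: DesignMatrix,
    span: float = 0.5,
    lm_sample_weights: np.ndarray | None = None,
) -> WeightedLogExpression:
    """The voom transform: log-CPM values with mean-variance precision weights.

    ``lm_sample_weights``, when given, are per-sample weights applied inside
    the gene-wise fits used to build the trend (the second pass of
    voomWithQualityWeights); they are not multiplied into the returned
    observation weights.
    """
    lc = log_cpm(pb)
    E = lc.values
    eff = lc.effective_lib_size
    w = None
    if lm_sample_weights is not None:
        w = np.ascontiguousarray(
            np.broadcast_to(np.asarray(lm_sample_weights)[None, :], E.shape)
        )
    _, sigma, _, fitted = fit_gene_lms(E, design, weights=w)
    sx = _avg_log_count(E.mean(axis=1), eff)
    trend = fit_trend(sx, np.sqrt(sigma), span=span)
    lam = _fitted_log_count(fitted, eff)
    weights = trend(lam) ** -4.0
    return WeightedLogExpression(
        E=E,
        weights=weights,
        design=design,
        gene_ids=pb.gene_ids,
        sample_ids=pb.sample_ids,
        method_tag="voom",
        effective_lib_size=eff,
        trend=trend,
    )
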