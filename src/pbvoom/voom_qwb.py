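"""voom with block-constrained sample quality weights (voomQWB).

Each sample i carries a variance inflation factor exp(gamma_i) in the
heteroscedastic model var(e_gi) = sigma_g^2 exp(gamma_i); its quality
weight is 1/exp(gamma_i). Constraining gamma to be constant within each
experimental group ("blocked" weights) turns the per-sample outlier
down-weighting of voomWithQualityWeights into a group-level variance
model: the combined observation weights are w*_gi = w_gi / exp(gamma_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .pseudobulk import PseudoBulkCounts
from .voom_core import DesignMatrix, WeightedLogExpression, fit_gene_lms, voom

__all__ = ["SampleWeightFit", "estimate_sample_weights", "voom_qwb"]


@dataclass
class SampleWeightFit:
    gamma_hat: np.ndarray  # per-sample log variance factors, mean-0 normalized
    sample_weight: np.ndarray  # 1 / exp(gamma_hat), geometric mean 1
    block: Optional[np.ndarray]  # group label per sample (None = per-sample)
    constrained: bool
    converged: bool
    n_iter: int


def _block_design(block: Optional[np.ndarray], n: int) -> tuple[np.ndarray, list]:
    if block is None:
        labels = list(range(n))
        member = np.eye(n, dtype=bool)
    else:
        block = np.asarray(block)
        labels = list(pd.unique(block))
        member = np.stack([block == lv for lv in labels])  # (n_blocks, n)
    return member, labels


def estimate_sample_weights(
    E: np.ndarray,
    design: DesignMatrix,
    obs_weights: np.ndarray | None = None,
    block: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> SampleWeightFit:
    """Estimate per-sample (or per-block) variance factors gamma.

    Iterates (a) gene-wise weighted fits under the current gamma and
    (b) a method-of-moments update of each block's gamma from the
    leverage-corrected standardized squared residuals pooled over genes,
    until max |delta gamma| < tol. With ``block`` given, gamma is one value
    per group; otherwise one per sample (standard quality weights).
    """
    X = design.X
    n, p = X.shape
    G = E.shape[0]
    if n <= design.rank + 1:
        raise ValueError("need at least 2 residual degrees of freedom overall")
    W0 = (
        np.ones_like(E, dtype=float)
        if obs_weights is None
        else np.asarray(obs_weights, dtype=float)
    )
    member, labels = _block_design(block, n)
    if block is not None:
        sizes = member.sum(axis=1)
        if (sizes == 1).any() and n - p < 2:
            raise ValueError("a block of size 1 contributes no residual information")

    gamma = np.zeros(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = W0 * np.exp(-gamma)[None, :]
        xtvx = np.einsum("ip,gi,iq->gpq", X, V, X)
        xtvy = np.einsum("ip,gi->gp", X, V * E)
        beta = np.linalg.solve(xtvx, xtvy[..., None])[..., 0]
        resid = E - beta @ X.T
        s2 = (V * resid**2).sum(axis=1) / (n - p)
        s2 = np.maximum(s2, 1e-12)
        # leverage of observation i in gene g under weights V
        xtvx_inv = np.linalg.inv(xtvx)
        h = V * np.einsum("ip,gpq,iq->gi", X, xtvx_inv, X)
        z = V * resid**2 / s2[:, None]  # E[z_gi] = 1 - h_gi at the truth
        delta = np.zeros(len(labels))
        for b, m in enumerate(member):
            denom = h[:, m].size - h[:, m].sum()
            if denom <= 0:
                continue
            delta[b] = np.log(max(z[:, m].sum() / denom, 1e-8))
        new_gamma = gamma + member.T @ delta
        new_gamma = new_gamma - new_gamma.mean()
        if np.max(np.abs(new_gamma - gamma)) < tol:
            gamma = new_gamma
            converged = True
            break
        gamma = new_gamma
    sw = np.exp(-gamma)
    sw = sw / np.exp(np.mean(np.log(sw)))
    return SampleWeightFit(
        gamma_hat=gamma,
        sample_weight=sw,
        block=None if block is None else np.asarray(block),
        constrained=block is not None,
        converged=converged,
        n_iter=it,
    )


def voom_qwb(
    pb: PseudoBulkCounts,
    design: DesignMatrix,
    group: np.ndarray | None = None,
    span: float = 0.5,
    n_iter: int = 2,
) -> WeightedLogExpression:
    """voom with (block-constrained) sample quality weights.

    Pipeline: voom, estimate sample weights, re-run voom with those weights
    in the gene-wise fits, re-estimate, then combine: w* = w x sample_weight.
    ``group=None`` gives the standard per-sample quality weights.
    """
    if group is None:
        group_arr = None
    else:
        group_arr = np.asarray(group)
        if len(group_arr) != pb.n_samples:
            raise ValueError("group must cover all samples")
    wle = voom(pb, design, span=span)
    sw = np.ones(pb.n_samples)
    n_iter = max(n_iter, 1)
    for k in range(n_iter):
        fit = estimate_sample_weights(
            wle.E, design, obs_weights=wle.weights, block=group_arr
        )
        sw = fit.sample_weight
        if k < n_iter - 1:
            wle = voom(pb, design, span=span, lm_sample_weights=sw)
    combined = wle.weights * sw[None, :]
    return WeightedLogExpression(
        E=wle.E,
        weights=combined,
        design=design,
        gene_ids=wle.gene_ids,
        sample_ids=wle.sample_ids,
        method_tag="voomQWB",
        effective_lib_size=wle.effective_lib_size,
        trend=wle.trend,
        sample_weights=sw,
    )
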