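"""Weighted linear-model contrasts with empirical-Bayes moderated t-tests.

The gene-wise residual variances s_g^2 are shrunk toward a common prior by
fitting a scaled-F (inverse-chi-square) prior via moment matching on
log s^2; moderated t-statistics use the posterior variance with d0 extra
degrees of freedom, and multiplicity is handled by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .voom_core import WeightedLogExpression

__all__ = [
    "ModeratedFit",
    "lm_contrast_fit",
    "squeeze_var",
    "moderated_t_table",
    "de_table",
    "decide_de",
]


@dataclass
class ModeratedFit:
    logFC: np.ndarray
    stdev_unscaled: np.ndarray
    s2: np.ndarray
    df_resid: float
    d0: float
    s0_sq: float
    s2_post: np.ndarray
    t: np.ndarray
    p: np.ndarray
    adj_p: np.ndarray
    valid: bool = True


def lm_contrast_fit(
    wle: WeightedLogExpression, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, np.ndarray, bool]:
    """Per-gene weighted LS fit and a single contrast c'beta.

    Returns (logFC, stdev_unscaled, s2, df_resid, ave_expr, valid) where
    stdev_unscaled = sqrt(c' (X'W_g X)^-1 c) so that the standard error of
    logFC is stdev_unscaled * s_g.
    """
    X = wle.design.X
    c = np.asarray(contrast, dtype=float)
    if c.shape != (X.shape[1],):
        raise ValueError("contrast length must equal number of design columns")
    n, p = X.shape
    df_resid = n - wle.design.rank
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    W = wle.weights
    E = wle.E
    xtwx = np.einsum("ip,gi,iq->gpq", X, W, X)
    xtwy = np.einsum("ip,gi->gp", X, W * E)
    xtwx_inv = np.linalg.inv(xtwx)
    beta = np.einsum("gpq,gq->gp", xtwx_inv, xtwy)
    resid = E - beta @ X.T
    s2 = (W * resid**2).sum(axis=1) / df_resid
    logFC = beta @ c
    var_unscaled = np.einsum("p,gpq,q->g", c, xtwx_inv, c)
    valid = bool(np.any(c != 0))
    stdev_unscaled = np.sqrt(np.maximum(var_unscaled, 0.0))
    return logFC, stdev_unscaled, s2, df_resid, E.mean(axis=1), valid


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for all x > 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def squeeze_var(s2: np.ndarray, df_resid: float) -> tuple[float, float, np.ndarray]:
    """Fit the scaled inverse-chi-square prior and return posterior variances.

    Moment matching on z = log s^2: solve trigamma(d0/2) =
    var(z) - trigamma(df/2); s0^2 from the mean of z with the digamma bias
    terms removed. d0 = inf when the observed spread of log s^2 is no larger
    than expected under a common variance; then s2_post == s0_sq.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2 or not np.isfinite(s2).all() or (s2 <= 0).any():
        raise ValueError("need >= 2 finite positive variances")
    df = float(df_resid)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # no excess spread in log s^2: point-mass prior at the common value
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(z)))
        s2_post = np.full_like(s2, s0_sq)
    else:
        d0 = 2.0 * float(_trigamma_inverse(np.array(evar)))
        s0_sq = float(
            np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return d0, s0_sq, s2_post


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def moderated_t_table(
    gene_ids: pd.Index,
    logFC: np.ndarray,
    stdev_unscaled: np.ndarray,
    s2: np.ndarray,
    df_resid: float,
    ave_expr: np.ndarray | None = None,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Moderated t-tests and a topTable-style result frame.

    When ``d0`` is not supplied the prior is fitted by :func:`squeeze_var`;
    d0 = 0 disables moderation (ordinary t). Rows are sorted by p-value
    with a stable tie-break on gene ID.
    """
    if d0 is None:
        d0, s0_sq, s2_post = squeeze_var(s2, df_resid)
    elif d0 == 0:
        s2_post = np.asarray(s2, dtype=float)
    elif np.isinf(d0):
        s2_post = np.full_like(np.asarray(s2, dtype=float), s0_sq)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logFC / (stdev_unscaled * np.sqrt(s2_post))
    t = np.where(np.isfinite(t), t, 0.0)
    df_total = df_resid + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    adj = bh_adjust(p)
    tab = pd.DataFrame(
        {
            "gene": np.asarray(gene_ids, dtype=object),
            "logFC": logFC,
            "AveExpr": ave_expr if ave_expr is not None else np.full(len(p), np.nan),
            "t": t,
            "P.Value": p,
            "adj.P.Val": adj,
        }
    )
    tab = tab.sort_values(["P.Value", "gene"], kind="stable").reset_index(drop=True)
    tab.attrs.update({"d0": d0, "s0_sq": s0_sq, "df_resid": df_resid})
    return tab


def de_table(wle: WeightedLogExpression, contrast: np.ndarray) -> pd.DataFrame:
    """Full pipeline for one contrast: weighted fit, squeeze, moderated t."""
    logFC, su, s2, df, ave, valid = lm_contrast_fit(wle, contrast)
    if not valid:
        raise ValueError("contrast of zeros is not testable")
    return moderated_t_table(wle.gene_ids, logFC, su, s2, df, ave_expr=ave)


def decide_de(table: pd.DataFrame, cutoff: float = 0.05) -> set:
    """Genes significant at the given BH-adjusted p-value cutoff."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    if len(table) == 0:
        return set()
    return set(table.loc[table["adj.P.Val"] <= cutoff, "gene"])
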