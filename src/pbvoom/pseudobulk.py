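"""Pseudo-bulk construction from single-cell counts.

Cells belonging to the same biological sample are summed gene-wise into a
single pseudo-bulk column; the resulting gene-by-sample count matrix is then
filtered, TMM-normalized and converted to log2 counts-per-million, mirroring
the standard limma-voom preprocessing of bulk RNA-seq.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellCounts",
    "PseudoBulkCounts",
    "LogCPM",
    "aggregate_cells",
    "filter_genes",
    "filter_samples",
    "tmm_norm_factors",
    "log_cpm",
    "read_cell_counts_tsv",
    "read_cell_counts_mtx",
    "write_pseudobulk_tsv",
    "read_pseudobulk_tsv",
]


@dataclass
class CellCounts:
    """Gene-by-cell UMI counts with cell -> sample and sample -> group maps."""

    counts: np.ndarray  # (n_genes, n_cells), non-negative integers
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_sample: np.ndarray  # sample id per cell (object array)
    sample_group: pd.Series  # index: sample id, values: group label

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        self.cell_sample = np.asarray(self.cell_sample, dtype=object)
        if not isinstance(self.sample_group, pd.Series):
            self.sample_group = pd.Series(self.sample_group)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape does not match gene/cell id lengths")
        if len(self.cell_sample) != len(self.cell_ids):
            raise ValueError("cell_sample length does not match number of cells")
        if not np.isfinite(self.counts).all() or (self.counts < 0).any():
            raise ValueError("counts must be finite and non-negative")
        missing = set(self.cell_sample) - set(self.sample_group.index)
        if missing:
            raise ValueError(f"cells map to samples without a group: {sorted(missing)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class PseudoBulkCounts:
    """Gene-by-sample aggregated counts with library sizes and TMM factors."""

    counts: np.ndarray  # (n_genes, n_samples)
    gene_ids: pd.Index
    sample_ids: pd.Index
    sample_group: pd.Series  # aligned to sample_ids
    cells_per_sample: np.ndarray
    norm_factor: np.ndarray = field(default=None)  # type: ignore[assignment]
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.sample_ids = pd.Index(self.sample_ids)
        if not isinstance(self.sample_group, pd.Series):
            self.sample_group = pd.Series(
                np.asarray(self.sample_group), index=self.sample_ids
            )
        self.sample_group = self.sample_group.reindex(self.sample_ids)
        self.cells_per_sample = np.asarray(self.cells_per_sample)
        if self.norm_factor is None:
            self.norm_factor = np.ones(self.counts.shape[1])
        self.norm_factor = np.asarray(self.norm_factor, dtype=float)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def lib_size(self) -> np.ndarray:
        """Per-sample raw library size (column sums of counts)."""
        return self.counts.sum(axis=0).astype(float)

    @property
    def effective_lib_size(self) -> np.ndarray:
        """Library size scaled by the TMM normalization factor."""
        return self.lib_size * self.norm_factor

    @property
    def group_labels(self) -> np.ndarray:
        return self.sample_group.to_numpy()


@dataclass
class LogCPM:
    """log2 counts-per-million with the voom prior-count offset."""

    values: np.ndarray  # (n_genes, n_samples)
    gene_ids: pd.Index
    sample_ids: pd.Index
    effective_lib_size: np.ndarray
    prior_count: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("log-CPM values must be finite")


def aggregate_cells(cc: CellCounts) -> PseudoBulkCounts:
    """Sum single-cell counts over all cells of each sample.

    Sample order follows ``cc.sample_group.index``. A sample with zero
    assigned cells is an error (it has no pseudo-bulk observation).
    """
    sample_ids = pd.Index(cc.sample_group.index)
    sample_pos = {s: j for j, s in enumerate(sample_ids)}
    col = np.array([sample_pos[s] for s in cc.cell_sample])
    n_cells = np.bincount(col, minlength=len(sample_ids))
    empty = [str(sample_ids[j]) for j in np.flatnonzero(n_cells == 0)]
    if empty:
        raise ValueError(f"sample(s) with zero cells: {', '.join(empty)}")
    agg = np.zeros((cc.n_genes, len(sample_ids)), dtype=cc.counts.dtype)
    np.add.at(agg.T, col, cc.counts.T)
    return PseudoBulkCounts(
        counts=agg,
        gene_ids=cc.gene_ids,
        sample_ids=sample_ids,
        sample_group=cc.sample_group,
        cells_per_sample=n_cells,
    )


def filter_genes(pb: PseudoBulkCounts, min_total: int = 30) -> PseudoBulkCounts:
    """Remove genes with fewer than ``min_total`` reads across all samples."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = pb.counts.sum(axis=1) >= min_total
    if not keep.any():
        raise ValueError(f"all genes removed at min_total={min_total}")
    return replace(
        pb,
        counts=pb.counts[keep],
        gene_ids=pb.gene_ids[keep],
        norm_factor=np.ones(pb.n_samples),
    )


def filter_samples(
    pb: PseudoBulkCounts, min_cells: int = 50, min_lib: int = 0
) -> PseudoBulkCounts:
    """Remove samples with too few cells or too small a library.

    A group losing all its samples is recorded as a warning in the result's
    metadata rather than raising, so exploratory filtering can proceed.
    """
    if min_cells < 0 or min_lib < 0:
        raise ValueError("thresholds must be >= 0")
    keep = (pb.cells_per_sample >= min_cells) & (pb.lib_size >= min_lib)
    out = PseudoBulkCounts(
        counts=pb.counts[:, keep],
        gene_ids=pb.gene_ids,
        sample_ids=pb.sample_ids[keep],
        sample_group=pb.sample_group[keep],
        cells_per_sample=pb.cells_per_sample[keep],
        warnings=list(pb.warnings),
    )
    for grp in pd.unique(pb.group_labels):
        if grp not in set(out.group_labels):
            out.warnings.append(f"group '{grp}' has no samples left after filtering")
    return out


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """Two-sample TMM factor: trimmed, precision-weighted mean of M-values."""
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
        # asymptotic binomial variance of M
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    ok = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[ok], a[ok], v[ok]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.nansum(m[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_norm_factors(pb: PseudoBulkCounts) -> PseudoBulkCounts:
    """Compute TMM normalization factors (trimmed mean of M-values).

    Log-ratios are trimmed by 30%, absolute intensities by 5%, and the
    remaining M-values averaged with inverse-variance precision weights.
    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean of those percentiles (lowest index on ties). Factors are
    rescaled to have geometric mean 1.
    """
    if pb.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = pb.lib_size
    if (lib <= 0).any():
        bad = pb.sample_ids[lib <= 0].tolist()
        raise ValueError(f"sample(s) with zero library size: {bad}")
    q75 = np.array(
        [np.quantile(pb.counts[:, j] / lib[j], 0.75) for j in range(pb.n_samples)]
    )
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.array(
        [
            _tmm_pair(
                pb.counts[:, j].astype(float),
                pb.counts[:, ref].astype(float),
                lib[j],
                lib[ref],
            )
            for j in range(pb.n_samples)
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return replace(pb, norm_factor=f)


def log_cpm(pb: PseudoBulkCounts, prior_count: float = 0.5) -> LogCPM:
    """log2((count + prior) / (effective library + 1) * 1e6), the voom dialect."""
    eff = pb.effective_lib_size
    if (eff <= 0).any():
        raise ValueError("non-positive effective library size")
    vals = np.log2((pb.counts + prior_count) / (eff + 1.0) * 1e6)
    return LogCPM(
        values=vals,
        gene_ids=pb.gene_ids,
        sample_ids=pb.sample_ids,
        effective_lib_size=eff,
        prior_count=prior_count,
    )


# ---------------------------------------------------------------------------
# I/O


def read_cell_counts_tsv(
    counts_path: str | Path, cell_meta_path: str | Path, sample_meta_path: str | Path
) -> CellCounts:
    """Dense gene-by-cell TSV plus cell and sample metadata tables.

    ``cell_meta`` needs columns cell_id, sample_id; ``sample_meta`` needs
    sample_id, group.
    """
    mat = pd.read_csv(counts_path, sep="\t", index_col=0)
    cell_meta = pd.read_csv(cell_meta_path, sep="\t").set_index("cell_id")
    sample_meta = pd.read_csv(sample_meta_path, sep="\t").set_index("sample_id")
    cell_sample = cell_meta.loc[mat.columns, "sample_id"].to_numpy(dtype=object)
    return CellCounts(
        counts=mat.to_numpy(),
        gene_ids=mat.index,
        cell_ids=mat.columns,
        cell_sample=cell_sample,
        sample_group=sample_meta["group"],
    )


def read_cell_counts_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    cell_meta_path: str | Path,
    sample_meta_path: str | Path,
) -> CellCounts:
    """MatrixMarket triple (matrix, gene list, barcodes) plus metadata TSVs."""
    from scipy.io import mmread

    mat = np.asarray(mmread(mtx_path).todense())
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0]
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0]
    cell_meta = pd.read_csv(cell_meta_path, sep="\t").set_index("cell_id")
    sample_meta = pd.read_csv(sample_meta_path, sep="\t").set_index("sample_id")
    cell_sample = cell_meta.loc[barcodes, "sample_id"].to_numpy(dtype=object)
    return CellCounts(
        counts=mat,
        gene_ids=pd.Index(genes),
        cell_ids=pd.Index(barcodes),
        cell_sample=cell_sample,
        sample_group=sample_meta["group"],
    )


def write_pseudobulk_tsv(pb: PseudoBulkCounts, counts_path: str | Path) -> None:
    """Write counts as TSV plus a JSON sidecar with per-sample metadata."""
    df = pd.DataFrame(pb.counts, index=pb.gene_ids, columns=pb.sample_ids)
    df.index.name = "gene"
    df.to_csv(counts_path, sep="\t")
    sidecar = Path(counts_path).with_suffix(".json")
    meta = {
        "sample_ids": [str(s) for s in pb.sample_ids],
        "group": [str(g) for g in pb.group_labels],
        "lib_size": pb.lib_size.tolist(),
        "norm_factor": pb.norm_factor.tolist(),
        "cells_per_sample": pb.cells_per_sample.tolist(),
        "warnings": pb.warnings,
    }
    sidecar.write_text(json.dumps(meta, indent=1))


def read_pseudobulk_tsv(
    counts_path: str | Path, sample_meta_path: str | Path | None = None
) -> PseudoBulkCounts:
    """Read a gene-by-sample count TSV; group labels from the JSON sidecar
    written by :func:`write_pseudobulk_tsv` or a sample metadata TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    sidecar = Path(counts_path).with_suffix(".json")
    if sample_meta_path is not None:
        meta = pd.read_csv(sample_meta_path, sep="\t").set_index("sample_id")
        group = meta.loc[df.columns, "group"]
        cells = meta["n_cells"].loc[df.columns].to_numpy() if "n_cells" in meta else np.ones(df.shape[1], dtype=int)
        nf = None
    elif sidecar.exists():
        m = json.loads(sidecar.read_text())
        group = pd.Series(m["group"], index=df.columns)
        cells = np.asarray(m["cells_per_sample"])
        nf = np.asarray(m["norm_factor"])
    else:
        raise FileNotFoundError(
            f"no sample metadata: provide a metadata TSV or the sidecar {sidecar}"
        )
    return PseudoBulkCounts(
        counts=df.to_numpy(),
        gene_ids=df.index,
        sample_ids=df.columns,
        sample_group=group,
        cells_per_sample=cells,
        norm_factor=nf,
    )
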