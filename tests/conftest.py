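import numpy as np
import pandas as pd
import pytest

from pbvoom.pseudobulk import CellCounts, PseudoBulkCounts
from pbvoom.simulator import GroupSpec, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cells(rng):
    """20 genes x 15 cells over 3 samples in 2 groups."""
    counts = rng.poisson(5.0, size=(20, 15))
    cell_sample = np.array(["s1"] * 5 + ["s2"] * 5 + ["s3"] * 5, dtype=object)
    return CellCounts(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(20)],
        cell_ids=[f"c{i}" for i in range(15)],
        cell_sample=cell_sample,
        sample_group=pd.Series({"s1": "A", "s2": "A", "s3": "B"}),
    )


def make_pb(counts, groups, cells=None):
    counts = np.asarray(counts)
    n = counts.shape[1]
    return PseudoBulkCounts(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{i}" for i in range(n)],
        sample_group=list(groups),
        cells_per_sample=np.ones(n, dtype=int) if cells is None else np.asarray(cells),
    )


@pytest.fixture
def nb_pb(rng):
    """600-gene, 6-sample NB pseudo-bulk (phi=0.04), two groups of three."""
    G, n = 600, 6
    base = rng.lognormal(-1, 1.5, G)
    base /= base.sum()
    mu = base[:, None] * 3e5
    lam = rng.gamma(1 / 0.04, mu * 0.04, size=(G, n))
    y = rng.poisson(lam)
    keep = y.sum(axis=1) >= 30
    return make_pb(y[keep], ["A"] * 3 + ["B"] * 3)


@pytest.fixture(scope="session")
def tiny_sim_config():
    """A scaled-down two-group simulation used for structural tests."""
    return SimConfig(
        n_genes=800,
        groups=[
            GroupSpec("group1", phi_sc=0.364, cell_counts=(60, 60, 60)),
            GroupSpec("group2", phi_sc=0.748, cell_counts=(60, 60, 60)),
        ],
        rho=0.1,
        n_de_per_group=20,
        seed=11,
    )
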