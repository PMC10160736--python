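import numpy as np
import pandas as pd
import pytest

from pbvoom.pseudobulk import (
    CellCounts,
    aggregate_cells,
    filter_genes,
    filter_samples,
    log_cpm,
    read_pseudobulk_tsv,
    tmm_norm_factors,
    write_pseudobulk_tsv,
)
from .conftest import make_pb


class TestAggregateCells:
    def test_one_cell_per_sample_is_identity(self, rng):
        counts = rng.poisson(4, size=(8, 3))
        cc = CellCounts(
            counts=counts,
            gene_ids=[f"g{i}" for i in range(8)],
            cell_ids=["c1", "c2", "c3"],
            cell_sample=np.array(["s1", "s2", "s3"], dtype=object),
            sample_group=pd.Series({"s1": "A", "s2": "A", "s3": "B"}),
        )
        pb = aggregate_cells(cc)
        np.testing.assert_array_equal(pb.counts, counts)
        np.testing.assert_array_equal(pb.cells_per_sample, [1, 1, 1])

    def test_two_cells_sum(self):
        cc = CellCounts(
            counts=np.array([[1, 3], [2, 4]]),
            gene_ids=["g1", "g2"],
            cell_ids=["c1", "c2"],
            cell_sample=np.array(["s1", "s1"], dtype=object),
            sample_group=pd.Series({"s1": "A"}),
        )
        pb = aggregate_cells(cc)
        np.testing.assert_array_equal(pb.counts[:, 0], [4, 6])

    def test_matches_loop_oracle_and_conserves_reads(self, small_cells):
        pb = aggregate_cells(small_cells)
        expected = np.zeros((20, 3))
        samples = list(pb.sample_ids)
        for c in range(small_cells.n_cells):
            j = samples.index(small_cells.cell_sample[c])
            expected[:, j] += small_cells.counts[:, c]
        np.testing.assert_array_equal(pb.counts, expected)
        assert pb.counts.sum() == small_cells.counts.sum()

    def test_empty_sample_errors_with_name(self, small_cells):
        small_cells.sample_group = pd.Series({"s1": "A", "s2": "A", "s3": "B", "s9": "B"})
        with pytest.raises(ValueError, match="s9"):
            aggregate_cells(small_cells)


class TestFilters:
    def test_gene_threshold_is_strict(self):
        pb = make_pb([[29, 0], [15, 15], [40, 0]], ["A", "B"])
        out = filter_genes(pb, 30)
        assert list(out.gene_ids) == ["g1", "g2"]

    def test_min_total_zero_keeps_all(self, nb_pb):
        assert filter_genes(nb_pb, 0).n_genes == nb_pb.n_genes

    def test_matches_brute_force_scan(self, rng):
        pb = make_pb(rng.poisson(3, size=(50, 4)), ["A", "A", "B", "B"])
        out = filter_genes(pb, 12)
        expected = [i for i in range(50) if pb.counts[i].sum() >= 12]
        assert list(out.gene_ids) == [f"g{i}" for i in expected]

    def test_all_filtered_errors(self):
        pb = make_pb([[1, 1]], ["A", "B"])
        with pytest.raises(ValueError):
            filter_genes(pb, 1000)

    def test_sample_cell_threshold(self, rng):
        pb = make_pb(rng.poisson(3, size=(10, 3)), ["A", "A", "B"], cells=[49, 50, 80])
        out = filter_samples(pb, min_cells=50)
        assert list(out.sample_ids) == ["s1", "s2"]

    def test_zero_thresholds_keep_everything(self, nb_pb):
        out = filter_samples(nb_pb, min_cells=0, min_lib=0)
        assert out.n_samples == nb_pb.n_samples

    def test_brute_force_survivors_and_group_warning(self, rng):
        cells = rng.integers(10, 120, size=6)
        pb = make_pb(rng.poisson(3, size=(10, 6)), ["A"] * 3 + ["B"] * 3, cells=cells)
        out = filter_samples(pb, min_cells=60)
        assert list(out.sample_ids) == [f"s{i}" for i in range(6) if cells[i] >= 60]
        gone = filter_samples(pb, min_cells=1000)
        assert any("group" in w for w in gone.warnings)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 41)
        pb = make_pb(np.tile(col[:, None], (1, 4)), ["A", "A", "B", "B"])
        np.testing.assert_allclose(tmm_norm_factors(pb).norm_factor, 1.0, atol=1e-12)

    def test_depth_invariance(self, rng):
        base = rng.poisson(20, size=(200, 1))
        counts = np.tile(base, (1, 4))
        counts[:, 2] *= 3  # pure depth change
        pb = make_pb(counts, ["A", "A", "B", "B"])
        np.testing.assert_allclose(tmm_norm_factors(pb).norm_factor, 1.0, atol=1e-6)

    def test_matches_straight_line_oracle(self, rng):
        # one composition-shifted sample among four
        counts = rng.poisson(50, size=(50, 4)).astype(float)
        counts[:10, 3] *= 6
        pb = make_pb(counts.astype(int), ["A", "A", "B", "B"])
        out = tmm_norm_factors(pb)

        # independent reimplementation of the trimmed weighted mean of M-values
        lib = counts.sum(axis=0)
        q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(4)])
        ref = int(np.argmin(np.abs(q75 - q75.mean())))
        fs = []
        for j in range(4):
            obs, refc = counts[:, j], counts[:, ref]
            ok = (obs > 0) & (refc > 0)
            o, r = obs[ok], refc[ok]
            m = np.log2((o / lib[j]) / (r / lib[ref]))
            a = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
            v = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
            n = len(m)
            lo_m = np.floor(n * 0.3) + 1
            lo_a = np.floor(n * 0.05) + 1
            rm = pd.Series(m).rank().to_numpy()
            ra = pd.Series(a).rank().to_numpy()
            keep = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
            if np.max(np.abs(m)) < 1e-6 or not keep.any():
                fs.append(1.0)
            else:
                fs.append(2 ** (np.sum(m[keep] / v[keep]) / np.sum(1 / v[keep])))
        fs = np.array(fs)
        fs /= np.exp(np.mean(np.log(fs)))
        np.testing.assert_allclose(out.norm_factor, fs, rtol=1e-10)

    def test_geometric_mean_one_and_permutation_invariance(self, rng):
        counts = rng.negative_binomial(5, 0.1, size=(300, 5))
        pb = make_pb(counts, ["A"] * 5)
        f = tmm_norm_factors(pb).norm_factor
        assert abs(np.prod(f) ** (1 / 5) - 1) < 1e-8
        perm = [3, 1, 4, 0, 2]
        pb2 = make_pb(counts[:, perm], ["A"] * 5)
        f2 = tmm_norm_factors(pb2).norm_factor
        np.testing.assert_allclose(f2, f[perm], rtol=1e-10)

    def test_all_zero_sample_errors(self):
        pb = make_pb([[5, 0], [3, 0]], ["A", "B"])
        with pytest.raises(ValueError):
            tmm_norm_factors(pb)


class TestLogCPM:
    def test_zero_count_closed_form(self):
        # lib 999,999 (+1 = 1e6): log2(0.5 / 1e6 * 1e6) = -1
        counts = np.zeros((2, 1), dtype=int)
        counts[1, 0] = 999_999
        pb = make_pb(counts, ["A"])
        assert log_cpm(pb).values[0, 0] == pytest.approx(-1.0)

    def test_doubling_large_count_adds_about_one(self):
        pb = make_pb([[10_000], [20_000], [970_000]], ["A"])
        v = log_cpm(pb).values
        assert v[1, 0] - v[0, 0] == pytest.approx(1.0, abs=1e-4)

    def test_matches_formula_cellwise(self, nb_pb):
        pb = tmm_norm_factors(nb_pb)
        lc = log_cpm(pb, prior_count=0.5)
        eff = pb.lib_size * pb.norm_factor
        for g in range(0, pb.n_genes, 97):
            for i in range(pb.n_samples):
                expected = np.log2((pb.counts[g, i] + 0.5) / (eff[i] + 1) * 1e6)
                assert lc.values[g, i] == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_count(self):
        pb = make_pb(np.array([[0], [1], [5], [50], [5000]]), ["A"])
        v = log_cpm(pb).values[:, 0]
        assert np.all(np.diff(v) > 0)


def test_tsv_round_trip(tmp_path, nb_pb):
    pb = tmm_norm_factors(nb_pb)
    path = tmp_path / "pb.tsv"
    write_pseudobulk_tsv(pb, path)
    back = read_pseudobulk_tsv(path)
    np.testing.assert_array_equal(back.counts, pb.counts)
    np.testing.assert_allclose(back.norm_factor, pb.norm_factor)
    assert list(back.group_labels) == list(pb.group_labels)
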