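import numpy as np
import pytest
from scipy import special, stats

from pbvoom.pseudobulk import aggregate_cells
from pbvoom.simulator import (
    GroupSpec,
    SimConfig,
    _gamma_quantile_table,
    aggregated_dispersion,
    effective_cell_number,
    make_baseline,
    scenario_preset,
    simulate_dataset,
    solve_phi_sc,
)


class TestEffectiveCellNumber:
    def test_equal_libraries(self):
        assert effective_cell_number(np.full(17, 1234.0)) == pytest.approx(17.0)

    def test_single_cell(self):
        assert effective_cell_number(np.array([5.0])) == pytest.approx(1.0)

    def test_two_unequal(self):
        assert effective_cell_number(np.array([1.0, 2.0])) == pytest.approx(9 / 5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            effective_cell_number(np.array([]))


class TestAggregatedDispersion:
    def test_rho_one_returns_phi_sc(self):
        L = np.full(100, 10.0)
        assert aggregated_dispersion(0.448, 1.0, L) == pytest.approx(0.448)

    def test_rho_zero_equal_cells(self):
        assert aggregated_dispersion(0.5, 0.0, np.full(40, 3.0)) == pytest.approx(1 / 40)

    def test_scenario_anchor_value(self):
        phi = aggregated_dispersion(0.448, 0.1, np.full(250, 1800.0))
        assert phi == pytest.approx(0.1 * 0.448 + 0.9 / 250)
        assert np.sqrt(phi) == pytest.approx(0.22, abs=1e-3)


class TestSolvePhiSc:
    @pytest.mark.parametrize(
        "target,expected",
        [(0.22, 0.448), (0.20, 0.364), (0.26, 0.640), (0.28, 0.748)],
    )
    def test_preset_anchors(self, target, expected):
        assert solve_phi_sc(target, 0.1, 250) == pytest.approx(expected, abs=5e-4)

    def test_round_trip(self):
        for b in (0.15, 0.22, 0.31):
            phi = solve_phi_sc(b, 0.1, 250)
            back = aggregated_dispersion(phi, 0.1, np.full(250, 7.0))
            assert back == pytest.approx(b**2, abs=1e-12)

    def test_infeasible_target_errors(self):
        with pytest.raises(ValueError, match="infeasible"):
            solve_phi_sc(0.01, 0.1, 250)


class TestMakeBaseline:
    def test_supplied_uniform_returned(self):
        b = make_baseline(5, supplied=np.full(5, 0.2))
        np.testing.assert_allclose(b, 0.2)

    def test_synthesized_sums_to_one_and_is_seeded(self):
        b1 = make_baseline(1000, seed=3)
        b2 = make_baseline(1000, seed=3)
        assert b1.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(b1, b2)

    def test_heavy_tail_spans_four_orders_of_magnitude(self):
        b = make_baseline(10_000, seed=0)
        assert b.max() / np.quantile(b, 0.01) > 1e4

    def test_bad_supplied_vector_errors(self):
        with pytest.raises(ValueError):
            make_baseline(4, supplied=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            make_baseline(2, supplied=np.array([-0.1, 1.1]))


class TestGammaQuantileTable:
    @pytest.mark.parametrize("phi", [0.364, 0.748, 2.0])
    def test_matches_exact_incomplete_gamma_inverse(self, rng, phi):
        zg, logq = _gamma_quantile_table(1.0 / phi)
        z = rng.normal(size=20_000)
        approx = np.exp(np.interp(z, zg, logq))
        exact = special.gammaincinv(1.0 / phi, stats.norm.cdf(z))
        rel = np.abs(approx - exact) / np.maximum(exact, 1e-12)
        assert rel.max() < 1e-5


class TestSimulateDataset:
    def test_reproducible_bit_identical(self, tiny_sim_config):
        c1, t1 = simulate_dataset(tiny_sim_config)
        c2, t2 = simulate_dataset(tiny_sim_config)
        np.testing.assert_array_equal(c1.counts, c2.counts)
        assert t1.de_genes == t2.de_genes

    def test_truth_bookkeeping(self, tiny_sim_config):
        _, truth = simulate_dataset(tiny_sim_config)
        assert all(len(v) == 20 for v in truth.de_genes.values())
        sets = list(truth.de_genes.values())
        assert not (sets[0] & sets[1])
        assert len(truth.de_for_comparison("group1", "group2")) == 40

    def test_nb_moment_oracle(self):
        # rho = 0, fixed mu = 100, phi = 0.5: var ~ mu + phi mu^2 = 5100
        cfg = SimConfig(
            n_genes=2,
            groups=[GroupSpec("g", phi_sc=0.5, cell_counts=(100_000,))],
            rho=0.0,
            n_de_per_group=0,
            libsize_meanlog=np.log(200.0),
            libsize_sdlog=0.0,
            baseline=np.array([0.5, 0.5]),
            seed=5,
        )
        cc, _ = simulate_dataset(cfg)
        y = cc.counts[0].astype(float)  # mu = 0.5 * 200 = 100 per cell
        assert y.mean() == pytest.approx(100.0, rel=0.02)
        assert y.var() == pytest.approx(100.0 + 0.5 * 100.0**2, rel=0.05)

    def test_poisson_limit_small_phi(self):
        cfg = SimConfig(
            n_genes=2,
            groups=[GroupSpec("g", phi_sc=1e-4, cell_counts=(100_000,))],
            rho=0.0,
            n_de_per_group=0,
            libsize_meanlog=np.log(100.0),
            libsize_sdlog=0.0,
            baseline=np.array([0.5, 0.5]),
            seed=6,
        )
        cc, _ = simulate_dataset(cfg)
        y = cc.counts[1].astype(float)
        assert y.var() / y.mean() == pytest.approx(1.0, rel=0.05)

    def test_copula_correlation_within_and_between_subjects(self):
        # uniform baseline: across genes, the two cells of one subject give
        # 10^4 iid replicate pairs of the equicorrelated construction
        rho = 0.4
        G = 10_000
        cfg = SimConfig(
            n_genes=G,
            groups=[GroupSpec("g", phi_sc=0.5, cell_counts=(2, 1))],
            rho=rho,
            n_de_per_group=0,
            libsize_meanlog=np.log(5e6),
            libsize_sdlog=0.0,
            baseline=np.full(G, 1.0 / G),
            seed=7,
        )
        cc, _ = simulate_dataset(cfg)
        y = cc.counts.astype(float)  # mu = 500 per gene per cell
        within = np.corrcoef(y[:, 0], y[:, 1])[0, 1]
        across = np.corrcoef(y[:, 0], y[:, 2])[0, 1]
        assert within == pytest.approx(rho, abs=0.03)
        assert abs(across) < 0.03

    def test_library_size_proportional_to_cell_number(self):
        cfg = scenario_preset("scenario3", seed=9)
        cc, _ = simulate_dataset(cfg)
        pb = aggregate_cells(cc)
        lib = pb.lib_size
        cells = pb.cells_per_sample
        base_mean = lib[cells == 250].mean()
        big_mean = lib[cells == 750].mean()
        assert big_mean / base_mean == pytest.approx(3.0, rel=0.05)


class TestScenarioPresets:
    def test_scenario1_structure(self):
        cfg = scenario_preset("scenario1")
        assert len(cfg.groups) == 4
        assert all(g.n_samples == 3 for g in cfg.groups)
        assert all(g.cell_counts == (250, 250, 250) for g in cfg.groups)
        assert cfg.n_genes == 10_000 and cfg.rho == 0.1
        targets = [0.20, 0.22, 0.26, 0.28]
        for g, t in zip(cfg.groups, targets):
            assert g.phi_sc == pytest.approx(solve_phi_sc(t, 0.1, 250))

    def test_scenario3_cell_proportions(self):
        cfg = scenario_preset("scenario3")
        assert cfg.groups[3].cell_counts == (250, 750, 750)
        assert cfg.groups[1].cell_counts == (250, 200, 200)
        assert len({g.phi_sc for g in cfg.groups}) == 1

    @pytest.mark.parametrize("name", ["scenario1", "scenario2", "scenario3", "scenario4"])
    def test_every_preset_has_100_de_per_pairwise_comparison(self, name):
        cfg = scenario_preset(name)
        cfg.n_genes = 2000  # structural check only; fewer genes, same truth sizes
        _, truth = simulate_dataset(cfg)
        names = [g.name for g in cfg.groups]
        total = set().union(*truth.de_genes.values())
        assert len(total) == 200
        for i in range(4):
            for j in range(i + 1, 4):
                assert len(truth.de_for_comparison(names[i], names[j])) == 100

    def test_unknown_name_errors(self):
        with pytest.raises(ValueError):
            scenario_preset("scenario9")


def test_config_yaml_round_trip(tmp_path, tiny_sim_config):
    p = tmp_path / "cfg.yaml"
    tiny_sim_config.to_yaml(p)
    back = SimConfig.from_yaml(p)
    assert back.n_genes == tiny_sim_config.n_genes
    assert back.groups[1].phi_sc == tiny_sim_config.groups[1].phi_sc
    c1, _ = simulate_dataset(back)
    c2, _ = simulate_dataset(tiny_sim_config)
    np.testing.assert_array_equal(c1.counts, c2.counts)
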