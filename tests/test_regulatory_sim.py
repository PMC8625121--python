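"""Simulator: exact sparsity, rectification, noise placement, reproducibility,
and the brute-force expression oracle."""

import numpy as np
import pytest

from latentdecoder import (
    ExpressionMatrix,
    RegNetConfig,
    RegulatorMatrix,
    RegulatoryNetwork,
    make_network,
    read_dataset,
    sample_regulators,
    simulate_dataset,
    simulate_expression,
    write_dataset,
)
from latentdecoder.errors import ConfigError, ShapeError


def brute_force_expression(adjacency, weights, z):
    """Independent oracle: per-entry double loop over genes and regulators."""
    N, m = z.shape
    n = adjacency.shape[0]
    out = np.zeros((N, n))
    for k in range(N):
        for i in range(n):
            s = 0.0
            for j in range(m):
                s += adjacency[i, j] * weights[i, j] * z[k, j]
            out[k, i] = max(0.0, s)
    return out


class TestMakeNetwork:
    def test_exact_sparsity_at_benchmark_scale(self):
        cfg = RegNetConfig(n_genes=1000, n_regulators=100, connectivity=0.1, seed=3)
        net = make_network(cfg)
        assert int((net.adjacency == 0).sum()) == 90_000
        assert int(net.adjacency.sum()) == 10_000

    @pytest.mark.parametrize("connectivity,n,m", [(1.0, 4, 2), (0.5, 10, 4), (0.25, 8, 2)])
    def test_exact_count_any_connectivity(self, connectivity, n, m):
        cfg = RegNetConfig(n_genes=n, n_regulators=m, connectivity=connectivity, seed=0)
        net = make_network(cfg)
        assert int(net.adjacency.sum()) == round(connectivity * n * m)

    def test_full_connectivity_is_all_ones(self):
        net = make_network(RegNetConfig(n_genes=3, n_regulators=2, connectivity=1.0, seed=0))
        assert (net.adjacency == 1).all()

    def test_seed_determinism(self, small_config):
        a, b = make_network(small_config), make_network(small_config)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert np.array_equal(a.weights, b.weights)

    def test_weights_within_bounds(self, small_config):
        net = make_network(small_config)
        assert net.weights.min() >= small_config.weight_low
        assert net.weights.max() < small_config.weight_high

    @pytest.mark.parametrize(
        "field,value",
        [
            ("connectivity", 0.0),
            ("connectivity", 1.5),
            ("n_regulators", 0),
            ("weight_low", 2.0),
            ("gamma_shape", -1.0),
            ("noise_sd", -0.1),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigError):
            RegNetConfig(**{field: value})

    def test_m_must_be_below_n(self):
        with pytest.raises(ConfigError):
            RegNetConfig(n_genes=10, n_regulators=10)


class TestSampleRegulators:
    def test_nonnegative_and_shape(self, small_config):
        z = sample_regulators(15, small_config)
        assert z.values.shape == (15, small_config.n_regulators)
        assert (z.values >= 0).all()

    def test_gamma_mean_matches_moments(self):
        cfg = RegNetConfig(n_genes=2, n_regulators=1, gamma_shape=2.0, gamma_scale=1.0, seed=5)
        z = sample_regulators(100_000, cfg)
        se = np.sqrt(2.0) / np.sqrt(100_000)  # sd of gamma(2,1) is sqrt(2)
        assert abs(z.values.mean() - 2.0) < 3 * se

    def test_seeded_reproducibility(self, small_config):
        a = sample_regulators(8, small_config, seed=11)
        b = sample_regulators(8, small_config, seed=11)
        assert np.array_equal(a.values, b.values)

    def test_rejects_nonpositive_n(self, small_config):
        with pytest.raises(ConfigError):
            sample_regulators(0, small_config)


class TestSimulateExpression:
    def test_single_positive_term(self):
        net = RegulatoryNetwork(adjacency=[[1]], weights=[[2.0]])
        x = simulate_expression(net, np.array([[3.0]]), noise_sd=0.0)
        assert x.values[0, 0] == pytest.approx(6.0)

    def test_rectification_of_negative_preactivation(self):
        net = RegulatoryNetwork(adjacency=[[1]], weights=[[-2.0]])
        x = simulate_expression(net, np.array([[3.0]]), noise_sd=0.0)
        assert x.values[0, 0] == 0.0

    def test_matches_brute_force_loop(self, rng):
        adjacency = (rng.random((5, 3)) < 0.6).astype(int)
        weights = rng.uniform(-1, 1, (5, 3))
        net = RegulatoryNetwork(adjacency=adjacency, weights=weights)
        z = rng.gamma(2.0, 1.0, (4, 3))
        got = simulate_expression(net, z, noise_sd=0.0).values
        assert np.allclose(got, brute_force_expression(adjacency, weights, z), atol=1e-10)

    def test_zero_noise_is_deterministic(self, small_dataset):
        net = small_dataset.network
        z = small_dataset.z_train
        a = simulate_expression(net, z, noise_sd=0.0, seed=1)
        b = simulate_expression(net, z, noise_sd=0.0, seed=99)
        assert np.array_equal(a.values, b.values)

    def test_noise_deviation_grows_with_sd(self, small_dataset):
        net, z = small_dataset.network, small_dataset.z_train
        clean = simulate_expression(net, z, noise_sd=0.0).values
        devs = []
        for sd in (0.1, 0.5):
            d = [
                np.abs(simulate_expression(net, z, noise_sd=sd, seed=s).values - clean).mean()
                for s in range(10)
            ]
            devs.append(np.mean(d))
        assert devs[1] > devs[0] > 0

    def test_output_nonnegative(self, small_dataset):
        x = simulate_expression(small_dataset.network, small_dataset.z_train,
                                noise_sd=1.0, seed=2)
        assert (x.values >= 0).all()

    def test_dimension_mismatch(self, small_dataset):
        with pytest.raises(ShapeError):
            simulate_expression(small_dataset.network, np.ones((3, 99)))

    def test_negative_noise_sd(self, small_dataset):
        with pytest.raises(ConfigError):
            simulate_expression(small_dataset.network, small_dataset.z_train, noise_sd=-1.0)


class TestDatasetRoundTrip:
    def test_write_then_read_regenerates(self, small_dataset, tmp_path):
        write_dataset(small_dataset, tmp_path / "ds")
        back = read_dataset(tmp_path / "ds")
        assert np.array_equal(back.x_train.values, small_dataset.x_train.values)
        assert np.array_equal(back.z_test.values, small_dataset.z_test.values)
        assert back.config == small_dataset.config

    def test_train_and_test_cohorts_differ(self, small_dataset):
        assert small_dataset.z_train.values[:20].shape == small_dataset.z_test.values.shape
        assert not np.allclose(small_dataset.z_train.values[:20], small_dataset.z_test.values)

    def test_expression_matrix_rejects_negative(self):
        with pytest.raises(ConfigError):
            ExpressionMatrix(values=np.array([[-0.1, 1.0]]))

    def test_regulator_matrix_rejects_negative(self):
        with pytest.raises(ConfigError):
            RegulatorMatrix(values=np.array([[-0.1]]))
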