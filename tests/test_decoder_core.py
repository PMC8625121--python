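"""Joint decoder/representation training: forward-map contracts, oracle
equivalences (simulator, least squares, PCA subspace), convergence and
reproducibility."""

import numpy as np
import pytest

from latentdecoder import (
    DecoderModel,
    DecoderSpec,
    LayerSpec,
    TrainConfig,
    infer_representations,
    principal_subspace,
    reconstruct,
    simulate_expression,
    sparse_linear_decoder,
    subspace_angle,
    train_decoder,
)
from latentdecoder.decoder_core import decoder_train_config
from latentdecoder.errors import ConfigError, DataError, ShapeError, StateError


def dense_linear_spec(m, n):
    return DecoderSpec([LayerSpec("dense-linear", m, n, activation="none")])


@pytest.fixture(scope="module")
def linear_gaussian():
    """Zero-mean data concentrated near a 3-dim subspace of R^30."""
    rng = np.random.default_rng(0)
    n, m, N = 30, 3, 200
    B = rng.normal(size=(m, n)) * np.array([5.0, 3.0, 2.0])[:, None]
    x = rng.normal(size=(N, m)) @ B + 0.05 * rng.normal(size=(N, n))
    return x - x.mean(axis=0)


@pytest.fixture(scope="module")
def trained_linear(linear_gaussian):
    spec = dense_linear_spec(3, linear_gaussian.shape[1])
    cfg = TrainConfig(epochs=2000, seed=0)
    return train_decoder(linear_gaussian, spec, cfg)


class TestReconstruct:
    def test_identity_weights_give_identity_map(self, rng):
        model = DecoderModel(dense_linear_spec(4, 4), rng=rng)
        model.net.layers[0].W = np.eye(4)
        model.trained = True
        z = rng.normal(size=(6, 4))
        assert np.allclose(reconstruct(model, z), z)

    def test_sparse_layer_reproduces_simulator(self, small_dataset, rng):
        """Forward map with the generating (A, W) equals zero-noise simulation."""
        net = small_dataset.network
        model = DecoderModel(sparse_linear_decoder(net.adjacency), rng=rng)
        model.net.layers[0].W = net.effective_weights.copy()
        z = small_dataset.z_train.values
        expected = simulate_expression(net, z, noise_sd=0.0).values
        assert np.allclose(model.reconstruct(z), expected, atol=1e-12)

    def test_scaling_invariance_single_linear_layer(self, rng):
        model = DecoderModel(dense_linear_spec(3, 8), rng=rng)
        z = rng.normal(size=(5, 3))
        base = model.reconstruct(z)
        for s in (2.0, -0.5, 10.0):
            model2 = DecoderModel(dense_linear_spec(3, 8), rng=np.random.default_rng(1))
            model2.net.layers[0].W = model.net.layers[0].W / s
            assert np.allclose(model2.reconstruct(z * s), base, atol=1e-9)

    def test_shape_mismatch(self, rng):
        model = DecoderModel(dense_linear_spec(3, 8), rng=rng)
        with pytest.raises(ShapeError):
            model.reconstruct(np.ones((2, 4)))


class TestSpecValidation:
    def test_dims_must_chain(self):
        with pytest.raises(ConfigError):
            DecoderSpec([
                LayerSpec("dense-linear", 3, 5),
                LayerSpec("dense-linear", 4, 8),
            ])

    def test_bce_requires_sigmoid(self):
        with pytest.raises(ConfigError):
            DecoderSpec([LayerSpec("dense-linear", 3, 5)], loss="binary-cross-entropy")

    def test_sparse_layer_requires_mask(self):
        with pytest.raises(ConfigError):
            LayerSpec("sparse-linear", 3, 5)

    def test_train_config_invariants(self):
        with pytest.raises(ConfigError):
            TrainConfig(lr_weights=0.0)
        with pytest.raises(ConfigError):
            TrainConfig(momentum_reps=1.0)
        with pytest.raises(ConfigError):
            TrainConfig(epochs=0)


class TestTrainDecoder:
    def test_single_sample_interpolation(self, rng):
        """One sample, >= n free parameters: training loss approaches zero."""
        x = np.abs(rng.normal(size=(1, 6))) + 0.5
        spec = DecoderSpec(
            [LayerSpec("dense-linear", 6, 6, activation="leaky-rectifier")]
        )
        res = train_decoder(x, spec, TrainConfig(epochs=1500, seed=0, batch_size=1))
        assert res.loss_history[-1] < 1e-3 * res.loss_history[0]

    def test_loss_decreases(self, small_dataset):
        spec = sparse_linear_decoder(small_dataset.network.adjacency)
        res = train_decoder(
            small_dataset.x_train.values, spec, decoder_train_config(epochs=60, seed=0)
        )
        assert res.loss_history[-1] < res.loss_history[0]
        assert len(res.loss_history) == 60

    def test_reproducibility(self, small_dataset):
        spec = sparse_linear_decoder(small_dataset.network.adjacency)
        cfg = decoder_train_config(epochs=15, seed=42)
        a = train_decoder(small_dataset.x_train.values, spec, cfg)
        b = train_decoder(small_dataset.x_train.values, spec, cfg)
        assert np.array_equal(a.representations.values, b.representations.values)
        assert np.array_equal(a.decoder.net.layers[0].W, b.decoder.net.layers[0].W)
        assert np.array_equal(a.loss_history, b.loss_history)

    def test_masked_entries_stay_zero(self, small_dataset):
        spec = sparse_linear_decoder(small_dataset.network.adjacency)
        res = train_decoder(
            small_dataset.x_train.values, spec, decoder_train_config(epochs=20, seed=0)
        )
        W = res.decoder.net.layers[0].W
        assert (W[small_dataset.network.adjacency == 0] == 0).all()

    def test_nonneg_reps_stay_nonneg(self, small_dataset):
        spec = sparse_linear_decoder(small_dataset.network.adjacency)
        res = train_decoder(
            small_dataset.x_train.values, spec, decoder_train_config(epochs=30, seed=0)
        )
        assert (res.representations.values >= 0).all()

    def test_recovers_principal_subspace(self, linear_gaussian, trained_linear):
        """A dense linear decoder spans the top-m principal subspace (SVD oracle)."""
        W = trained_linear.decoder.net.layers[0].W
        basis = principal_subspace(linear_gaussian, 3)
        assert subspace_angle(W, basis) < 1e-2

    def test_rejects_nan(self):
        x = np.ones((4, 5))
        x[0, 0] = np.nan
        with pytest.raises(DataError):
            train_decoder(x, dense_linear_spec(2, 5), TrainConfig(epochs=5))

    def test_bce_requires_unit_interval_data(self):
        spec = DecoderSpec(
            [LayerSpec("dense-linear", 2, 5, activation="sigmoid")],
            loss="binary-cross-entropy",
        )
        with pytest.raises(DataError):
            train_decoder(np.full((3, 5), 2.0), spec, TrainConfig(epochs=5))


class TestInferRepresentations:
    def test_requires_trained_decoder(self, rng):
        model = DecoderModel(dense_linear_spec(2, 5), rng=rng)
        with pytest.raises(StateError):
            infer_representations(np.ones((2, 5)), model, TrainConfig(epochs=5))

    def test_identity_decoder_recovers_input(self, rng):
        model = DecoderModel(dense_linear_spec(4, 4), rng=rng)
        model.net.layers[0].W = np.eye(4)
        model.trained = True
        x = rng.normal(size=(3, 4))
        res = infer_representations(
            x, model, TrainConfig(epochs=2000, seed=0, batch_size=3), tol=1e-12
        )
        assert np.allclose(res.values, x, atol=1e-4)

    def test_matches_normal_equations(self, trained_linear, rng):
        """Linear decoder: inferred z equals the least-squares projection."""
        W = trained_linear.decoder.net.layers[0].W
        xnew = rng.normal(size=(5, 3)) @ W.T  # points exactly on the subspace
        res = infer_representations(
            xnew, trained_linear.decoder, TrainConfig(epochs=3000, seed=1, batch_size=5)
        )
        z_ls = np.linalg.solve(W.T @ W, W.T @ xnew.T).T
        rel = np.linalg.norm(res.values - z_ls) / np.linalg.norm(z_ls)
        assert rel < 1e-3

    def test_training_sample_reoptimization(self, small_dataset):
        """Re-inferring a training sample's representation approaches the
        training optimum."""
        spec = sparse_linear_decoder(small_dataset.network.adjacency)
        cfg = decoder_train_config(epochs=400, seed=0)
        res = train_decoder(small_dataset.x_train.values, spec, cfg)
        x0 = small_dataset.x_train.values[:1]
        z0 = res.representations.values[:1]
        train_loss = float(np.sum((res.decoder.reconstruct(z0) - x0) ** 2))
        inf = infer_representations(x0, res.decoder, cfg)
        assert inf.losses[0] <= 1.05 * train_loss + 1e-9

    def test_early_stopping_reports_epochs(self, rng):
        model = DecoderModel(dense_linear_spec(4, 4), rng=rng)
        model.net.layers[0].W = np.eye(4)
        model.trained = True
        x = rng.normal(size=(2, 4))
        res = infer_representations(
            x, model, TrainConfig(epochs=5000, seed=0, batch_size=2),
            tol=1e-8, patience=10,
        )
        assert res.n_epochs < 5000

    def test_restarts_keep_best(self, trained_linear, rng):
        xnew = rng.normal(size=(4, 30))
        one = infer_representations(
            xnew, trained_linear.decoder, TrainConfig(epochs=300, seed=3, batch_size=4)
        )
        multi = infer_representations(
            xnew, trained_linear.decoder, TrainConfig(epochs=300, seed=3, batch_size=4),
            restarts=3,
        )
        assert (multi.losses <= one.losses + 1e-12).all()


class TestCheckpoint:
    def test_save_load_round_trip(self, small_dataset, tmp_path):
        spec = sparse_linear_decoder(small_dataset.network.adjacency)
        res = train_decoder(
            small_dataset.x_train.values, spec, decoder_train_config(epochs=10, seed=0)
        )
        res.decoder.save(tmp_path / "ckpt")
        back = DecoderModel.load(tmp_path / "ckpt")
        assert back.trained
        z = small_dataset.z_test.values
        assert np.array_equal(back.reconstruct(z), res.decoder.reconstruct(z))
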