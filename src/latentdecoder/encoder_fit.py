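"""Encoders on frozen decoders, and the naive-autoencoder baseline.

Two ways to obtain an encoder after (or instead of) decoder-only training:

* :func:`train_encoder_fixed_decoder` — keep a pre-trained decoder frozen and
  train only the encoder so that ``decoder(encoder(x~))`` reconstructs the
  clean ``x``; ``x~`` may carry added Gaussian input noise (the denoising
  variant), which teaches the encoder to project off-manifold points onto the
  decoder's manifold.  Training against the composed reconstruction loss is
  equivalent to regressing the encoder onto the decoder's representations;
  the direct-regression form is available via ``z_targets``.
* :func:`train_autoencoder` — the baseline: encoder and decoder trained
  jointly end-to-end from scratch, representations being whatever the
  encoder outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._nn import Adam, LinearLayer, Network, loss_and_grad
from .decoder_core import (
    DecoderModel,
    DecoderSpec,
    LayerSpec,
    TrainConfig,
    _check_data,
    _epoch_batches,
)
from .errors import ConfigError, ShapeError, StateError, TrainingError

__all__ = [
    "EncoderSpec",
    "NoiseConfig",
    "EncoderModel",
    "AutoencoderModel",
    "dense_leaky_encoder",
    "encoder_train_config",
    "autoencoder_train_config",
    "train_encoder_fixed_decoder",
    "train_autoencoder",
]


@dataclass
class EncoderSpec:
    """Encoder architecture: layers chaining from input dim ``n`` down to the
    representation dim ``m``."""

    layers: list[LayerSpec]

    def __post_init__(self):
        if not self.layers:
            raise ConfigError("encoder needs at least one layer")
        for a, b in zip(self.layers, self.layers[1:]):
            if a.out_dim != b.in_dim:
                raise ConfigError(f"layer dims do not chain: {a.out_dim} -> {b.in_dim}")

    @property
    def input_dim(self) -> int:
        return self.layers[0].in_dim

    @property
    def rep_dim(self) -> int:
        return self.layers[-1].out_dim


def dense_leaky_encoder(n: int, m: int, slope: float = 0.1) -> EncoderSpec:
    """The benchmark encoder: one dense linear layer ``n -> m`` with
    leaky-rectifier activation (default slope 0.1)."""
    return EncoderSpec([LayerSpec("dense-linear", n, m, activation="leaky-rectifier", slope=slope)])


@dataclass(frozen=True)
class NoiseConfig:
    """Input corruption for the denoising-encoder variant: Gaussian noise of
    sd ``input_noise_sd`` drawn fresh (``draws_per_epoch`` times per sample
    per epoch); sd 0 recovers the plain fixed-decoder encoder."""

    input_noise_sd: float = 0.0
    draws_per_epoch: int = 1

    def __post_init__(self):
        if self.input_noise_sd < 0:
            raise ConfigError("input_noise_sd must be non-negative")
        if self.draws_per_epoch < 1:
            raise ConfigError("draws_per_epoch must be at least 1")


def encoder_train_config(**overrides) -> TrainConfig:
    """Benchmark settings for encoder training: Adam lr 1e-4, 500 epochs."""
    defaults = dict(lr_weights=1e-4, epochs=500)
    defaults.update(overrides)
    return TrainConfig(**defaults)


def autoencoder_train_config(**overrides) -> TrainConfig:
    """Benchmark settings for the naive autoencoder: Adam lr 1e-4, 1000 epochs."""
    defaults = dict(lr_weights=1e-4, epochs=1000)
    defaults.update(overrides)
    return TrainConfig(**defaults)


class EncoderModel:
    """A trained encoder: forward map from input space to representations."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        self.net = Network(
            [
                LinearLayer(ls.in_dim, ls.out_dim, activation=ls.activation,
                            slope=ls.slope, mask=ls.mask, rng=rng)
                for ls in spec.layers
            ]
        )
        self.trained = False
        self.loss_history: np.ndarray | None = None

    def encode(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.spec.input_dim:
            raise ShapeError(f"x has shape {x.shape}; expected (N, {self.spec.input_dim})")
        return self.net.forward(x, cache=False)


class AutoencoderModel:
    """Encoder + decoder trained jointly; representations are encoder
    outputs, reconstructions are ``decoder(encoder(x))``."""

    def __init__(self, encoder: EncoderModel, decoder: DecoderModel):
        if encoder.spec.rep_dim != decoder.rep_dim:
            raise ShapeError("encoder output dim must equal decoder representation dim")
        self.encoder = encoder
        self.decoder = decoder
        self.trained = False
        self.loss_history: np.ndarray | None = None

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.encode(x)

    def reconstruct_input(self, x: np.ndarray) -> np.ndarray:
        return self.decoder.reconstruct(self.encode(x))


def train_encoder_fixed_decoder(
    x: np.ndarray,
    decoder: DecoderModel,
    cfg: TrainConfig,
    noise: NoiseConfig = NoiseConfig(),
    encoder_spec: EncoderSpec | None = None,
    z_targets: np.ndarray | None = None,
) -> EncoderModel:
    """Train an encoder against a frozen, pre-trained decoder.

    The objective is the composed reconstruction loss
    ``L(x, decoder(encoder(x + noise)))`` with clean targets; gradients flow
    through the decoder but its weights are never updated.  If ``z_targets``
    is given, the encoder is instead regressed directly onto those
    representations with squared error (the two framings agree up to the
    decoder's conditioning).

    Raises ``StateError`` if the decoder is untrained (its weights would not
    define a meaningful manifold to project onto).
    """
    if not decoder.trained:
        raise StateError("decoder must be trained (and is kept frozen) before encoder fitting")
    x = _check_data(x, decoder.spec.loss)
    if x.shape[1] != decoder.input_dim:
        raise ShapeError(f"x has {x.shape[1]} columns; decoder expects {decoder.input_dim}")
    if encoder_spec is None:
        encoder_spec = dense_leaky_encoder(decoder.input_dim, decoder.rep_dim)
    if encoder_spec.rep_dim != decoder.rep_dim:
        raise ShapeError("encoder output dim must equal decoder representation dim")
    if z_targets is not None:
        z_targets = np.asarray(z_targets, dtype=np.float64)
        if z_targets.shape != (x.shape[0], decoder.rep_dim):
            raise ShapeError("z_targets must be (N, m) aligned with x rows")

    rng = np.random.default_rng(cfg.seed)
    encoder = EncoderModel(encoder_spec, rng=rng)
    adam = Adam(encoder.net.layers, lr=cfg.lr_weights, weight_decay=cfg.weight_decay)
    frozen = [w.copy() for w in decoder.weight_arrays()]
    N = x.shape[0]
    history = np.empty(cfg.epochs)

    for epoch in range(cfg.epochs):
        total, count = 0.0, 0
        for _ in range(noise.draws_per_epoch):
            for idx in _epoch_batches(rng, N, cfg.batch_size):
                xb = x[idx]
                if noise.input_noise_sd > 0:
                    xb_in = xb + rng.normal(0.0, noise.input_noise_sd, size=xb.shape)
                else:
                    xb_in = xb
                z = encoder.net.forward(xb_in)
                if z_targets is not None:
                    loss, g = loss_and_grad("squared-error", z, z_targets[idx])
                else:
                    out = decoder.net.forward(z)
                    loss, g = decoder.net.loss_and_grad(out, xb)
                    g = decoder.net.backward(g)  # gradients w.r.t. z; weights untouched
                encoder.net.backward(g)
                adam.step()
                total += loss * len(idx)
                count += len(idx)
        history[epoch] = total / count
        if not np.isfinite(history[epoch]):
            raise TrainingError(f"encoder training loss diverged at epoch {epoch}")

    for w_now, w_before in zip(decoder.weight_arrays(), frozen):
        if not np.array_equal(w_now, w_before):  # pragma: no cover - safety net
            raise StateError("decoder weights changed during encoder training")
    encoder.trained = True
    encoder.loss_history = history
    return encoder


def train_autoencoder(
    x: np.ndarray,
    enc_spec: EncoderSpec,
    dec_spec: DecoderSpec,
    cfg: TrainConfig,
) -> AutoencoderModel:
    """Train encoder and decoder jointly end-to-end on reconstruction loss
    (the naive baseline: no decoder pre-training, no representation table)."""
    x = _check_data(x, dec_spec.loss)
    if enc_spec.input_dim != dec_spec.input_dim:
        raise ShapeError("encoder input dim must equal decoder output dim")
    if enc_spec.rep_dim != dec_spec.rep_dim:
        raise ShapeError("encoder output dim must equal decoder representation dim")
    if x.shape[1] != dec_spec.input_dim:
        raise ShapeError(f"x has {x.shape[1]} columns; model expects {dec_spec.input_dim}")

    rng = np.random.default_rng(cfg.seed)
    encoder = EncoderModel(enc_spec, rng=rng)
    decoder = DecoderModel(dec_spec, rng=rng)
    adam = Adam(
        encoder.net.layers + decoder.net.layers,
        lr=cfg.lr_weights,
        weight_decay=cfg.weight_decay,
    )
    N = x.shape[0]
    history = np.empty(cfg.epochs)

    for epoch in range(cfg.epochs):
        total, count = 0.0, 0
        for idx in _epoch_batches(rng, N, cfg.batch_size):
            xb = x[idx]
            z = encoder.net.forward(xb)
            out = decoder.net.forward(z)
            loss, g = decoder.net.loss_and_grad(out, xb)
            g = decoder.net.backward(g)
            encoder.net.backward(g)
            adam.step()
            total += loss * len(idx)
            count += len(idx)
        history[epoch] = total / count
        if not np.isfinite(history[epoch]):
            raise TrainingError(f"autoencoder training loss diverged at epoch {epoch}")

    encoder.trained = True
    decoder.trained = True
    model = AutoencoderModel(encoder, decoder)
    model.trained = True
    model.loss_history = history
    return model
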