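"""Encoder-free representation learning: joint optimization of decoder
weights and per-sample latent codes.

A decoder ``g_w`` maps an ``m``-dimensional representation ``z`` to input
space (dimension ``n``); its image is an ``m``-dimensional manifold.  Instead
of learning an encoder, the representations ``z_1 ... z_N`` of the training
samples are treated as free parameters and the total loss

    sum_k L(x_k, g_w(z_k))

is minimized with respect to both ``w`` and all ``z_k`` by gradient descent:
weights take Adam steps (with weight decay, which also tames the scale
invariance ``g_w(z) = g_{w/s}(z s)``), representation rows take momentum-SGD
steps.  Each sample's representation receives exactly one update per epoch —
when its mini-batch is visited — while the weights accumulate updates from
every batch.

Representations of *new* samples are found the same way with the weights
frozen (:func:`infer_representations`), which is how test-set metrics are
produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._nn import ACTIVATIONS, LOSSES, Adam, LinearLayer, Network, RowMomentumSGD, loss_and_grad
from .errors import ConfigError, DataError, ShapeError, StateError, TrainingError

__all__ = [
    "LayerSpec",
    "DecoderSpec",
    "TrainConfig",
    "RepresentationTable",
    "TrainResult",
    "InferenceResult",
    "DecoderModel",
    "decoder_train_config",
    "reconstruct",
    "train_decoder",
    "infer_representations",
    "sparse_linear_decoder",
]

LAYER_KINDS = ("dense-linear", "sparse-linear")


@dataclass
class LayerSpec:
    """One layer: dense or masked (sparse) linear map plus activation."""

    kind: str
    in_dim: int
    out_dim: int
    activation: str = "none"
    slope: float = 0.1
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ConfigError(f"unknown layer kind {self.kind!r}")
        if self.activation not in ACTIVATIONS:
            raise ConfigError(f"unknown activation {self.activation!r}")
        if self.in_dim < 1 or self.out_dim < 1:
            raise ConfigError("layer dimensions must be positive")
        if self.kind == "sparse-linear":
            if self.mask is None:
                raise ConfigError("sparse-linear layer requires a mask")
            self.mask = np.asarray(self.mask, dtype=np.float64)
            if self.mask.shape != (self.out_dim, self.in_dim):
                raise ShapeError(
                    f"mask shape {self.mask.shape} != ({self.out_dim}, {self.in_dim})"
                )
        elif self.mask is not None:
            raise ConfigError("dense-linear layer must not carry a mask")


@dataclass
class DecoderSpec:
    """Architecture of a decoder: layers chaining from rep dim ``m`` to input
    dim ``n``, plus the reconstruction loss."""

    layers: list[LayerSpec]
    loss: str = "squared-error"

    def __post_init__(self):
        if not self.layers:
            raise ConfigError("decoder needs at least one layer")
        if self.loss not in LOSSES:
            raise ConfigError(f"unknown loss {self.loss!r}")
        for a, b in zip(self.layers, self.layers[1:]):
            if a.out_dim != b.in_dim:
                raise ConfigError(f"layer dims do not chain: {a.out_dim} -> {b.in_dim}")
        if self.loss == "binary-cross-entropy" and self.layers[-1].activation != "sigmoid":
            raise ConfigError("binary-cross-entropy requires a final sigmoid activation")

    @property
    def rep_dim(self) -> int:
        return self.layers[0].in_dim

    @property
    def input_dim(self) -> int:
        return self.layers[-1].out_dim


def sparse_linear_decoder(adjacency: np.ndarray, loss: str = "squared-error") -> DecoderSpec:
    """Single sparse linear layer masked by a regulator->gene adjacency
    ``(n, m)``, rectified output — the decoder matching the regulatory
    simulator's functional form (no bias)."""
    adjacency = np.asarray(adjacency)
    n, m = adjacency.shape
    return DecoderSpec(
        layers=[LayerSpec("sparse-linear", m, n, activation="rectifier", mask=adjacency)],
        loss=loss,
    )


@dataclass
class TrainConfig:
    """Optimizer hyperparameters for joint decoder/representation training.

    Defaults are the regulatory-benchmark settings: Adam lr 1e-3 with weight
    decay 1e-5 for weights, momentum-SGD lr 1e-2 (momentum 0.9) for
    representation rows, mini-batches of 32, 500 epochs.

    ``rep_init`` selects the representation initializer: ``"normal"`` draws
    ``N(0, rep_init_sd^2)`` (the generic choice for unconstrained latent
    spaces); ``"uniform-nonneg"`` draws ``U[0, rep_init_sd)``, used together
    with ``nonneg_reps`` for latent factors that are physical concentrations.

    ``nonneg_reps`` switches the representation updates to projected
    gradient descent on the non-negative orthant.  A masked linear decoder
    is identifiable only up to a per-dimension sign; when the latents are
    known non-negative (regulator levels), the projection removes the
    sign-flipped solutions, so the recovered dimensions carry the true
    orientation.
    """

    lr_weights: float = 1e-3
    lr_reps: float = 1e-2
    momentum_reps: float = 0.9
    weight_decay: float = 1e-5
    batch_size: int = 32
    epochs: int = 500
    seed: int = 0
    rep_init_sd: float = 0.1
    rep_init: str = "normal"
    nonneg_reps: bool = False

    def __post_init__(self):
        if self.lr_weights <= 0 or self.lr_reps <= 0:
            raise ConfigError("learning rates must be positive")
        if not (0.0 <= self.momentum_reps < 1.0):
            raise ConfigError("momentum_reps must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ConfigError("weight_decay must be non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("batch_size and epochs must be positive integers")
        if self.rep_init not in ("normal", "uniform-nonneg"):
            raise ConfigError(f"unknown rep_init {self.rep_init!r}")
        if self.rep_init_sd <= 0:
            raise ConfigError("rep_init_sd must be positive")


def decoder_train_config(**overrides) -> TrainConfig:
    """Benchmark preset for the regulatory data: published learning rates
    plus non-negative (projected) representation optimization from a small
    positive init."""
    defaults = dict(rep_init="uniform-nonneg", nonneg_reps=True)
    defaults.update(overrides)
    return TrainConfig(**defaults)


@dataclass
class RepresentationTable:
    """Learned representations: one ``m``-vector per training sample."""

    values: np.ndarray
    sample_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("representation table must be 2-D")
        if not np.isfinite(self.values).all():
            raise DataError("representation table contains non-finite entries")
        if self.sample_ids is not None and len(self.sample_ids) != self.values.shape[0]:
            raise ShapeError("sample_ids length must equal the number of rows")


class DecoderModel:
    """A decoder with concrete weight values.

    Built untrained from a :class:`DecoderSpec` (seeded init) and marked
    trained by :func:`train_decoder`; only trained models may be used for
    inference.
    """

    CHECKPOINT_FORMAT = "latentdecoder-checkpoint-v1"

    def __init__(self, spec: DecoderSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        self.net = Network(
            [
                LinearLayer(
                    ls.in_dim, ls.out_dim, activation=ls.activation,
                    slope=ls.slope, mask=ls.mask, rng=rng,
                )
                for ls in spec.layers
            ],
            loss=spec.loss,
        )
        self.trained = False

    @property
    def rep_dim(self) -> int:
        return self.spec.rep_dim

    @property
    def input_dim(self) -> int:
        return self.spec.input_dim

    def reconstruct(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        if z.ndim != 2 or z.shape[1] != self.rep_dim:
            raise ShapeError(f"z has shape {z.shape}; expected (N, {self.rep_dim})")
        return self.net.forward(z, cache=False)

    def weight_arrays(self) -> list[np.ndarray]:
        return self.net.weight_arrays()

    # -- checkpointing -------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays = {}
        layer_meta = []
        for i, (ls, layer) in enumerate(zip(self.spec.layers, self.net.layers)):
            arrays[f"W{i}"] = layer.W
            if ls.mask is not None:
                arrays[f"mask{i}"] = ls.mask
            layer_meta.append(
                {
                    "kind": ls.kind, "in_dim": ls.in_dim, "out_dim": ls.out_dim,
                    "activation": ls.activation, "slope": ls.slope,
                    "has_mask": ls.mask is not None,
                }
            )
        np.savez(out / "weights.npz", **arrays)
        meta = {
            "format": self.CHECKPOINT_FORMAT,
            "loss": self.spec.loss,
            "layers": layer_meta,
            "trained": self.trained,
        }
        (out / "model.json").write_text(json.dumps(meta, indent=2))
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "DecoderModel":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "model.json").read_text())
        if meta.get("format") != cls.CHECKPOINT_FORMAT:
            raise ConfigError(f"unrecognized checkpoint format {meta.get('format')!r}")
        arrays = np.load(in_dir / "weights.npz")
        layers = []
        for i, lm in enumerate(meta["layers"]):
            mask = arrays[f"mask{i}"] if lm["has_mask"] else None
            layers.append(
                LayerSpec(lm["kind"], lm["in_dim"], lm["out_dim"], lm["activation"],
                          lm["slope"], mask)
            )
        model = cls(DecoderSpec(layers, loss=meta["loss"]))
        for i, layer in enumerate(model.net.layers):
            layer.W = np.array(arrays[f"W{i}"])
        model.trained = bool(meta["trained"])
        return model


@dataclass
class TrainResult:
    """Outcome of joint training: trained decoder, the representation table,
    and per-epoch mean training loss."""

    decoder: DecoderModel
    representations: RepresentationTable
    loss_history: np.ndarray


@dataclass
class InferenceResult:
    """Representations inferred on a frozen decoder, with per-sample final
    losses and the number of epochs actually run."""

    values: np.ndarray
    losses: np.ndarray
    n_epochs: int


def reconstruct(decoder: DecoderModel, z: np.ndarray) -> np.ndarray:
    """Forward map ``g_w(z)`` for a batch of representations."""
    return decoder.reconstruct(z)


def _check_data(x: np.ndarray, loss: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ShapeError("x must be a 2-D matrix with at least one row")
    if not np.isfinite(x).all():
        raise DataError("x contains NaN or Inf")
    if loss == "binary-cross-entropy" and (x.min() < 0 or x.max() > 1):
        raise DataError("binary-cross-entropy requires data in [0, 1]")
    return x


def _init_reps(rng: np.random.Generator, shape: tuple[int, int], cfg: TrainConfig) -> np.ndarray:
    if cfg.rep_init == "uniform-nonneg":
        return rng.uniform(0.0, cfg.rep_init_sd, size=shape)
    return rng.normal(0.0, cfg.rep_init_sd, size=shape)


def _epoch_batches(rng: np.random.Generator, N: int, batch_size: int) -> list[np.ndarray]:
    perm = rng.permutation(N)
    return [perm[i : i + batch_size] for i in range(0, N, batch_size)]


def train_decoder(
    x: np.ndarray,
    spec: DecoderSpec,
    cfg: TrainConfig,
    z_init: np.ndarray | None = None,
) -> TrainResult:
    """Jointly optimize decoder weights and training-sample representations.

    Parameters
    ----------
    x
        Training matrix, shape ``(N, n)``; non-negative for squared-error on
        expression data, within ``[0, 1]`` for binary-cross-entropy.
    spec
        Decoder architecture and loss.
    cfg
        Optimizer settings; ``cfg.seed`` fixes weight init, representation
        init and batch shuffling, so identical inputs give identical results.
    z_init
        Optional explicit ``(N, m)`` initial representations, overriding
        ``cfg.rep_init``.

    Returns
    -------
    TrainResult
        Trained decoder (marked ``trained``), representation table and the
        per-epoch mean training loss.
    """
    x = _check_data(x, spec.loss)
    N = x.shape[0]
    if x.shape[1] != spec.input_dim:
        raise ShapeError(f"x has {x.shape[1]} columns; decoder expects {spec.input_dim}")
    rng = np.random.default_rng(cfg.seed)
    model = DecoderModel(spec, rng=rng)
    if z_init is not None:
        Z = np.array(z_init, dtype=np.float64)
        if Z.shape != (N, spec.rep_dim):
            raise ShapeError(f"z_init has shape {Z.shape}; expected ({N}, {spec.rep_dim})")
    else:
        Z = _init_reps(rng, (N, spec.rep_dim), cfg)

    adam = Adam(model.net.layers, lr=cfg.lr_weights, weight_decay=cfg.weight_decay)
    rep_opt = RowMomentumSGD(Z, lr=cfg.lr_reps, momentum=cfg.momentum_reps,
                             nonneg=cfg.nonneg_reps)
    history = np.empty(cfg.epochs)

    for epoch in range(cfg.epochs):
        total, count = 0.0, 0
        for idx in _epoch_batches(rng, N, cfg.batch_size):
            out = model.net.forward(Z[idx])
            loss, g = model.net.loss_and_grad(out, x[idx])
            g_z = model.net.backward(g)
            adam.step()
            rep_opt.step(idx, g_z)
            total += loss * len(idx)
            count += len(idx)
        history[epoch] = total / count
        if not np.isfinite(history[epoch]):
            raise TrainingError(f"training loss diverged at epoch {epoch}")

    model.trained = True
    return TrainResult(
        decoder=model,
        representations=RepresentationTable(values=Z),
        loss_history=history,
    )


def infer_representations(
    x_new: np.ndarray,
    decoder: DecoderModel,
    cfg: TrainConfig,
    tol: float = 1e-6,
    patience: int = 20,
    restarts: int = 1,
) -> InferenceResult:
    """Find representations for new samples on a frozen, trained decoder.

    Runs the same per-sample momentum-SGD updates as training, with weights
    fixed, for at most ``cfg.epochs`` epochs; stops early once the mean loss
    improves by less than ``tol`` for ``patience`` consecutive epochs.  With
    ``restarts > 1`` the optimization is repeated from ``restarts`` seeded
    initializations and each sample keeps its lowest-loss solution (a guard
    against the rare local minimum).
    """
    if not decoder.trained:
        raise StateError("decoder must be trained before inferring representations")
    x_new = _check_data(x_new, decoder.spec.loss)
    if x_new.shape[1] != decoder.input_dim:
        raise ShapeError(
            f"x_new has {x_new.shape[1]} columns; decoder expects {decoder.input_dim}"
        )
    if restarts < 1:
        raise ConfigError("restarts must be at least 1")
    N = x_new.shape[0]
    best_vals: np.ndarray | None = None
    best_losses: np.ndarray | None = None
    epochs_run = 0

    for r in range(restarts):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, r)))
        Z = _init_reps(rng, (N, decoder.rep_dim), cfg)
        rep_opt = RowMomentumSGD(Z, lr=cfg.lr_reps, momentum=cfg.momentum_reps,
                                 nonneg=cfg.nonneg_reps)
        prev, stall = np.inf, 0
        for epoch in range(cfg.epochs):
            total, count = 0.0, 0
            for idx in _epoch_batches(rng, N, cfg.batch_size):
                out = decoder.net.forward(Z[idx])
                loss, g = decoder.net.loss_and_grad(out, x_new[idx])
                g_z = decoder.net.backward(g)
                rep_opt.step(idx, g_z)
                total += loss * len(idx)
                count += len(idx)
            mean_loss = total / count
            if not np.isfinite(mean_loss):
                raise TrainingError(f"inference loss diverged at epoch {epoch}")
            stall = stall + 1 if prev - mean_loss < tol else 0
            prev = mean_loss
            epochs_run = epoch + 1
            if stall >= patience:
                break
        losses = _per_sample_losses(decoder, Z, x_new)
        if best_vals is None:
            best_vals, best_losses = Z, losses
        else:
            better = losses < best_losses
            best_vals[better] = Z[better]
            best_losses[better] = losses[better]

    return InferenceResult(values=best_vals, losses=best_losses, n_epochs=epochs_run)


def _per_sample_losses(decoder: DecoderModel, Z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-sample loss in the training convention (sum over output dims)."""
    out = decoder.net.forward(Z, cache=False)
    if decoder.spec.loss == "squared-error":
        return np.sum((out - x) ** 2, axis=1)
    p = np.clip(out, 1e-12, 1.0 - 1e-12)
    return -np.sum(x * np.log(p) + (1.0 - x) * np.log1p(-p), axis=1)
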