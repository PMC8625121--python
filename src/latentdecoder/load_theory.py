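"""Load theory: data constraints per trainable parameter.

A decoder trained jointly with per-sample representations must satisfy
``N * n`` reconstruction constraints (one per sample per input unit) using
``C_d`` weight parameters plus ``N * m`` representation parameters::

    alpha_d = N n / (C_d + N m)

An encoder regressed onto fixed representations faces ``N * m`` constraints
with ``C_e`` weights::

    alpha_e = m N / C_e

A load above 1 means the model is over-determined by the data (the desirable
regime); below 1 it can interpolate noise.  When the encoder and decoder have
equal complexity the two loads are linked by

    alpha_d = (n / m) * alpha_e / (1 + alpha_e),

so the decoder load approaches the compression rate ``n/m`` for large
``alpha_e`` and is ``n/m`` times larger for small ``alpha_e`` — the decoder
is generally far better specified by the same data than the encoder.

Complexity ``C`` is approximated by the count of trainable multiplicative
weight entries: masked entries are never trainable and are excluded, and
biases are excluded (the models here have none, and constraint counting
concerns the multiplicative map).  The weight count upper-bounds the
effective parameter count, so computed loads are conservative
(underestimated).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConfigError, ShapeError

__all__ = [
    "ModelComplexity",
    "LoadReport",
    "count_complexity",
    "decoder_load",
    "encoder_load",
    "load_relation",
]


@dataclass(frozen=True)
class ModelComplexity:
    """Count of trainable weight entries (mask-aware, biases excluded)."""

    n_weight_params: int

    def __post_init__(self):
        if self.n_weight_params < 0:
            raise ConfigError("n_weight_params must be non-negative")

    def __int__(self) -> int:
        return self.n_weight_params


def _as_count(c) -> int:
    return int(c) if isinstance(c, ModelComplexity) else int(c)


def count_complexity(model_spec) -> ModelComplexity:
    """Sum trainable weight entries over a layer list.

    ``model_spec`` is a sequence of layers, each either an object with
    ``in_dim``/``out_dim`` (and optional ``mask``) attributes or a mapping
    with those keys.  For masked layers only nonzero mask entries count.
    """
    total = 0
    for layer in model_spec:
        if isinstance(layer, dict):
            in_dim, out_dim = layer["in_dim"], layer["out_dim"]
            mask = layer.get("mask")
        else:
            in_dim, out_dim = layer.in_dim, layer.out_dim
            mask = getattr(layer, "mask", None)
        if in_dim < 1 or out_dim < 1:
            raise ShapeError("layer dimensions must be positive")
        if mask is None:
            total += int(in_dim) * int(out_dim)
        else:
            mask = np.asarray(mask)
            if mask.size != int(in_dim) * int(out_dim):
                raise ShapeError(
                    f"mask size {mask.size} inconsistent with layer "
                    f"{in_dim}x{out_dim}"
                )
            total += int(np.count_nonzero(mask))
    return ModelComplexity(total)


def decoder_load(N: int, n: int, m: int, c_d) -> float:
    """Decoder load ``alpha_d = N n / (C_d + N m)``.

    Strictly increasing in ``N`` with supremum ``n/m`` (attained only at
    ``C_d = 0``).
    """
    if N < 1 or n < 1 or m < 1:
        raise ConfigError("N, n and m must be positive integers")
    c = _as_count(c_d)
    return (N * n) / (c + N * m)


def encoder_load(N: int, m: int, c_e) -> float:
    """Encoder load ``alpha_e = m N / C_e`` for an encoder trained against
    fixed representations."""
    if N < 0 or m < 1:
        raise ConfigError("N must be non-negative and m positive")
    c = _as_count(c_e)
    if c == 0:
        raise ConfigError("encoder load undefined for zero complexity")
    return (m * N) / c


def load_relation(alpha_e: float, n: int, m: int) -> float:
    """Decoder load implied by an encoder load under equal complexity:
    ``(n/m) * alpha_e / (1 + alpha_e)``."""
    if alpha_e < 0:
        raise ConfigError("alpha_e must be non-negative")
    if n < 1 or m < 1:
        raise ConfigError("n and m must be positive")
    return (n / m) * alpha_e / (1.0 + alpha_e)


@dataclass(frozen=True)
class LoadReport:
    """Loads for one experimental configuration."""

    n_samples: int
    input_dim: int
    rep_dim: int
    decoder_load: float
    encoder_load: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def load_report(
    N: int,
    n: int,
    m: int,
    decoder_spec,
    encoder_spec=None,
) -> LoadReport:
    """Compute a :class:`LoadReport` from layer lists (see
    :func:`count_complexity`)."""
    c_d = count_complexity(decoder_spec)
    alpha_e = None
    if encoder_spec is not None:
        alpha_e = encoder_load(N, m, count_complexity(encoder_spec))
    return LoadReport(
        n_samples=N,
        input_dim=n,
        rep_dim=m,
        decoder_load=decoder_load(N, n, m, c_d),
        encoder_load=alpha_e,
    )
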