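"""Model scoring: latent recovery (Pearson correlation), reconstruction
error, and the linear-case principal-subspace oracle.

Latent recovery is measured per regulator dimension: across the test
samples, the Pearson correlation between a regulator's true levels and the
corresponding learned representation column.  Alignment by index is valid
when the decoder's sparsity mask is the true adjacency, which makes hidden
units identifiable as specific regulators.  The correlation is invariant to
the per-dimension positive rescaling that the model family cannot determine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.linalg import orth, subspace_angles, svd

from .decoder_core import DecoderModel, TrainConfig, TrainResult, infer_representations
from .encoder_fit import AutoencoderModel, EncoderModel
from .errors import RankError, ShapeError

__all__ = [
    "EvalReport",
    "representation_pcc",
    "principal_subspace",
    "subspace_angle",
    "evaluate_model",
]


@dataclass
class EvalReport:
    """Test-set metrics for one model."""

    test_mse: float
    per_dimension_pcc: np.ndarray
    mean_pcc: float
    model_tag: str

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_dimension_pcc"] = list(self.per_dimension_pcc)
        return d


def representation_pcc(
    z_true: np.ndarray, z_learned: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-dimension Pearson correlation between true and learned
    representations, plus the unweighted mean over dimensions.

    A dimension with zero variance in either matrix is undefined; it is
    reported as NaN, excluded from the mean, and flagged with a warning.
    """
    z_true = np.asarray(z_true, dtype=np.float64)
    z_learned = np.asarray(z_learned, dtype=np.float64)
    if z_true.shape != z_learned.shape or z_true.ndim != 2:
        raise ShapeError(f"shapes differ: {z_true.shape} vs {z_learned.shape}")
    a = z_true - z_true.mean(axis=0)
    b = z_learned - z_learned.mean(axis=0)
    sa = np.sqrt((a * a).sum(axis=0))
    sb = np.sqrt((b * b).sum(axis=0))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (a * b).sum(axis=0) / denom
    bad = denom == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} dimension(s) have zero variance; PCC undefined there",
            RuntimeWarning,
            stacklevel=2,
        )
        pcc[bad] = np.nan
    mean = float(np.nanmean(pcc)) if (~bad).any() else float("nan")
    return pcc, mean


def principal_subspace(x: np.ndarray, m: int) -> np.ndarray:
    """Orthonormal basis (``n x m``) of the top-``m`` principal subspace of
    column-centered ``x`` — the linear manifold minimizing the summed squared
    distance between the samples and their projections."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ShapeError("x must be 2-D")
    xc = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if m > rank:
        raise RankError(f"requested {m} components but centered data have rank {rank}")
    _, _, vt = svd(xc, full_matrices=False)
    return vt[:m].T


def subspace_angle(basis_a: np.ndarray, basis_b: np.ndarray) -> float:
    """Largest principal angle (radians) between the column spans of two
    full-column-rank bases; 0 iff the spans coincide."""
    basis_a = np.asarray(basis_a, dtype=np.float64)
    basis_b = np.asarray(basis_b, dtype=np.float64)
    for name, b in (("basis_a", basis_a), ("basis_b", basis_b)):
        if b.ndim != 2:
            raise ShapeError(f"{name} must be 2-D")
        if np.linalg.matrix_rank(b) < b.shape[1]:
            raise RankError(f"{name} is rank deficient")
    return float(np.max(subspace_angles(orth(basis_a), orth(basis_b))))


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def evaluate_model(
    model,
    test_x: np.ndarray,
    z_true: np.ndarray,
    cfg: TrainConfig | None = None,
    **infer_kwargs,
) -> EvalReport:
    """Score a trained model on held-out data.

    For a decoder (``TrainResult`` or ``DecoderModel``) test representations
    are found by gradient descent on the frozen weights
    (:func:`infer_representations`, which needs ``cfg``); for encoder and
    autoencoder models they are a forward pass.  Reports test MSE of the
    reconstructions and per-dimension / mean PCC against the true regulator
    levels.
    """
    test_x = np.asarray(test_x, dtype=np.float64)
    z_true = np.asarray(z_true, dtype=np.float64)
    if isinstance(model, TrainResult):
        model = model.decoder
    if isinstance(model, DecoderModel):
        if cfg is None:
            raise ValueError("decoder evaluation requires a TrainConfig for inference")
        inferred = infer_representations(test_x, model, cfg, **infer_kwargs)
        z_hat = inferred.values
        recon = model.reconstruct(z_hat)
        tag = "decoder"
    elif isinstance(model, AutoencoderModel):
        z_hat = model.encode(test_x)
        recon = model.decoder.reconstruct(z_hat)
        tag = "autoencoder"
    elif isinstance(model, EncoderModel):
        raise ShapeError(
            "a bare encoder cannot reconstruct; pass (encoder, decoder) as an "
            "AutoencoderModel or use evaluate_encoder_on_decoder"
        )
    else:
        raise TypeError(f"cannot evaluate object of type {type(model).__name__}")
    pcc, mean = representation_pcc(z_true, z_hat)
    return EvalReport(test_mse=_mse(recon, test_x), per_dimension_pcc=pcc,
                      mean_pcc=mean, model_tag=tag)


def evaluate_encoder_on_decoder(
    encoder: EncoderModel,
    decoder: DecoderModel,
    test_x: np.ndarray,
    z_true: np.ndarray,
) -> EvalReport:
    """Score a fixed-decoder encoder: representations are the encoder's
    forward pass, reconstructions go through the frozen decoder."""
    z_hat = encoder.encode(np.asarray(test_x, dtype=np.float64))
    recon = decoder.reconstruct(z_hat)
    pcc, mean = representation_pcc(z_true, z_hat)
    return EvalReport(test_mse=_mse(recon, test_x), per_dimension_pcc=pcc,
                      mean_pcc=mean, model_tag="encoder")
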