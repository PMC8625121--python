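"""Sparse gene-regulatory expression simulator.

Expression of ``n`` genes is driven by ``m`` transcription-factor levels
through a weighted bipartite graph::

    x_i = ReLU( sum_j a_ij * w_ij * z_j + eps_i )

where ``A = (a_ij)`` is a sparse binary adjacency matrix (which regulators
bind near which genes), ``W = (w_ij)`` holds the signed regulation strengths,
``z`` are the regulator levels (gamma-distributed, hence non-negative and
right-skewed like real abundances), and ``eps`` is optional Gaussian noise
added before rectification.  Regulation is direct and regulators act
independently; there are no regulator-regulator interactions or dynamics.

The simulator retains the ground-truth regulator levels so that learned
representations can be scored against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ShapeError

__all__ = [
    "RegNetConfig",
    "RegulatoryNetwork",
    "RegulatorMatrix",
    "ExpressionMatrix",
    "Dataset",
    "default_config",
    "noiseless_config",
    "make_network",
    "sample_regulators",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class RegNetConfig:
    """Configuration of the regulatory network and its sampling distributions.

    Parameters
    ----------
    n_genes
        Number of genes ``n`` (input-space dimension).
    n_regulators
        Number of transcription factors ``m``; must satisfy ``m < n``.
    connectivity
        Fraction of nonzero entries in the adjacency matrix, in ``(0, 1]``.
        The count of ones is exactly ``round(connectivity * n * m)``.
    weight_low, weight_high
        Bounds of the uniform distribution for regulation strengths
        ``w_ij`` (sign encodes activation vs. repression).
    gamma_shape, gamma_scale
        Parameters of the gamma distribution for regulator levels.  The
        default (shape 0.5, scale 2; mean 1) is the bursty regime of the
        standard transcriptional-bursting model of protein abundance: most
        factors sit near zero in any one sample with occasional high
        levels, as sequence-specific TFs do.
    noise_sd
        Standard deviation of the Gaussian noise added inside the
        rectifier; ``0`` gives a deterministic map from ``z`` to ``x``.
    seed
        Base seed; network structure, regulator draws and noise use
        deterministic sub-streams of it.
    """

    n_genes: int = 1000
    n_regulators: int = 100
    connectivity: float = 0.1
    weight_low: float = -1.0
    weight_high: float = 1.0
    gamma_shape: float = 0.5
    gamma_scale: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes >= 1):
            raise ConfigError("n_genes must be a positive integer")
        if not (isinstance(self.n_regulators, (int, np.integer)) and self.n_regulators >= 1):
            raise ConfigError("n_regulators must be a positive integer")
        if self.n_genes <= self.n_regulators:
            raise ConfigError("n_genes must exceed n_regulators")
        if not (0.0 < self.connectivity <= 1.0):
            raise ConfigError("connectivity must lie in (0, 1]")
        if not (self.weight_low < self.weight_high):
            raise ConfigError("weight_low must be below weight_high")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ConfigError("gamma_shape and gamma_scale must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def default_config(**overrides) -> RegNetConfig:
    """The noisy generator: n=1000 genes, m=100 regulators, 10% connectivity,
    noise sd 0.2."""
    return RegNetConfig(**overrides)


def noiseless_config(**overrides) -> RegNetConfig:
    """The headline benchmark condition: same network, zero observation noise."""
    overrides.setdefault("noise_sd", 0.0)
    return RegNetConfig(**overrides)


@dataclass
class RegulatoryNetwork:
    """Bipartite regulator-to-gene graph: binary adjacency plus signed weights,
    both of shape ``(n_genes, n_regulators)``."""

    adjacency: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.adjacency.shape != self.weights.shape or self.adjacency.ndim != 2:
            raise ShapeError("adjacency and weights must be 2-D with equal shapes")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ConfigError("adjacency entries must be 0 or 1")
        if not np.isfinite(self.weights).all():
            raise ConfigError("weights must be finite")

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_regulators(self) -> int:
        return self.adjacency.shape[1]

    @property
    def effective_weights(self) -> np.ndarray:
        """Elementwise product ``A * W`` — the linear map actually applied."""
        return self.adjacency * self.weights


@dataclass
class RegulatorMatrix:
    """``N x m`` matrix of non-negative regulator levels (one row per sample)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ShapeError("regulator matrix must be 2-D with at least one row")
        if (self.values < 0).any():
            raise ConfigError("regulator levels must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class ExpressionMatrix:
    """``N x n`` matrix of rectified (non-negative) expression values."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("expression matrix must be 2-D")
        if (self.values < 0).any():
            raise ConfigError("expression values must be non-negative")


def make_network(config: RegNetConfig) -> RegulatoryNetwork:
    """Draw a seeded network: exact-count sparsity via a uniform permutation of
    entry positions, weights i.i.d. uniform on ``[weight_low, weight_high)``.

    The number of ones in the adjacency is exactly
    ``round(connectivity * n * m)``, so e.g. connectivity 0.1 gives exactly
    90% zeros, not merely 90% in expectation.
    """
    n, m = config.n_genes, config.n_regulators
    rng = np.random.default_rng(config.seed)
    n_ones = int(round(config.connectivity * n * m))
    flat = np.zeros(n * m, dtype=np.int8)
    flat[rng.permutation(n * m)[:n_ones]] = 1
    weights = rng.uniform(config.weight_low, config.weight_high, size=(n, m))
    return RegulatoryNetwork(adjacency=flat.reshape(n, m), weights=weights)


def sample_regulators(N: int, config: RegNetConfig, seed: int | None = None) -> RegulatorMatrix:
    """Draw ``N`` i.i.d. regulator-level vectors from the gamma prior.

    ``seed`` defaults to a sub-stream of ``config.seed`` distinct from the
    network's stream; pass an explicit value to obtain independent cohorts
    (e.g. train vs. test) from one config.
    """
    if not (isinstance(N, (int, np.integer)) and N >= 1):
        raise ConfigError("N must be a positive integer")
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 1)) if seed is None else seed
    )
    values = rng.gamma(config.gamma_shape, config.gamma_scale, size=(N, config.n_regulators))
    return RegulatorMatrix(values=values)


def simulate_expression(
    network: RegulatoryNetwork,
    z: RegulatorMatrix | np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Map regulator levels to expression: ``x = max(0, (A*W) z + eps)``.

    Noise is drawn fresh per sample and per gene and added *before*
    rectification; with ``noise_sd=0`` the output is a deterministic function
    of the network and ``z``.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    zv = z.values if isinstance(z, RegulatorMatrix) else np.asarray(z, dtype=np.float64)
    if zv.ndim != 2 or zv.shape[1] != network.n_regulators:
        raise ShapeError(
            f"z has shape {zv.shape}; expected (N, {network.n_regulators})"
        )
    pre = zv @ network.effective_weights.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pre = pre + rng.normal(0.0, noise_sd, size=pre.shape)
    return ExpressionMatrix(values=np.maximum(pre, 0.0))


@dataclass
class Dataset:
    """A simulated cohort: the generating network, train/test regulator levels
    and the corresponding expression matrices."""

    config: RegNetConfig
    network: RegulatoryNetwork
    z_train: RegulatorMatrix
    x_train: ExpressionMatrix
    z_test: RegulatorMatrix
    x_test: ExpressionMatrix
    seeds: dict = field(default_factory=dict)


def simulate_dataset(config: RegNetConfig, n_train: int, n_test: int = 100) -> Dataset:
    """Generate a full train/test cohort from one config.

    Sub-seeds for the network, the two regulator cohorts and the two noise
    draws are derived deterministically from ``config.seed``, so a dataset is
    fully regenerable from its config.
    """
    base = config.seed
    seeds = {
        "network": base,
        "z_train": int(np.random.SeedSequence((base, 1)).generate_state(1)[0] % 2**31),
        "z_test": int(np.random.SeedSequence((base, 2)).generate_state(1)[0] % 2**31),
        "noise_train": int(np.random.SeedSequence((base, 3)).generate_state(1)[0] % 2**31),
        "noise_test": int(np.random.SeedSequence((base, 4)).generate_state(1)[0] % 2**31),
    }
    network = make_network(config)
    z_train = sample_regulators(n_train, config, seed=seeds["z_train"])
    z_test = sample_regulators(n_test, config, seed=seeds["z_test"])
    x_train = simulate_expression(network, z_train, config.noise_sd, seed=seeds["noise_train"])
    x_test = simulate_expression(network, z_test, config.noise_sd, seed=seeds["noise_test"])
    return Dataset(config, network, z_train, x_train, z_test, x_test, seeds)


def _frame(values: np.ndarray, prefix_row: str, prefix_col: str) -> pd.DataFrame:
    return pd.DataFrame(
        values,
        index=[f"{prefix_row}{i}" for i in range(values.shape[0])],
        columns=[f"{prefix_col}{j}" for j in range(values.shape[1])],
    )


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write a dataset as tab-delimited matrices plus a JSON sidecar.

    Expression files have sample IDs as rows and gene IDs as columns;
    regulator files have regulator IDs as columns.  The sidecar stores the
    full config and all sub-seeds, so the files are regenerable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, mat, col in (
        ("train_expression", dataset.x_train.values, "gene"),
        ("test_expression", dataset.x_test.values, "gene"),
        ("train_regulators", dataset.z_train.values, "regulator"),
        ("test_regulators", dataset.z_test.values, "regulator"),
    ):
        _frame(mat, "sample", col).to_csv(out / f"{name}.tsv", sep="\t")
    for name, mat in (
        ("network_adjacency", dataset.network.adjacency),
        ("network_weights", dataset.network.weights),
    ):
        _frame(mat, "gene", "regulator").to_csv(out / f"{name}.tsv", sep="\t")
    sidecar = {
        "format": "latentdecoder-dataset-v1",
        "config": asdict(dataset.config),
        "seeds": dataset.seeds,
        "n_train": dataset.z_train.n_samples,
        "n_test": dataset.z_test.n_samples,
    }
    (out / "dataset.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_dataset(in_dir: str | Path) -> Dataset:
    """Regenerate a dataset from its sidecar config (the TSVs are the
    human-readable view; the sidecar is authoritative)."""
    sidecar = json.loads((Path(in_dir) / "dataset.json").read_text())
    config = RegNetConfig(**sidecar["config"])
    return simulate_dataset(config, sidecar["n_train"], sidecar["n_test"])


def read_matrix(path: str | Path) -> np.ndarray:
    """Read any delimited sample-by-feature matrix with a header row and
    row-ID column (the generic entry point for user-supplied data)."""
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=np.float64)
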