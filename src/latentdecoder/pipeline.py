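"""Load-sweep experiment: decoder vs. fixed-decoder encoder vs. naive
autoencoder across training-set sizes.

For each training size ``N`` and replicate, a fresh regulatory network and
train/test cohort are simulated (a new test set for every training set), the
three models are trained on the identical data, and test reconstruction MSE
and latent-recovery PCC are recorded together with the decoder load
``alpha_d = Nn/(C_d + Nm)``.  Varying ``N`` at fixed ``n=1000``, ``m=100``
and 10% connectivity sweeps the load from under- to over-determined.

All randomness derives from one base seed; per-run seeds are deterministic
functions of (base seed, grid index, replicate), so a sweep is reproducible
from a single number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder_core import TrainConfig, decoder_train_config, sparse_linear_decoder, train_decoder
from .encoder_fit import (
    autoencoder_train_config,
    dense_leaky_encoder,
    encoder_train_config,
    train_autoencoder,
    train_encoder_fixed_decoder,
)
from .errors import ConfigError, TrainingError
from .evaluation import evaluate_encoder_on_decoder, evaluate_model
from .load_theory import decoder_load, encoder_load
from .regulatory_sim import RegNetConfig, noiseless_config, simulate_dataset

__all__ = ["SweepConfig", "SweepResult", "run_sweep", "summarize", "default_sweep_config"]

logger = logging.getLogger(__name__)

#: Default grid of training sizes, bracketing loads alpha_d ~ 0.9 -> 9.9
#: (the under-determined, threshold and saturated regimes).
DEFAULT_N_GRID = (15, 25, 50, 100, 300, 1000, 3000, 10000, 15000)


@dataclass
class SweepConfig:
    """Configuration of a full load sweep."""

    n_train_grid: tuple = DEFAULT_N_GRID
    n_replicates: int = 5
    test_size: int = 100
    base_seed: int = 0
    net_config: RegNetConfig = field(default_factory=noiseless_config)
    decoder_cfg: TrainConfig = field(default_factory=decoder_train_config)
    encoder_cfg: TrainConfig = field(default_factory=encoder_train_config)
    ae_cfg: TrainConfig = field(default_factory=autoencoder_train_config)
    inference_epochs: int = 500
    epoch_scale_ref: int | None = None
    models: tuple = ("decoder", "encoder", "autoencoder")

    def __post_init__(self):
        if not self.n_train_grid:
            raise ConfigError("n_train_grid must be nonempty")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be at least 1")
        if self.test_size < 1:
            raise ConfigError("test_size must be at least 1")
        if "decoder" not in self.models:
            raise ConfigError("the decoder is the reference model and cannot be dropped")
        unknown = set(self.models) - {"decoder", "encoder", "autoencoder"}
        if unknown:
            raise ConfigError(f"unknown models: {sorted(unknown)}")


def default_sweep_config(**overrides) -> SweepConfig:
    return SweepConfig(**overrides)


@dataclass
class SweepResult:
    """Tidy sweep table: one row per (model, N, replicate)."""

    table: pd.DataFrame
    config: SweepConfig


class _SkipModel(Exception):
    """Internal control flow: a model excluded from cfg.models."""


def _run_seed(base_seed: int, n_index: int, replicate: int) -> int:
    return int(np.random.SeedSequence((base_seed, n_index, replicate)).generate_state(1)[0] % 2**31)


def _scaled_epochs(epochs: int, N: int, ref: int | None) -> int:
    """Reduce the epoch budget proportionally for training sizes above
    ``ref`` so the number of gradient updates stays roughly constant."""
    if ref is None or N <= ref:
        return epochs
    return max(25, int(round(epochs * ref / N)))


def _data_hash(x: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(x).tobytes()).hexdigest()[:12]


def run_sweep(cfg: SweepConfig) -> SweepResult:
    """Execute the full sweep; returns one tidy row per (model, N, replicate).

    Per run: simulate a fresh network and cohort; train the true-mask sparse
    decoder jointly with its representations; train the encoder on the frozen
    decoder; train the naive autoencoder (each model only if selected in
    ``cfg.models``); evaluate on the shared test set.  A training failure is recorded in the affected rows (``failed``
    flag, NaN metrics) and the sweep continues.
    """
    n, m = cfg.net_config.n_genes, cfg.net_config.n_regulators
    c_d = int(round(cfg.net_config.connectivity * n * m))
    c_e = n * m
    rows = []
    for n_index, N in enumerate(cfg.n_train_grid):
        for rep in range(cfg.n_replicates):
            seed = _run_seed(cfg.base_seed, n_index, rep)
            alpha_d = decoder_load(N, n, m, c_d)
            alpha_e = encoder_load(N, m, c_e)
            t0 = time.perf_counter()
            net_config = replace(cfg.net_config, seed=seed)
            ds = simulate_dataset(net_config, N, cfg.test_size)
            xh = _data_hash(ds.x_train.values)
            base = dict(N=N, replicate=rep, seed=seed, alpha_d=alpha_d,
                        alpha_e=alpha_e, train_hash=xh)
            spec = sparse_linear_decoder(ds.network.adjacency)
            dec_cfg = replace(
                cfg.decoder_cfg, seed=seed,
                epochs=_scaled_epochs(cfg.decoder_cfg.epochs, N, cfg.epoch_scale_ref),
            )
            infer_cfg = replace(dec_cfg, epochs=cfg.inference_epochs)
            enc_cfg = replace(
                cfg.encoder_cfg, seed=seed,
                epochs=_scaled_epochs(cfg.encoder_cfg.epochs, N, cfg.epoch_scale_ref),
            )
            ae_cfg = replace(
                cfg.ae_cfg, seed=seed,
                epochs=_scaled_epochs(cfg.ae_cfg.epochs, N, cfg.epoch_scale_ref),
            )

            result = None
            try:
                result = train_decoder(ds.x_train.values, spec, dec_cfg)
                rep_dec = evaluate_model(result, ds.x_test.values, ds.z_test.values, infer_cfg)
                rows.append(dict(model="decoder", test_mse=rep_dec.test_mse,
                                 mean_pcc=rep_dec.mean_pcc, failed=False, **base))
            except TrainingError as exc:
                logger.warning("decoder run failed (N=%d rep=%d): %s", N, rep, exc)
                rows.append(dict(model="decoder", test_mse=np.nan, mean_pcc=np.nan,
                                 failed=True, **base))
            try:
                if "encoder" not in cfg.models:
                    raise _SkipModel
                if result is None:
                    raise TrainingError("no pre-trained decoder available")
                encoder = train_encoder_fixed_decoder(ds.x_train.values, result.decoder, enc_cfg)
                rep_enc = evaluate_encoder_on_decoder(
                    encoder, result.decoder, ds.x_test.values, ds.z_test.values
                )
                rows.append(dict(model="encoder", test_mse=rep_enc.test_mse,
                                 mean_pcc=rep_enc.mean_pcc, failed=False, **base))
            except _SkipModel:
                pass
            except TrainingError as exc:
                logger.warning("encoder run failed (N=%d rep=%d): %s", N, rep, exc)
                rows.append(dict(model="encoder", test_mse=np.nan, mean_pcc=np.nan,
                                 failed=True, **base))
            try:
                if "autoencoder" not in cfg.models:
                    raise _SkipModel
                ae = train_autoencoder(
                    ds.x_train.values,
                    dense_leaky_encoder(n, m),
                    sparse_linear_decoder(ds.network.adjacency),
                    ae_cfg,
                )
                rep_ae = evaluate_model(ae, ds.x_test.values, ds.z_test.values)
                rows.append(dict(model="autoencoder", test_mse=rep_ae.test_mse,
                                 mean_pcc=rep_ae.mean_pcc, failed=False, **base))
            except _SkipModel:
                pass
            except TrainingError as exc:
                logger.warning("autoencoder run failed (N=%d rep=%d): %s", N, rep, exc)
                rows.append(dict(model="autoencoder", test_mse=np.nan, mean_pcc=np.nan,
                                 failed=True, **base))
            logger.info("N=%d rep=%d done in %.1fs (alpha_d=%.2f)",
                        N, rep, time.perf_counter() - t0, alpha_d)

    cols = ["model", "N", "replicate", "alpha_d", "alpha_e", "test_mse",
            "mean_pcc", "seed", "train_hash", "failed"]
    return SweepResult(table=pd.DataFrame(rows)[cols], config=cfg)


def summarize(result: SweepResult, out_dir: str | Path | None = None):
    """Aggregate a sweep per (model, N): mean and sd of test MSE and PCC.

    If ``out_dir`` is given, writes ``sweep.csv``, ``summary.csv`` and the
    two panel figures (MSE vs. load, PCC vs. load), plus a JSON snapshot of
    the sweep config.
    """
    if result.table.empty:
        raise ConfigError("cannot summarize an empty sweep result")
    g = result.table.groupby(["model", "N"], as_index=False).agg(
        alpha_d=("alpha_d", "first"),
        alpha_e=("alpha_e", "first"),
        mse_mean=("test_mse", "mean"),
        mse_sd=("test_mse", "std"),
        pcc_mean=("mean_pcc", "mean"),
        pcc_sd=("mean_pcc", "std"),
        n_failed=("failed", "sum"),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.table.to_csv(out / "sweep.csv", index=False)
        g.to_csv(out / "summary.csv", index=False)
        _write_figures(g, out)
        snapshot = asdict(result.config)
        snapshot["net_config"] = asdict(result.config.net_config)
        (out / "sweep_config.json").write_text(json.dumps(snapshot, indent=2, default=str))
    return g


def _write_figures(summary: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, sd, fname, ylabel, logy in (
        ("mse_mean", "mse_sd", "fig4_mse.png", "test MSE", True),
        ("pcc_mean", "pcc_sd", "fig4_pcc.png", "mean representation PCC", False),
    ):
        fig, ax = plt.subplots(figsize=(5, 4))
        for model, sub in summary.groupby("model"):
            sub = sub.sort_values("alpha_d")
            ax.errorbar(sub["alpha_d"], sub[metric], yerr=sub[sd],
                        marker="o", capsize=3, label=model)
        ax.set_xlabel(r"decoder load $\alpha_d$")
        ax.set_ylabel(ylabel)
        ax.set_xscale("log")
        if logy:
            ax.set_yscale("log")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / fname, dpi=150)
        plt.close(fig)
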