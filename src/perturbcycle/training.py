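"""Optimization loops: paired (joint MSE) and unpaired (adversarial + cycle).

All randomness — parameter initialization, batch order, cycle-label
sampling — flows from the single seed in the training config, so a rerun
with the same config and data reproduces the same history. Discriminator
updates see detached generator outputs and use their own optimizer, so
encoder/decoder parameters only move during generator steps.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np

from ._nn import Adam, Tensor, as_tensor, concat
from .data_io import (
    ExpressionDataset,
    PairedSet,
    PerturbationKind,
    PerturbationRecord,
    UnpairedSet,
    build_pairs,
)
from .drug_encoder import Featurization
from .losses import (
    LossWeights,
    adversarial_losses,
    cycle_loss,
    identity_loss,
    identity_loss_reverse,
    paired_mse_loss,
    reconstruction_loss,
    total_loss,
)
from .model_core import ModelConfig, ModelState

__all__ = ["TrainingConfig", "TrainingError", "train", "predict_batch"]

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    mode: str = "paired"
    epochs: int = 100
    batch_size: int = 128
    lr_gen: float = 1e-3
    lr_disc: float = 2e-4
    weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    seed: int = 0
    disc_steps_per_gen_step: int = 1
    patience: int = 20
    latent_dim: int = 128
    shared_autoencoder: bool = False
    encoder_hidden: tuple[int, ...] = (512, 256)
    decoder_hidden: tuple[int, ...] = (256, 512)
    disc_hidden: tuple[int, ...] = (256, 64)
    gat_hidden: tuple[int, int] = (64, 64)
    batchnorm: bool = True
    log_every: int = 10

    def __post_init__(self):
        if self.mode not in ("paired", "unpaired"):
            raise ValueError(f"unknown training mode '{self.mode}'")
        for name in ("epochs", "batch_size", "disc_steps_per_gen_step",
                     "patience", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.lr_gen < 0 or self.lr_disc < 0:
            raise ValueError("learning rates must be nonnegative")


def _build_model(ds: ExpressionDataset, cfg: TrainingConfig) -> ModelState:
    vocab = tuple(
        sorted(
            {
                r.target_gene
                for r in ds.records
                if r.kind == PerturbationKind.GENETIC and r.target_gene
            }
        )
    )
    if ds.graphs:
        feat_dim = next(iter(ds.graphs.values())).node_features.shape[1]
    else:
        feat_dim = Featurization().width
    mc = ModelConfig(
        n_genes=ds.n_genes,
        latent_dim=cfg.latent_dim,
        encoder_hidden=cfg.encoder_hidden,
        decoder_hidden=cfg.decoder_hidden,
        disc_hidden=cfg.disc_hidden,
        gat_hidden=cfg.gat_hidden,
        drug_feature_dim=feat_dim,
        genetic_vocabulary=vocab,
        shared_autoencoder=cfg.shared_autoencoder,
        batchnorm=cfg.batchnorm,
    )
    return ModelState(mc, seed=cfg.seed)


def _embedding_tensor(
    model: ModelState,
    records: list[PerturbationRecord],
    graphs: Optional[dict],
    cache: dict[str, Tensor],
) -> Tensor:
    """Row-stack of perturbation embeddings aligned to ``records``.

    Embeddings are tensor-valued so gradients reach the drug / genetic
    encoders; one encoder forward per unique perturbation per step.
    """
    rows = []
    for rec in records:
        key = rec.perturbation_id if rec.dose is None else f"{rec.perturbation_id}@{rec.dose}"
        if key not in cache:
            if rec.kind == PerturbationKind.CONTROL:
                emb = as_tensor(np.zeros((1, model.config.latent_dim)))
            elif rec.kind == PerturbationKind.GENETIC:
                emb = model.genetic_encoder.forward(rec.target_gene).reshape(
                    1, model.config.latent_dim
                )
            else:
                graph = graphs.get(rec.perturbation_id) if graphs else None
                if graph is None:
                    from .drug_encoder import smiles_to_graph

                    graph = smiles_to_graph(rec.smiles)
                emb = model.drug_encoder.forward(graph).reshape(1, model.config.latent_dim)
            if rec.dose is not None:
                emb = emb * model.dose_net.embedding(rec.dose).reshape(
                    1, model.config.latent_dim
                )
            cache[key] = emb
        rows.append(cache[key])
    return concat(rows, axis=0)


def _check_finite(value: float, epoch: int, step: int) -> None:
    if not np.isfinite(value):
        raise TrainingError(f"non-finite loss at epoch {epoch}, step {step}")


def train(
    ds_train: ExpressionDataset,
    ds_val: Optional[ExpressionDataset],
    cfg: TrainingConfig,
) -> tuple[ModelState, list[dict]]:
    """Fit a model; returns the best-validation checkpoint and loss history."""
    if ds_train.n_samples == 0:
        raise TrainingError("empty training dataset")
    model = _build_model(ds_train, cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])

    if cfg.mode == "paired":
        history = _train_paired(model, ds_train, ds_val, cfg, rng)
    else:
        history = _train_unpaired(model, ds_train, ds_val, cfg, rng)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# paired regime
# ---------------------------------------------------------------------------


def _paired_epoch_loss(
    model: ModelState, pairs: PairedSet, cfg: TrainingConfig
) -> float:
    """Full-set paired objective in evaluation mode (no parameter updates)."""
    model.eval()
    cache: dict[str, Tensor] = {}
    d = _embedding_tensor(model, pairs.records, pairs.graphs, cache)
    reco = reconstruction_loss(pairs.x, model)
    mse = paired_mse_loss(pairs.x, pairs.y, d, model)
    total, _ = total_loss("paired", cfg.weights, reco=reco, paired_mse=mse)
    return float(total.data)


def _train_paired(model, ds_train, ds_val, cfg, rng) -> list[dict]:
    pairs = build_pairs(ds_train, "paired")
    val_pairs = build_pairs(ds_val, "paired") if ds_val is not None else None
    n = len(pairs)
    opt = Adam(model.generator_parameters(), lr=cfg.lr_gen)
    history: list[dict] = []
    best_val = np.inf
    best_state = None
    stale = 0

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_terms: dict[str, float] = {}
        n_steps = 0
        for step, lo in enumerate(range(0, n, cfg.batch_size)):
            idx = order[lo : lo + cfg.batch_size]
            if idx.size < 2:
                continue  # batchnorm needs at least two samples
            cache: dict[str, Tensor] = {}
            recs = [pairs.records[i] for i in idx]
            d = _embedding_tensor(model, recs, pairs.graphs, cache)
            reco = reconstruction_loss(pairs.x[idx], model)
            mse = paired_mse_loss(pairs.x[idx], pairs.y[idx], d, model)
            total, breakdown = total_loss("paired", cfg.weights, reco=reco, paired_mse=mse)
            _check_finite(breakdown["total"], epoch, step)
            opt.zero_grad()
            total.backward()
            opt.step()
            for k, v in breakdown.items():
                epoch_terms[k] = epoch_terms.get(k, 0.0) + v
            n_steps += 1
        entry = {"epoch": epoch}
        entry.update({k: v / max(n_steps, 1) for k, v in epoch_terms.items()})
        val_metric = None
        if val_pairs is not None:
            val_metric = _paired_epoch_loss(model, val_pairs, cfg)
            entry["val_total"] = val_metric
        history.append(entry)
        if epoch % cfg.log_every == 0:
            logger.info("epoch=%d %s", epoch, " ".join(f"{k}={v:.4g}" for k, v in entry.items() if k != "epoch"))
        if val_metric is not None:
            if val_metric < best_val - 1e-12:
                best_val = val_metric
                best_state = {k: v.copy() for k, v in model.state_arrays().items()}
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return history


# ---------------------------------------------------------------------------
# unpaired (adversarial) regime
# ---------------------------------------------------------------------------


def _sample_cycle_records(
    treated_records: list[PerturbationRecord], n: int, rng
) -> list[PerturbationRecord]:
    """Assign each control a perturbation drawn from the batch's treated labels."""
    idx = rng.integers(0, len(treated_records), size=n)
    return [treated_records[i] for i in idx]


def _unpaired_val_loss(model, val_set: UnpairedSet, cfg, rng) -> float:
    """Validation progress metric: cycle + identity (adversarial value is
    not a progress measure)."""
    model.eval()
    cache: dict[str, Tensor] = {}
    d_y = _embedding_tensor(model, val_set.treated_records, val_set.graphs, cache)
    recs_x = _sample_cycle_records(
        val_set.treated_records, val_set.controls.shape[0], rng
    )
    d_x = _embedding_tensor(model, recs_x, val_set.graphs, cache)
    cyc = cycle_loss(val_set.controls, val_set.treated, d_x, d_y, model)
    ident = identity_loss(val_set.treated, model) + identity_loss_reverse(
        val_set.controls, model
    )
    return float(cyc.data + ident.data)


def _train_unpaired(model, ds_train, ds_val, cfg, rng) -> list[dict]:
    pool = build_pairs(ds_train, "unpaired")
    val_pool = build_pairs(ds_val, "unpaired") if ds_val is not None else None
    n_t = pool.treated.shape[0]
    n_c = pool.controls.shape[0]
    opt_gen = Adam(model.generator_parameters(), lr=cfg.lr_gen)
    opt_disc = Adam(model.discriminator_parameters(), lr=cfg.lr_disc)
    history: list[dict] = []
    best_val = np.inf
    best_state = None
    stale = 0
    val_rng = np.random.default_rng(cfg.seed + 9999)

    steps_per_epoch = max(n_t // cfg.batch_size, 1)
    for epoch in range(cfg.epochs):
        model.train()
        epoch_terms: dict[str, float] = {}
        n_steps = 0
        for step in range(steps_per_epoch):
            bi_t = rng.integers(0, n_t, size=cfg.batch_size)
            bi_c = rng.integers(0, n_c, size=cfg.batch_size)
            xb = pool.controls[bi_c]
            yb = pool.treated[bi_t]
            recs_y = [pool.treated_records[i] for i in bi_t]
            recs_x = _sample_cycle_records(recs_y, xb.shape[0], rng)

            # discriminator step(s): detached fakes, own optimizer
            for _ in range(cfg.disc_steps_per_gen_step):
                cache: dict[str, Tensor] = {}
                d_x = _embedding_tensor(model, recs_x, pool.graphs, cache)
                d_y = _embedding_tensor(model, recs_y, pool.graphs, cache)
                _, disc_fwd, _, disc_rev = adversarial_losses(
                    xb, yb, d_x, d_y, model, detach_fakes=True
                )
                disc_total = disc_fwd + disc_rev
                _check_finite(float(disc_total.data), epoch, step)
                opt_disc.zero_grad()
                model.zero_grad()
                disc_total.backward()
                opt_disc.step()

            # generator step: fresh graph
            cache = {}
            d_x = _embedding_tensor(model, recs_x, pool.graphs, cache)
            d_y = _embedding_tensor(model, recs_y, pool.graphs, cache)
            gen_fwd, _, gen_rev, _ = adversarial_losses(xb, yb, d_x, d_y, model)
            reco = reconstruction_loss(xb, model)
            cyc = cycle_loss(xb, yb, d_x, d_y, model)
            ident = identity_loss(yb, model) + identity_loss_reverse(xb, model)
            total, breakdown = total_loss(
                "unpaired",
                cfg.weights,
                reco=reco,
                gan=gen_fwd + gen_rev,
                cyc=cyc,
                identity=ident,
            )
            breakdown["disc"] = float(disc_total.data)
            _check_finite(breakdown["total"], epoch, step)
            opt_gen.zero_grad()
            model.zero_grad()
            total.backward()
            opt_gen.step()
            for k, v in breakdown.items():
                epoch_terms[k] = epoch_terms.get(k, 0.0) + v
            n_steps += 1

        entry = {"epoch": epoch}
        entry.update({k: v / max(n_steps, 1) for k, v in epoch_terms.items()})
        val_metric = None
        if val_pool is not None:
            val_metric = _unpaired_val_loss(model, val_pool, cfg, val_rng)
            entry["val_cyc_identity"] = val_metric
        history.append(entry)
        if epoch % cfg.log_every == 0:
            logger.info("epoch=%d %s", epoch, " ".join(f"{k}={v:.4g}" for k, v in entry.items() if k != "epoch"))
        if val_metric is not None:
            if val_metric < best_val - 1e-12:
                best_val = val_metric
                best_state = {k: v.copy() for k, v in model.state_arrays().items()}
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return history


# ---------------------------------------------------------------------------
# batch prediction
# ---------------------------------------------------------------------------


def predict_batch(
    ds: ExpressionDataset, model: ModelState, direction: str = "forward"
) -> ExpressionDataset:
    """Predict one treated profile per treated record (forward) or one
    restored control per treated record (reverse).

    Forward prediction starts from each treated row's paired control when a
    pairing map exists, otherwise from the dataset's mean control profile.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction '{direction}'")
    model.eval()
    treated = ds.treated_rows()
    if treated.size == 0:
        return ExpressionDataset(
            np.zeros((0, ds.n_genes)), [], ds.gene_ids, graphs=ds.graphs
        )
    ctrl_rows = ds.control_rows()
    mean_control = (
        ds.matrix[ctrl_rows].mean(axis=0) if ctrl_rows.size else np.zeros(ds.n_genes)
    )

    out = np.zeros((treated.size, ds.n_genes))
    # group rows by perturbation so each embedding is computed once
    by_pert: dict[str, list[int]] = {}
    for k, i in enumerate(treated):
        key = ds.records[i].perturbation_id
        dose = ds.records[i].dose
        by_pert.setdefault(f"{key}@{dose}", []).append(k)
    for rows in by_pert.values():
        rec = ds.records[treated[rows[0]]]
        d = model.resolve_embedding(rec, graphs=ds.graphs)
        if direction == "forward":
            starts = np.stack(
                [
                    ds.matrix[ds.pairing[treated[k]]]
                    if ds.pairing is not None and treated[k] in ds.pairing
                    else mean_control
                    for k in rows
                ]
            )
            z = model.encode_control_t(starts).data
            out[rows] = model.decode_treated_t(as_tensor(z + d.vector)).data
        else:
            ys = ds.matrix[treated[rows]]
            z = model.encode_treated_t(ys).data
            out[rows] = model.decode_control_t(as_tensor(z - d.vector)).data
    return ExpressionDataset(
        out, [ds.records[i] for i in treated], ds.gene_ids, graphs=ds.graphs
    )
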