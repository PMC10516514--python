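"""Model fitting: MSE loss, Adadelta, cross-validation, and ensembling.

The training protocol is R repeats of F-fold cross-validation (10 x 5 by
default) with fresh random initialization per model; final predictions
average the eval-mode outputs of all R*F models.  Artificial negatives
join every training partition but never a validation partition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .data import (
    DatasetTable,
    Origin,
    add_artificial_negatives,
    encode_peptide,
    encode_pseudo,
)
from .model import Model, ModelConfig

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    batch_size: int = 128
    epochs: int = 50
    learning_rate: float = 0.9
    weight_decay: float = 1e-4
    scheduler_patience: int = 5
    scheduler_factor: float = 0.1
    repeats: int = 10
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1 or self.folds < 2:
            raise ValueError("need repeats >= 1 and folds >= 2")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


class Adadelta:
    """Adadelta with decoupled-from-nothing (classic L2) weight decay.

    Per-parameter running averages of squared gradients and squared
    updates (rho = 0.9, eps = 1e-6); ``lr`` scales the computed step.
    """

    def __init__(self, params: dict[str, ad.Tensor], lr: float = 0.9,
                 rho: float = 0.9, eps: float = 1e-6, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.weight_decay = weight_decay
        self._sq_grad = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._sq_delta = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            sg, sd = self._sq_grad[k], self._sq_delta[k]
            sg *= self.rho
            sg += (1 - self.rho) * g * g
            delta = np.sqrt(sd + self.eps) / np.sqrt(sg + self.eps) * g
            sd *= self.rho
            sd += (1 - self.rho) * delta * delta
            p.data -= self.lr * delta


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored loss."""

    def __init__(self, optimizer: Adadelta, patience: int = 5, factor: float = 0.1,
                 min_lr: float = 1e-4):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> None:
        if loss < self.best - 1e-12:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    fold_ids: np.ndarray  # per measured-record fold, aligned with table.measured()
    source: str  # "file" or "random_by_peptide"


def assign_folds(table: DatasetTable, folds: int = 5, seed: int = 0) -> FoldAssignment:
    """Fold ids for the measured records of ``table``.

    File-provided folds (every measured record carries a fold_id) pass
    through unchanged.  Otherwise records are grouped by peptide
    sequence — identical peptides always share a fold, an approximation
    of overlap-aware splitting — and groups are shuffled into folds of
    near-equal size.
    """
    measured = table.measured()
    if not measured:
        raise ValueError("table has no measured records")
    if all(r.fold_id is not None for r in measured):
        ids = np.array([r.fold_id for r in measured], dtype=np.int64)
        if ids.min() < 0 or ids.max() >= folds:
            raise ValueError("file-provided fold ids outside range")
        return FoldAssignment(ids, "file")
    peptides = sorted({r.peptide.sequence for r in measured})
    if len(peptides) < folds:
        raise ValueError(f"only {len(peptides)} peptide groups for {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(peptides))
    fold_of_pep = {peptides[j]: int(i % folds) for i, j in enumerate(order)}
    ids = np.array([fold_of_pep[r.peptide.sequence] for r in measured], dtype=np.int64)
    return FoldAssignment(ids, "random_by_peptide")


# ---------------------------------------------------------------------------
# encoding a table to arrays
# ---------------------------------------------------------------------------

def encode_table(table: DatasetTable, model_length: int = 15):
    """Encode all records to (pep_idx, pseudo_idx, affinity, is_measured)."""
    n = len(table.records)
    pep = np.zeros((n, model_length), dtype=np.int64)
    pseudo = np.zeros((n, 34), dtype=np.int64)
    y = np.zeros(n)
    measured = np.zeros(n, dtype=bool)
    cache: dict[str, np.ndarray] = {}
    for i, rec in enumerate(table.records):
        pep[i] = encode_peptide(rec.peptide, model_length)
        key = rec.allele.name
        if key not in cache:
            cache[key] = encode_pseudo(rec.allele)
        pseudo[i] = cache[key]
        y[i] = rec.affinity
        measured[i] = rec.origin is Origin.MEASURED
    return pep, pseudo, y, measured


# ---------------------------------------------------------------------------
# single-model training
# ---------------------------------------------------------------------------

def train_single(
    table: DatasetTable,
    fold_assignment: FoldAssignment,
    held_out_fold: int,
    config: TrainingConfig,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
) -> tuple[Model, dict]:
    """Fit one model on all folds except ``held_out_fold``.

    Minimizes mean squared error between predicted and measured affinity.
    Artificial negatives are always in the training split.  The scheduler
    monitors held-out MSE.  Returns the final-epoch model and a log of
    per-epoch train/validation losses.
    """
    model_config = model_config or ModelConfig()
    epochs = epochs if epochs is not None else config.epochs
    if not 0 <= held_out_fold < config.folds:
        raise ValueError(f"held_out_fold {held_out_fold} outside 0..{config.folds - 1}")

    pep, pseudo, y, measured = encode_table(table, model_config.model_length)
    fold_full = np.full(len(table.records), -1, dtype=np.int64)
    fold_full[measured] = fold_assignment.fold_ids
    train_mask = fold_full != held_out_fold  # negatives (fold -1) always train
    val_mask = fold_full == held_out_fold

    rng = np.random.default_rng(seed)
    model = Model(model_config, seed=int(rng.integers(2**31)))
    opt = Adadelta(model.trainable(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    sched = ReduceLROnPlateau(opt, patience=config.scheduler_patience,
                              factor=config.scheduler_factor)

    tr_idx = np.flatnonzero(train_mask)
    va_pep, va_pseudo, va_y = pep[val_mask], pseudo[val_mask], y[val_mask]
    log = {"train_mse": [], "val_mse": [], "lr": [], "seed": seed}
    for epoch in range(epochs):
        order = rng.permutation(tr_idx)
        total, count = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo : lo + config.batch_size]
            yhat = model.forward_batch(pep[batch], pseudo[batch], training=True, rng=rng)
            diff = yhat - ad.Tensor(y[batch])
            loss = ad.mean(ad.mul(diff, diff))
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            model.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(batch)
            count += len(batch)
        val_pred = model.predict_encoded(va_pep, va_pseudo)
        val_mse = float(np.mean((val_pred - va_y) ** 2)) if len(va_y) else np.nan
        log["train_mse"].append(total / max(count, 1))
        log["val_mse"].append(val_mse)
        log["lr"].append(opt.lr)
        if np.isfinite(val_mse):
            sched.step(val_mse)
        logger.info("epoch %d train_mse=%.5f val_mse=%.5f lr=%.4f",
                    epoch + 1, log["train_mse"][-1], val_mse, opt.lr)
    return model, log


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleBundle:
    models: list[Model]
    training_log: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)

    def predict_encoded(self, pep_idx: np.ndarray, pseudo_idx: np.ndarray) -> np.ndarray:
        if not self.models:
            raise ValueError("empty ensemble")
        acc = np.zeros(pep_idx.shape[0])
        for m in self.models:
            acc += m.predict_encoded(pep_idx, pseudo_idx)
        return acc / len(self.models)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        for i, m in enumerate(self.models):
            name = f"model{i:03d}.npz"
            m.save(directory / name)
            names.append(name)
        manifest = {"models": names, "logs": self.training_log}
        (directory / "ensemble.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "EnsembleBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "ensemble.json").read_text())
        models = [Model.load(directory / name) for name in manifest["models"]]
        return cls(models, manifest.get("logs", []))


def train_ensemble(
    table: DatasetTable,
    config: TrainingConfig,
    model_config: ModelConfig | None = None,
    epochs: int | None = None,
    add_negatives: bool = True,
) -> EnsembleBundle:
    """R repeats of F-fold CV -> R*F models averaged at prediction time.

    Each repeat redraws initialization seeds and (when folds are not
    file-provided) the fold assignment, and regenerates artificial
    negatives with a repeat-specific seed.
    """
    master = np.random.default_rng(config.seed)
    models: list[Model] = []
    logs: list[dict] = []
    file_folds = all(r.fold_id is not None for r in table.measured())
    for r in range(config.repeats):
        repeat_seed = int(master.integers(2**31))
        fold_seed = repeat_seed if not file_folds else 0
        folds = assign_folds(table, config.folds, seed=fold_seed)
        train_table = (
            add_artificial_negatives(table, seed=repeat_seed) if add_negatives else table
        )
        for f in range(config.folds):
            model_seed = int(master.integers(2**31))
            model, log = train_single(
                train_table, folds, f, config, model_config, seed=model_seed,
                epochs=epochs,
            )
            log.update({"repeat": r, "fold": f})
            models.append(model)
            logs.append(log)
    return EnsembleBundle(models, logs)


def ensemble_predict(bundle: EnsembleBundle, pairs, model_length: int = 15) -> np.ndarray:
    """Mean eval-mode prediction over all models for (allele, peptide) pairs."""
    pep = np.stack([encode_peptide(p, model_length) for _, p in pairs])
    pseudo = np.stack([encode_pseudo(a) for a, _ in pairs])
    return bundle.predict_encoded(pep, pseudo)
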