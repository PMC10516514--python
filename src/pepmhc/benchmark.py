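"""Synthetic end-to-end benchmark protocols.

Self-contained experiments on the planted-motif simulator: train a model
on one cross-validation split, measure held-out binder-classification
AUC, compare single models against their ensemble, and test whether
motif extraction recovers the planted anchor positions.  These back
both the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DatasetTable, add_artificial_negatives
from .metrics import auc, classify_binder
from .model import Model, ModelConfig
from .motif import extract_motif
from .synthetic import GroundTruth, SyntheticDatasetConfig, generate_dataset
from .training import (
    EnsembleBundle,
    FoldAssignment,
    TrainingConfig,
    assign_folds,
    encode_table,
    train_single,
)


@dataclass
class SyntheticSplit:
    """A generated dataset with one fixed CV split and encoded arrays."""

    table: DatasetTable
    truth: GroundTruth
    train_table: DatasetTable  # with artificial negatives
    folds: FoldAssignment
    held_out_fold: int
    pep: np.ndarray
    pseudo: np.ndarray
    y: np.ndarray
    val_mask: np.ndarray

    @property
    def val_labels(self) -> np.ndarray:
        return classify_binder(self.y[self.val_mask])


def make_synthetic_split(
    dataset_seed: int = 42,
    held_out_fold: int = 0,
    config: SyntheticDatasetConfig | None = None,
) -> SyntheticSplit:
    """Generate the default synthetic benchmark and its 5-fold split."""
    config = config or SyntheticDatasetConfig(seed=dataset_seed)
    table, truth = generate_dataset(config)
    train_table = add_artificial_negatives(table, seed=dataset_seed)
    folds = assign_folds(train_table, 5, seed=dataset_seed)
    pep, pseudo, y, measured = encode_table(train_table)
    fold_full = np.full(len(train_table.records), -1, dtype=np.int64)
    fold_full[measured] = folds.fold_ids
    return SyntheticSplit(
        table, truth, train_table, folds, held_out_fold,
        pep, pseudo, y, fold_full == held_out_fold,
    )


def train_on_split(
    split: SyntheticSplit,
    train_seed: int,
    epochs: int,
    model_config: ModelConfig | None = None,
) -> tuple[Model, float]:
    """Train one model on the split and return it with held-out AUC."""
    model, _ = train_single(
        split.train_table,
        split.folds,
        split.held_out_fold,
        TrainingConfig(seed=train_seed),
        model_config,
        seed=train_seed,
        epochs=epochs,
    )
    return model, held_out_auc(split, model)


def held_out_auc(split: SyntheticSplit, model_or_bundle) -> float:
    """Binder-classification AUC on the held-out fold's measured records."""
    pred = model_or_bundle.predict_encoded(
        split.pep[split.val_mask], split.pseudo[split.val_mask]
    )
    return auc(pred, split.val_labels)


def ensemble_vs_singles(
    split: SyntheticSplit, seeds: tuple[int, ...], epochs: int
) -> dict:
    """Train one model per seed; compare each against their mean ensemble."""
    models, aucs = [], []
    for s in seeds:
        m, a = train_on_split(split, s, epochs)
        models.append(m)
        aucs.append(a)
    bundle = EnsembleBundle(models)
    return {
        "single_aucs": aucs,
        "ensemble_auc": held_out_auc(split, bundle),
        "bundle": bundle,
    }


def motif_recovery(
    bundle,
    truth: GroundTruth,
    length: int,
    n: int = 20000,
    top_fraction: float = 0.01,
    seed: int = 0,
) -> dict[str, bool]:
    """Per allele: do the two highest-IC motif positions equal the planted anchors?"""
    out = {}
    for name, spec in truth.specs.items():
        m = extract_motif(
            bundle, spec.allele, length, n=n, top_fraction=top_fraction, seed=seed
        )
        top2 = set(np.argsort(m.information_content)[-2:])
        expected = set(spec.anchor_peptide_positions(length))
        out[name] = top2 == expected
    return out
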