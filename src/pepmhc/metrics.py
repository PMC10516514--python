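"""Evaluation statistics for binding-affinity prediction.

Per-allele, per-length-bin AUC / Pearson / Spearman with the standard
reporting filters (>20 data points, >= 3 binders), the cross-dataset
overall percent-rank aggregate, the Frank epitope-ranking statistic, and
the one-tailed binomial sign test for paired method comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .data import BINDER_THRESHOLD, DatasetTable, length_bin

MIN_POINTS = 20  # a group needs strictly more points than this
MIN_BINDERS = 3


def classify_binder(affinity) -> np.ndarray | int:
    """Binder iff IC50 < 500 nM, i.e. transformed affinity > 0.42562...

    The threshold is the exact transform of 500 nM, not the rounded
    0.426.
    """
    arr = np.asarray(affinity)
    out = (arr > BINDER_THRESHOLD).astype(int)
    return int(out) if arr.ndim == 0 else out


def auc(scores, labels) -> float | None:
    """ROC AUC (= Mann-Whitney concordance, ties 0.5); None if one class."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pcc(x, y) -> float | None:
    """Pearson correlation; None when either input has zero variance."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def srcc(x, y) -> float | None:
    """Spearman rank correlation (average ranks for ties)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# grouped report
# ---------------------------------------------------------------------------

def build_report(predictions: dict[tuple[str, str], float], truth: DatasetTable) -> pd.DataFrame:
    """Per-(allele, length-bin) metric table under the reporting filters.

    ``predictions`` maps (allele_name, peptide) to predicted affinity and
    must cover every measured record of ``truth``.  A group enters the
    report only with more than 20 points and at least 3 binders; the
    appended aggregate rows average each metric per length bin over the
    reported groups only.
    """
    measured = truth.measured()
    missing = [
        (r.allele.name, r.peptide.sequence)
        for r in measured
        if (r.allele.name, r.peptide.sequence) not in predictions
    ]
    if missing:
        raise KeyError(f"missing predictions for {len(missing)} pairs, e.g. {missing[:3]}")

    rows = []
    frame = pd.DataFrame(
        {
            "allele": [r.allele.name for r in measured],
            "bin": [r.length_bin for r in measured],
            "y": [r.affinity for r in measured],
            "pred": [predictions[(r.allele.name, r.peptide.sequence)] for r in measured],
        }
    )
    for (name, lbin), grp in frame.groupby(["allele", "bin"], sort=True):
        labels = classify_binder(grp["y"].to_numpy())
        n, n_binders = len(grp), int(labels.sum())
        if n <= MIN_POINTS or n_binders < MIN_BINDERS:
            continue
        rows.append(
            {
                "allele": name,
                "length_bin": lbin,
                "n": n,
                "n_binders": n_binders,
                "auc": auc(grp["pred"], labels),
                "pcc": pcc(grp["pred"], grp["y"]),
                "srcc": srcc(grp["pred"], grp["y"]),
            }
        )
    report = pd.DataFrame(
        rows, columns=["allele", "length_bin", "n", "n_binders", "auc", "pcc", "srcc"]
    )
    return report


def aggregate_report(report: pd.DataFrame) -> pd.DataFrame:
    """Mean metric per length bin over reported groups (None excluded)."""
    if report.empty:
        return pd.DataFrame(columns=["length_bin", "n_alleles", "auc", "pcc", "srcc"])
    out = []
    for lbin, grp in report.groupby("length_bin", sort=True):
        row = {"length_bin": lbin, "n_alleles": len(grp)}
        for m in ("auc", "pcc", "srcc"):
            vals = grp[m].dropna()
            row[m] = float(vals.mean()) if len(vals) else None
        out.append(row)
    return pd.DataFrame(out)


def write_report(report: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        report.to_csv(fh, sep="\t", index=False, float_format="%.6f")
        fh.write("# aggregates\n")
        aggregate_report(report).to_csv(fh, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# cross-dataset aggregates
# ---------------------------------------------------------------------------

def percent_rank(values, method_index: int) -> float:
    """Percent rank of one method among N: (n_l - 1) / (N - 1) * 100.

    ``n_l`` counts methods (self included) with value less than or equal
    to the method's own value, so tied methods share the higher rank.
    """
    values = np.asarray(values, dtype=float)
    N = len(values)
    if N < 2:
        raise ValueError("need at least two methods")
    own = values[method_index]
    n_l = int(np.sum(values <= own))
    return (n_l - 1) / (N - 1) * 100.0


def overall_metric(matrix: np.ndarray, method_index: int) -> float:
    """Overall percent-rank Ov: mean PR over M metrics x D datasets.

    ``matrix`` has shape (M, D, N) holding each method's value of metric
    m on dataset d.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 3:
        raise ValueError("matrix must be (metrics, datasets, methods)")
    if np.isnan(matrix).any():
        raise ValueError("matrix has missing cells")
    M, D, _ = matrix.shape
    total = 0.0
    for i in range(M):
        for j in range(D):
            total += percent_rank(matrix[i, j], method_index)
    return total / (M * D)


def frank(scores, epitope_index: int) -> float:
    """Fraction of same-protein peptides scored strictly above the epitope."""
    scores = np.asarray(scores, dtype=float)
    if not 0 <= epitope_index < len(scores):
        raise IndexError("epitope index out of range")
    n_p = int(np.sum(scores > scores[epitope_index]))
    return n_p / len(scores)


# ---------------------------------------------------------------------------
# sign test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignTestResult:
    wins: int
    losses: int
    ties: int
    p_value: float | None


def sign_test(deltas) -> SignTestResult:
    """One-tailed binomial sign test on per-dataset differences.

    Ties (delta == 0) are excluded; the p-value is the exact upper tail
    P(X >= wins) for X ~ Binomial(wins + losses, 1/2).
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("no datasets")
    wins = int(np.sum(deltas > 0))
    losses = int(np.sum(deltas < 0))
    ties = int(deltas.size) - wins - losses
    n = wins + losses
    if n == 0:
        return SignTestResult(wins, losses, ties, None)
    p = float(stats.binomtest(wins, n, 0.5, alternative="greater").pvalue)
    return SignTestResult(wins, losses, ties, p)
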