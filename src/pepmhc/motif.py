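"""Binding-motif extraction from a trained model.

Scores a large random peptide set for one allele at one length, keeps
the top fraction of predicted binders (1% by default), and tallies a
position-frequency matrix with per-position information content — the
data behind a sequence logo.  Information content is Shannon-style,
IC_p = log2(20) - H_p in bits, with no small-sample correction and
uniform background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .data import AMINO_ACIDS, MHCAllele, encode_peptide, encode_pseudo
from .training import EnsembleBundle

LOG2_20 = math.log2(20)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class MotifMatrix:
    length: int
    frequencies: np.ndarray  # (length, 20), rows sum to 1
    information_content: np.ndarray  # (length,), bits
    n_sequences: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.information_content = np.asarray(self.information_content, dtype=float)
        if self.frequencies.shape != (self.length, 20):
            raise ValueError("frequency matrix must be (length, 20)")
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")


def information_content(frequencies: np.ndarray) -> np.ndarray:
    """Per-position IC in bits: log2(20) minus the Shannon entropy."""
    f = np.asarray(frequencies, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    return LOG2_20 + plogp.sum(axis=1)


def motif_from_peptides(peptides: list[str]) -> MotifMatrix:
    """Position-frequency matrix and IC from an aligned same-length set."""
    if not peptides:
        raise ValueError("no peptides")
    length = len(peptides[0])
    if any(len(p) != length for p in peptides):
        raise ValueError("peptides must share one length")
    counts = np.zeros((length, 20))
    for pep in peptides:
        for pos, aa in enumerate(pep):
            counts[pos, _AA_INDEX[aa]] += 1
    freq = counts / len(peptides)
    return MotifMatrix(length, freq, information_content(freq), len(peptides))


# ---------------------------------------------------------------------------
# background sampling
# ---------------------------------------------------------------------------

def sample_background_peptides(
    length: int,
    n: int = 100000,
    source=None,
    seed: int | None = 0,
) -> list[str]:
    """Random background peptides of one length.

    With ``source`` (a FASTA path) peptides are contiguous substrings:
    a record is chosen with probability proportional to its number of
    valid windows, then a start position uniformly; windows containing
    non-standard residues are rejected and resampled.  Without a source,
    residues are i.i.d. uniform over the 20 standard amino acids.
    """
    rng = np.random.default_rng(seed)
    if source is None:
        idx = rng.integers(0, 20, size=(n, length))
        return ["".join(AMINO_ACIDS[i] for i in row) for row in idx]
    seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")]
    weights = np.array([max(len(s) - length + 1, 0) for s in seqs], dtype=float)
    if weights.sum() == 0:
        raise ValueError(f"no windows of length {length} in {source}")
    valid = set(AMINO_ACIDS)
    probs = weights / weights.sum()
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError("could not sample enough valid windows (non-standard residues?)")
        r = int(rng.choice(len(seqs), p=probs))
        start = int(rng.integers(0, len(seqs[r]) - length + 1))
        pep = seqs[r][start : start + length]
        if set(pep) <= valid:
            out.append(pep)
    return out


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_motif(
    bundle: EnsembleBundle,
    allele: MHCAllele,
    length: int,
    n: int = 100000,
    top_fraction: float = 0.01,
    source=None,
    seed: int | None = 0,
    model_length: int = 15,
) -> MotifMatrix:
    """Motif of the top predicted binders among random background peptides.

    The ``ceil(n * top_fraction)`` highest-scoring peptides are kept;
    score ties break lexicographically on the peptide so the selection
    is deterministic.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    peptides = sample_background_peptides(length, n, source=source, seed=seed)
    pep_idx = np.stack([encode_peptide(p, model_length) for p in peptides])
    pseudo_idx = np.tile(encode_pseudo(allele), (len(peptides), 1))
    scores = bundle.predict_encoded(pep_idx, pseudo_idx)
    k = math.ceil(len(peptides) * top_fraction)
    order = sorted(range(len(peptides)), key=lambda i: (-scores[i], peptides[i]))
    selected = [peptides[i] for i in order[:k]]
    return motif_from_peptides(selected)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_motif(motif: MotifMatrix, path) -> None:
    """TSV: 20-residue header + IC column; one row per motif position."""
    with open(path, "w") as fh:
        fh.write("\t".join(AMINO_ACIDS) + "\tIC\n")
        for p in range(motif.length):
            freqs = "\t".join(format(v, ".10g") for v in motif.frequencies[p])
            fh.write(f"{freqs}\t{motif.information_content[p]:.10g}\n")


def read_motif(path, n_sequences: int = 0) -> MotifMatrix:
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:20] != list(AMINO_ACIDS) or header[20] != "IC":
            raise ValueError(f"{path}: not a motif file")
        for line in fh:
            rows.append([float(v) for v in line.split("\t")])
    arr = np.array(rows)
    return MotifMatrix(arr.shape[0], arr[:, :20], arr[:, 20], n_sequences)
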