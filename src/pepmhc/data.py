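"""Sequence vocabulary, affinity transforms, and on-disk formats.

The binding-affinity scale used throughout is the log-transformed IC50
convention: an experimental IC50 of ``x`` nM maps to
``1 - log(x)/log(50000)``, clamped to [0, 1], so 1 nM -> 1.0 (strong
binder) and 50,000 nM -> 0.0 (non-binder).  The conventional 500 nM
binder cutoff corresponds to 0.4256 on this scale.

MHC class I molecules are represented by their 34-residue pseudo
sequence: the groove residues in contact with the bound peptide, a
compact allele-discriminating encoding.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

IC50_MAX = 50000.0
LOG_IC50_MAX = math.log(IC50_MAX)

#: Exact transformed-affinity equivalent of the IC50 < 500 nM binder rule.
BINDER_THRESHOLD = 1.0 - math.log(500.0) / LOG_IC50_MAX

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD_TOKEN = "0"
PSEUDO_LENGTH = 34


class AlphabetError(ValueError):
    """A residue outside the 20-letter amino-acid alphabet."""


class PeptideLengthError(ValueError):
    """Peptide length outside the supported model range."""


@dataclass(frozen=True)
class AminoAcidVocabulary:
    """Index mapping over the 20 standard residues plus a pad symbol at 0."""

    tokens: tuple[str, ...] = (PAD_TOKEN, *AMINO_ACIDS)

    def __post_init__(self) -> None:
        if len(self.tokens) != 21 or len(set(self.tokens)) != 21:
            raise ValueError("vocabulary must hold 21 distinct symbols")

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return 0

    def index(self, residue: str) -> int:
        try:
            i = self.tokens.index(residue)
        except ValueError:
            raise AlphabetError(f"unknown residue {residue!r}") from None
        return i

    def encode(self, sequence: str) -> np.ndarray:
        """Residue string -> integer index vector (no padding)."""
        lookup = _INDEX_LOOKUP
        try:
            return np.array([lookup[c] for c in sequence], dtype=np.int64)
        except KeyError as exc:
            raise AlphabetError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None

    def checksum(self) -> str:
        return hashlib.sha256("".join(self.tokens).encode()).hexdigest()[:16]


VOCABULARY = AminoAcidVocabulary()
_INDEX_LOOKUP = {tok: i for i, tok in enumerate(VOCABULARY.tokens)}


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str

    def __post_init__(self) -> None:
        VOCABULARY.encode(self.sequence)  # validates alphabet

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MHCAllele:
    """An MHC-I molecule named by allele and represented by its pseudo sequence."""

    name: str
    pseudo_sequence: str

    def __post_init__(self) -> None:
        if len(self.pseudo_sequence) != PSEUDO_LENGTH:
            raise ValueError(
                f"pseudo sequence of {self.name} has length "
                f"{len(self.pseudo_sequence)}, expected {PSEUDO_LENGTH}"
            )
        VOCABULARY.encode(self.pseudo_sequence)


class Origin(Enum):
    MEASURED = "measured"
    ARTIFICIAL_NEGATIVE = "artificial_negative"


LENGTH_BINS = ("8", "9", "10", "11", "ge12")


def length_bin(length: int) -> str:
    """Bin a peptide length into the reporting bins 8/9/10/11/>=12."""
    return str(length) if length < 12 else "ge12"


@dataclass(frozen=True)
class BindingRecord:
    allele: MHCAllele
    peptide: PeptideRecord
    affinity: float
    origin: Origin = Origin.MEASURED
    fold_id: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.affinity <= 1.0:
            raise ValueError(f"affinity {self.affinity} outside [0,1]")

    @property
    def length_bin(self) -> str:
        return length_bin(self.peptide.length)


@dataclass
class DatasetTable:
    """A binding-affinity dataset plus its allele catalogue and provenance."""

    records: list[BindingRecord]
    alleles: dict[str, MHCAllele]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.allele.name not in self.alleles:
                raise ValueError(f"record allele {rec.allele.name} missing from catalogue")

    def __len__(self) -> int:
        return len(self.records)

    def measured(self) -> list[BindingRecord]:
        """Only experimentally measured records (evaluation never sees artificial negatives)."""
        return [r for r in self.records if r.origin is Origin.MEASURED]


# ---------------------------------------------------------------------------
# affinity transforms
# ---------------------------------------------------------------------------

def transform_ic50(ic50) -> float | np.ndarray:
    """Map IC50 in nM onto the [0, 1] affinity scale, 1 - log(IC50)/log(50000).

    Values above 50,000 nM clamp to 0 and below 1 nM clamp to 1.
    """
    arr = np.asarray(ic50, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be positive")
    out = np.clip(1.0 - np.log(arr) / LOG_IC50_MAX, 0.0, 1.0)
    return float(out) if np.isscalar(ic50) or arr.ndim == 0 else out


def inverse_transform(affinity) -> float | np.ndarray:
    """Affinity in [0, 1] back to IC50 in nM (50000**(1 - a))."""
    arr = np.asarray(affinity, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("affinity must lie in [0,1]")
    out = np.power(IC50_MAX, 1.0 - arr)
    return float(out) if np.isscalar(affinity) or arr.ndim == 0 else out


def encode_peptide(peptide: PeptideRecord | str, model_length: int = 15) -> np.ndarray:
    """Right-pad a peptide to the model length with the pad index 0.

    Right padding keeps the N-terminal anchor columns (positions 1-2)
    aligned across peptide lengths.
    """
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
    if not 8 <= len(seq) <= model_length:
        raise PeptideLengthError(
            f"peptide length {len(seq)} outside [8, {model_length}]"
        )
    out = np.zeros(model_length, dtype=np.int64)
    out[: len(seq)] = VOCABULARY.encode(seq)
    return out


def encode_pseudo(allele: MHCAllele | str) -> np.ndarray:
    seq = allele.pseudo_sequence if isinstance(allele, MHCAllele) else allele
    if len(seq) != PSEUDO_LENGTH:
        raise ValueError(f"pseudo sequence length {len(seq)} != {PSEUDO_LENGTH}")
    return VOCABULARY.encode(seq)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    pass


def read_pseudo_map(path) -> dict[str, MHCAllele]:
    """Read a two-column ``allele pseudo_sequence(34)`` table."""
    out: dict[str, MHCAllele] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            name, pseudo = parts
            try:
                allele = MHCAllele(name, pseudo)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if name in out and out[name].pseudo_sequence != pseudo:
                raise ParseError(f"{path}:{lineno}: conflicting pseudo sequence for {name}")
            out[name] = allele
    return out


def read_binding_table(
    path,
    pseudo_map: Mapping[str, MHCAllele],
    dialect: str = "netmhcpan_train",
    strict: bool = True,
    max_length: int = 15,
    fold_file=None,
) -> DatasetTable:
    """Read a binding-affinity table.

    ``netmhcpan_train`` rows are whitespace-separated
    ``peptide target allele [fold]`` with targets already on the [0, 1]
    scale; ``tsv_ic50`` rows are tab-separated ``allele peptide ic50_nm``
    (with header) and raw IC50 values are transformed on read.  Peptides
    longer than ``max_length`` are skipped with a warning.  ``fold_file``
    optionally supplies one fold id per data row (a sidecar for splits
    published separately from the measurements).
    """
    sidecar: list[int] | None = None
    if fold_file is not None:
        sidecar = [int(x) for x in open(fold_file).read().split()]
    if dialect not in ("netmhcpan_train", "tsv_ic50"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[BindingRecord] = []
    alleles: dict[str, MHCAllele] = {}
    skipped_long = 0
    with open(path) as fh:
        lines = list(fh)
    start = 0
    if dialect == "tsv_ic50":
        # header row required
        if not lines or lines[0].split("\t")[0].strip() != "allele":
            raise ParseError(f"{path}: tsv_ic50 dialect requires 'allele\\tpeptide\\tic50_nm' header")
        start = 1
    data_row = 0
    for lineno, line in enumerate(lines[start:], start + 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if dialect == "tsv_ic50" else line.split()
        try:
            fold: int | None = None
            if sidecar is not None:
                # one id per data row, consumed even for skipped rows
                if data_row >= len(sidecar):
                    raise ParseError("fold sidecar shorter than table")
                fold = sidecar[data_row]
            data_row += 1
            if dialect == "netmhcpan_train":
                if len(parts) == 4:
                    pep_s, target_s, name, fold_s = parts
                    if fold is None:
                        fold = int(fold_s)
                elif len(parts) == 3:
                    pep_s, target_s, name = parts
                else:
                    raise ParseError(f"expected 3-4 columns, got {len(parts)}")
                affinity = float(target_s)
                if not 0.0 <= affinity <= 1.0:
                    raise ParseError(f"target {affinity} outside [0,1]")
            else:
                if len(parts) != 3:
                    raise ParseError(f"expected 3 columns, got {len(parts)}")
                name, pep_s, ic50_s = (p.strip() for p in parts)
                affinity = transform_ic50(float(ic50_s))
            if len(pep_s) > max_length:
                skipped_long += 1
                continue
            if name not in pseudo_map:
                if strict:
                    raise ParseError(f"allele {name} missing from pseudo-sequence map")
                logger.warning("%s:%d: dropping row for unmapped allele %s", path, lineno, name)
                continue
            allele = pseudo_map[name]
            alleles[name] = allele
            records.append(
                BindingRecord(allele, PeptideRecord(pep_s), float(affinity), fold_id=fold)
            )
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        except (ValueError, AlphabetError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    if skipped_long:
        logger.warning("%s: skipped %d peptides longer than %d", path, skipped_long, max_length)
    return DatasetTable(records, alleles, {"path": str(path), "dialect": dialect})


def write_binding_table(table: DatasetTable, path) -> None:
    """Write in the ``peptide target allele [fold]`` training layout."""
    with open(path, "w") as fh:
        for rec in table.records:
            # repr-precision target so write -> read round-trips exactly
            cols = [rec.peptide.sequence, format(rec.affinity, ".17g"), rec.allele.name]
            if rec.fold_id is not None:
                cols.append(str(rec.fold_id))
            fh.write("\t".join(cols) + "\n")


def write_pseudo_map(alleles: Mapping[str, MHCAllele] | Iterable[MHCAllele], path) -> None:
    items = alleles.values() if isinstance(alleles, Mapping) else alleles
    with open(path, "w") as fh:
        for a in items:
            fh.write(f"{a.name}\t{a.pseudo_sequence}\n")


def write_predictions(rows, path) -> None:
    """Write predictions as ``allele peptide length pred_affinity pred_ic50_nm binder``.

    ``rows`` yields (allele_name, peptide, affinity) triples.
    """
    with open(path, "w") as fh:
        fh.write("allele\tpeptide\tlength\tpred_affinity\tpred_ic50_nm\tbinder\n")
        for name, pep, aff in rows:
            binder = int(aff > BINDER_THRESHOLD)
            fh.write(
                f"{name}\t{pep}\t{len(pep)}\t{aff:.6f}\t{inverse_transform(aff):.2f}\t{binder}\n"
            )


# ---------------------------------------------------------------------------
# artificial negatives
# ---------------------------------------------------------------------------

def uniform_peptide_sampler(rng: np.random.Generator):
    """Sampler drawing i.i.d. uniform residues (used when no FASTA is given)."""

    def sample(length: int) -> str:
        idx = rng.integers(0, len(AMINO_ACIDS), size=length)
        return "".join(AMINO_ACIDS[i] for i in idx)

    return sample


def add_artificial_negatives(
    table: DatasetTable,
    per_length: int = 25,
    lengths: Sequence[int] = (8, 9, 10, 11),
    background=None,
    seed: int | None = 0,
) -> DatasetTable:
    """Inject random natural peptides as non-binders (affinity 0) per allele.

    These records carry ``origin=artificial_negative``; they join every
    training partition and never any evaluation set.
    """
    rng = np.random.default_rng(seed)
    sampler = background if background is not None else uniform_peptide_sampler(rng)
    new = list(table.records)
    for name in sorted(table.alleles):
        allele = table.alleles[name]
        for length in lengths:
            for _ in range(per_length):
                new.append(
                    BindingRecord(
                        allele,
                        PeptideRecord(sampler(length)),
                        0.0,
                        origin=Origin.ARTIFICIAL_NEGATIVE,
                    )
                )
    return DatasetTable(new, dict(table.alleles), dict(table.provenance))


__all__ = [
    "AMINO_ACIDS",
    "PAD_TOKEN",
    "PSEUDO_LENGTH",
    "BINDER_THRESHOLD",
    "AminoAcidVocabulary",
    "VOCABULARY",
    "AlphabetError",
    "PeptideLengthError",
    "ParseError",
    "PeptideRecord",
    "MHCAllele",
    "Origin",
    "BindingRecord",
    "DatasetTable",
    "length_bin",
    "transform_ic50",
    "inverse_transform",
    "encode_peptide",
    "encode_pseudo",
    "read_pseudo_map",
    "read_binding_table",
    "write_binding_table",
    "write_pseudo_map",
    "write_predictions",
    "uniform_peptide_sampler",
    "add_artificial_negatives",
]
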