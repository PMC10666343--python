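"""Reading, validating and assembling labelled peptide datasets.

Peptides are short (benchmark assemblies use 8–15-mers) sequences over the
20-letter canonical amino-acid alphabet.  Labels are binary: 1 marks an
experimentally validated binder of a non-classical HLA class I allele
(HLA-E / HLA-G), 0 a non-binder.  Positive and negative peptides normally
arrive in separate FASTA files, mirroring the layout of public binder
benchmarks; a two-column TSV label table is accepted as an alternative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    DatasetSizeError,
    FastaParseError,
    LengthError,
    SequenceValidationError,
)

#: The 20 canonical residues, in the conventional A,R,N,D,… order.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_ALPHABET_SET = frozenset(ALPHABET)

#: Peptide length bounds used for benchmark-style dataset assembly.
DEFAULT_LENGTH_BOUNDS = (8, 15)


@dataclass(frozen=True)
class PeptideRecord:
    """A validated peptide: identifier plus residue string ``S = s1…sn``."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        for ch in seq:
            if ch not in _ALPHABET_SET:
                raise SequenceValidationError(
                    f"record {self.id!r}: non-canonical residue {ch!r}"
                )
        object.__setattr__(self, "sequence", seq)

    @property
    def n(self) -> int:
        """Residue count (the sequence length n)."""
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Peptide records with binary labels (1 = binder, 0 = non-binder)."""

    records: list[PeptideRecord]
    labels: np.ndarray
    #: negatives-per-positive count; None when the classes are not an exact ratio
    ratio: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.records):
            raise DatasetSizeError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        n_pos = int(self.labels.sum())
        n_neg = int(len(self.labels) - n_pos)
        if self.ratio is not None and n_pos and n_neg != self.ratio * n_pos:
            raise DatasetSizeError(
                f"declared ratio {self.ratio} but counts are "
                f"{n_neg} negatives / {n_pos} positives"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive

    def subset(self, indices: Sequence[int]) -> tuple[list[PeptideRecord], np.ndarray]:
        """Records and labels at ``indices`` (no ratio bookkeeping)."""
        idx = np.asarray(indices, dtype=int)
        return [self.records[i] for i in idx], self.labels[idx]


def _check_bounds(
    records: Iterable[PeptideRecord], length_bounds: tuple[int, int]
) -> None:
    lo, hi = length_bounds
    for rec in records:
        if not lo <= rec.n <= hi:
            raise LengthError(
                f"record {rec.id!r}: length {rec.n} outside [{lo}, {hi}]"
            )


def read_fasta(
    path: str | Path, length_bounds: tuple[int, int] | None = None
) -> list[PeptideRecord]:
    """Read peptides from a FASTA file.

    Sequence lines may be wrapped; they are concatenated and uppercased.
    ``length_bounds``, when given, is an inclusive ``(min, max)`` pair that
    every record must satisfy.

    Raises
    ------
    FastaParseError
        If sequence data precedes the first ``>`` header.
    SequenceValidationError
        If a sequence contains a residue outside the canonical alphabet.
    LengthError
        If bounds are supplied and a record violates them.
    """
    path = Path(path)
    # Biopython silently skips leading junk before the first header, so the
    # malformed-file check is done on the raw text first.
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    records = [
        PeptideRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if length_bounds is not None:
        _check_bounds(records, length_bounds)
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records as unwrapped two-line FASTA entries.

    ``read_fasta(write_fasta(records))`` reproduces ids and sequences exactly.
    """
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta-2line")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV label table (header row ``id<TAB>label``)."""
    labels: dict[str, int] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not {"id", "label"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected tab-separated columns 'id' and 'label'")
        for row in reader:
            value = int(row["label"])
            if value not in (0, 1):
                raise ValueError(f"{path}: label for {row['id']!r} must be 0 or 1")
            labels[row["id"]] = value
    return labels


def assemble_dataset(
    positives: Sequence[PeptideRecord],
    negatives: Sequence[PeptideRecord],
    ratio: int = 1,
    seed: int = 0,
) -> LabeledDataset:
    """Combine positives with a seeded subsample of negatives.

    All positives are kept and exactly ``ratio × len(positives)`` negatives are
    drawn without replacement; the combined record order is then shuffled,
    both deterministically under ``seed``.  ``ratio=10`` reproduces the
    1:10 imbalanced benchmark layout.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    required = ratio * len(positives)
    if len(negatives) < required:
        raise DatasetSizeError(
            f"need {required} negatives for ratio {ratio} "
            f"({len(positives)} positives) but only {len(negatives)} supplied"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(negatives), size=required, replace=False)
    records = list(positives) + [negatives[i] for i in chosen]
    labels = np.concatenate(
        [np.ones(len(positives), dtype=int), np.zeros(required, dtype=int)]
    )
    order = rng.permutation(len(records))
    return LabeledDataset(
        records=[records[i] for i in order], labels=labels[order], ratio=ratio
    )
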