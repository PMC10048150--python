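"""Reading, validating and writing DNA sequences and difficulty labels.

Every downstream feature extractor assumes the strict alphabet contract
enforced here: uppercase sequences over {A, C, G, T}, unique identifiers,
and (for training data) exactly one EASY/HARD label per record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

EASY = "EASY"
HARD = "HARD"
#: HARD (difficult to synthesize) is the positive class everywhere.
POSITIVE_LABEL = HARD

_VALID_BASES = frozenset("ACGT")
# IUPAC ambiguity codes (anything that is not a concrete base)
_AMBIGUOUS = frozenset("NRYSWKMBDHVU")


class SequenceValidationError(ValueError):
    """A sequence violates the A/C/G/T alphabet contract."""


class FastaFormatError(ValueError):
    """Malformed FASTA input or duplicate identifiers."""


class LabelTableError(ValueError):
    """Malformed or inconsistent id→label table."""


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with its identifier; the atomic input unit."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class LabeledDataset:
    """Sequences plus one EASY/HARD label per record id."""

    records: list[SequenceRecord]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise LabelTableError(f"records without a label: {missing[:5]}")
        orphans = sorted(set(self.labels) - set(ids))
        if orphans:
            raise LabelTableError(f"labels without a record: {orphans[:5]}")
        bad = sorted({v for v in self.labels.values()} - {EASY, HARD})
        if bad:
            raise LabelTableError(f"labels must be EASY/HARD, got {bad}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def label_vector(self) -> list[str]:
        """Labels in record order."""
        return [self.labels[r.id] for r in self.records]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, uppercasing sequences.

    Order is preserved. Duplicate identifiers are an error because ids key
    the label table and the feature matrix.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals malformed entries this way
        # name the first offending line for the user
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    if not line.startswith(">"):
                        raise FastaFormatError(
                            f"{path}: line {lineno} precedes any FASTA header"
                        ) from exc
                    break
        raise FastaFormatError(f"{path}: {exc}") from exc
    for rec in parsed:
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise FastaFormatError(f"{path}: duplicate sequence ids: {dups}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def validate_record(
    record: SequenceRecord,
    policy: Literal["strict", "strip_ambiguous"] = "strict",
) -> SequenceRecord:
    """Enforce the A/C/G/T contract.

    strict
        any non-ACGT character is an error (position reported 1-based).
    strip_ambiguous
        N and IUPAC ambiguity characters are removed with a warning;
        characters outside the IUPAC alphabet are still an error.
    """
    seq = record.seq.upper()
    if not seq:
        raise SequenceValidationError(f"{record.id}: empty sequence")
    if set(seq) <= _VALID_BASES:
        return record if seq == record.seq else SequenceRecord(record.id, seq)
    if policy == "strict":
        for pos, ch in enumerate(seq, start=1):
            if ch not in _VALID_BASES:
                raise SequenceValidationError(
                    f"{record.id}: invalid character {ch!r} at position {pos}"
                )
    if policy != "strip_ambiguous":
        raise ValueError(f"unknown validation policy: {policy!r}")
    unknown = sorted(set(seq) - _VALID_BASES - _AMBIGUOUS)
    if unknown:
        raise SequenceValidationError(
            f"{record.id}: characters outside the IUPAC DNA alphabet: {unknown}"
        )
    cleaned = "".join(ch for ch in seq if ch in _VALID_BASES)
    removed = len(seq) - len(cleaned)
    warnings.warn(
        f"{record.id}: removed {removed} ambiguous base(s)", stacklevel=2
    )
    if not cleaned:
        raise SequenceValidationError(
            f"{record.id}: no unambiguous bases remain after stripping"
        )
    return SequenceRecord(record.id, cleaned)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated id→label table (case-insensitive)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LabelTableError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            sid, lab = parts[0].strip(), parts[1].strip().upper()
            if lab not in (EASY, HARD):
                raise LabelTableError(
                    f"{path}: line {lineno}: label must be EASY or HARD, got {parts[1]!r}"
                )
            if sid in labels:
                raise LabelTableError(f"{path}: duplicate id {sid!r} at line {lineno}")
            labels[sid] = lab
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


def load_labeled_dataset(fasta_path: str | Path, labels_path: str | Path) -> LabeledDataset:
    records = [validate_record(r) for r in read_fasta(fasta_path)]
    return LabeledDataset(records=records, labels=read_labels(labels_path))
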