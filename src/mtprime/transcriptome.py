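"""FASTA sequence sets and the mRNA/rRNA/tRNA transcriptome partition.

The primer search operates on a three-way partition of a transcriptome:
the annotated mRNAs (the targets), and the rRNA and tRNA genes (the
counter-selected background).  Sequences are stored on the transcript
sense strand exactly as provided; U is mapped to T so RNA FASTA dialects
are accepted, and non-ACGT IUPAC letters are retained (the motif engine
treats them as never matching).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "RNA_CLASSES",
    "TranscriptRecord",
    "TranscriptomePartition",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "build_partition",
    "partition_from_records",
]

logger = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "rRNA", "tRNA")

_VALID_LETTERS = frozenset("ACGTRYSWKMBDHVN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty sequence, duplicate id, ...)."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A single transcript: unique id, uppercase DNA sequence, RNA class."""

    id: str
    seq: str
    rna_class: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be nonempty")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: sequence must be nonempty")
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(
                f"transcript {self.id!r}: rna_class must be one of {RNA_CLASSES}, "
                f"got {self.rna_class!r}"
            )


def _normalize_seq(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_LETTERS
    if bad:
        raise FastaParseError(
            f"record {rec_id!r}: invalid sequence letters {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path, rna_class: str) -> list[TranscriptRecord]:
    """Read a multi-record FASTA file, attaching ``rna_class`` to every record.

    Order is preserved.  Empty sequences and duplicate ids are errors.
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has empty sequence")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            TranscriptRecord(rec.id, _normalize_seq(str(rec.seq), rec.id), rna_class)
        )
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    """Write records as unwrapped-header FASTA with ``width``-column sequence lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


@dataclass
class TranscriptomePartition:
    """Labeled mRNA/rRNA/tRNA sequence sets — the search's universe.

    ``m_t`` is the total number of annotated mRNAs, the denominator of the
    search score.
    """

    mrna: list[TranscriptRecord]
    rrna: list[TranscriptRecord] = field(default_factory=list)
    trna: list[TranscriptRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mrna:
            raise ValueError("partition needs >= 1 mRNA (score undefined with m_t = 0)")
        ids: set[str] = set()
        for rec in self.all_records():
            if rec.id in ids:
                raise ValueError(f"duplicate transcript id across partition: {rec.id!r}")
            ids.add(rec.id)

    @property
    def m_t(self) -> int:
        return len(self.mrna)

    def all_records(self) -> Iterable[TranscriptRecord]:
        yield from self.mrna
        yield from self.rrna
        yield from self.trna

    def class_records(self, rna_class: str) -> Sequence[TranscriptRecord]:
        return {"mRNA": self.mrna, "rRNA": self.rrna, "tRNA": self.trna}[rna_class]


def partition_from_records(records: Iterable[TranscriptRecord]) -> TranscriptomePartition:
    """Assemble a partition from mixed records using their ``rna_class`` labels."""
    by_class: dict[str, list[TranscriptRecord]] = {c: [] for c in RNA_CLASSES}
    for rec in records:
        by_class[rec.rna_class].append(rec)
    return TranscriptomePartition(by_class["mRNA"], by_class["rRNA"], by_class["tRNA"])


def build_partition(
    mrna_path: str | Path,
    rrna_path: str | Path | None = None,
    trna_path: str | Path | None = None,
) -> TranscriptomePartition:
    """Read the three FASTA files and assemble the transcriptome partition.

    rRNA/tRNA files are optional (an empty background is allowed); the mRNA
    set must be nonempty.
    """
    mrna = read_fasta(mrna_path, "mRNA")
    rrna = read_fasta(rrna_path, "rRNA") if rrna_path else []
    trna = read_fasta(trna_path, "tRNA") if trna_path else []
    part = TranscriptomePartition(mrna, rrna, trna)
    for cls in RNA_CLASSES:
        recs = part.class_records(cls)
        logger.info(
            "%s: %d sequences, %d nt total", cls, len(recs), sum(len(r.seq) for r in recs)
        )
    return part
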