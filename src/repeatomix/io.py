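"""Read records and FASTA/FASTQ input/output.

Files are read through Biopython's SeqIO; in memory a read is a lightweight
:class:`ReadRecord`. All writers are gzip-aware (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

PREFIX_LEN = 7


@dataclass
class ReadRecord:
    """A single sequencing read.

    ``qualities`` is a list of per-base phred scores, or None for FASTA input.
    ``species_prefix`` is the fixed 7-character genotype code prepended to the
    read name in comparative analyses (empty string when untagged).
    """

    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    species_prefix: str = field(default="")

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")
        if self.species_prefix and len(self.species_prefix) != PREFIX_LEN:
            raise ValueError(
                f"species prefix must be exactly {PREFIX_LEN} characters, got "
                f"{self.species_prefix!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> list[ReadRecord]:
    with _open(path, "r") as fh:
        return [
            ReadRecord(r.id, str(r.seq), r.letter_annotations["phred_quality"])
            for r in SeqIO.parse(fh, "fastq")
        ]


def read_fasta(path) -> list[ReadRecord]:
    with _open(path, "r") as fh:
        return [ReadRecord(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]


def iter_fasta(path) -> Iterator[tuple[str, str]]:
    with _open(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with _open(path, "w") as fh:
        for r in reads:
            if r.qualities is None:
                raise ValueError(f"read {r.id} has no qualities; cannot write FASTQ")
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with _open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_reads_fasta(reads: Iterable[ReadRecord], path) -> None:
    write_fasta(((r.id, r.sequence) for r in reads), path, width=10**9)
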