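"""Read pre-processing: trimming, quality filtering, pair-aware subsampling,
species-prefix tagging, interlacing and coverage accounting.

The pipeline operates on fixed-length reads: every read is cropped to the
target length and any read retaining a base below the phred threshold is
dropped together with its mate (strictest reading of "low quality bases
removed"; a sliding-window alternative is available via ``mode="window"``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import PREFIX_LEN, ReadRecord

log = logging.getLogger(__name__)


@dataclass
class SampledReadSet:
    """A (sub)sampled set of reads plus its bookkeeping."""

    records: list[ReadRecord]
    sample_size_reads: int
    sample_size_bp: int
    genome_size: Optional[int] = None
    seed: Optional[int] = None

    def coverage(self) -> Optional[float]:
        if self.genome_size is None:
            return None
        return coverage(self.sample_size_bp, self.genome_size)


def _passes(read: ReadRecord, target_length: int, min_phred: int, mode: str) -> Optional[ReadRecord]:
    if len(read.sequence) < target_length:
        return None
    seq = read.sequence[:target_length]
    if read.qualities is None:
        return ReadRecord(read.id, seq, None, read.species_prefix)
    qual = read.qualities[:target_length]
    if mode == "drop":
        if min(qual) < min_phred:
            return None
        return ReadRecord(read.id, seq, qual, read.species_prefix)
    # sliding-window alternative: crop to the longest prefix of bases >= Q
    n = 0
    while n < target_length and qual[n] >= min_phred:
        n += 1
    if n < target_length:
        return None
    return ReadRecord(read.id, seq, qual, read.species_prefix)


def trim_and_filter(
    reads1: Sequence[ReadRecord],
    reads2: Optional[Sequence[ReadRecord]] = None,
    target_length: int = 150,
    min_phred: int = 30,
    mode: str = "drop",
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Crop reads to `target_length` and drop reads with sub-threshold bases.

    Pairing is preserved: if either mate fails, both are removed. With a
    single (unpaired) input pass ``reads2=None``; the second returned list is
    then empty. FASTA records (no qualities) skip quality filtering with a
    logged warning.
    """
    if reads2 is not None and len(reads1) != len(reads2):
        raise ValueError("mate lists differ in length")
    if any(r.qualities is None for r in reads1):
        log.warning("input reads carry no qualities; phred filter skipped")
    out1: list[ReadRecord] = []
    out2: list[ReadRecord] = []
    if reads2 is None:
        for r in reads1:
            kept = _passes(r, target_length, min_phred, mode)
            if kept is not None:
                out1.append(kept)
    else:
        for r1, r2 in zip(reads1, reads2):
            k1 = _passes(r1, target_length, min_phred, mode)
            k2 = _passes(r2, target_length, min_phred, mode)
            if k1 is not None and k2 is not None:
                out1.append(k1)
                out2.append(k2)
    return out1, out2


def sample_reads(
    reads: Sequence[ReadRecord],
    n: int,
    seed: int = 0,
    genome_size: Optional[int] = None,
) -> SampledReadSet:
    """Sample `n` reads (n/2 pairs) without replacement, keeping mates together.

    The input is taken as interlaced pairs (r1, r2, r1, r2, ...). If fewer
    than `n` reads are available all are returned with a warning.
    """
    if n % 2:
        raise ValueError("n must be even (pairs are sampled together)")
    n_pairs_avail = len(reads) // 2
    want = n // 2
    if len(reads) % 2:
        raise ValueError("interlaced input must hold an even number of reads")
    if want >= n_pairs_avail:
        if want > n_pairs_avail:
            warnings.warn(
                f"requested {n} reads but only {len(reads)} available; returning all"
            )
        chosen = list(range(n_pairs_avail))
    else:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(n_pairs_avail, size=want, replace=False).tolist())
    records: list[ReadRecord] = []
    for i in chosen:
        records.append(reads[2 * i])
        records.append(reads[2 * i + 1])
    bp = sum(len(r) for r in records)
    return SampledReadSet(records, len(records), bp, genome_size, seed)


def coverage(sample_size_bp: int, genome_size_bp: int) -> float:
    """Fold coverage = sample size (bp) / genome size (bp)."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    return sample_size_bp / genome_size_bp


def affix_prefix(reads: Sequence[ReadRecord], code: str) -> list[ReadRecord]:
    """Prepend a 7-character genotype code to every read name (no separator)."""
    if len(code) != PREFIX_LEN or not code.isalnum():
        raise ValueError(f"genotype code must be {PREFIX_LEN} alphanumeric characters")
    return [
        ReadRecord(code + r.id, r.sequence, r.qualities, code) for r in reads
    ]


def parse_prefix(read_id: str) -> str:
    """Recover the genotype code from a prefixed read name."""
    if len(read_id) < PREFIX_LEN:
        raise ValueError(f"read id shorter than the {PREFIX_LEN}-character prefix")
    return read_id[:PREFIX_LEN]


def _stem(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def interlace(
    reads1: Sequence[ReadRecord], reads2: Sequence[ReadRecord]
) -> list[ReadRecord]:
    """Merge mate streams into one: r1[0], r2[0], r1[1], r2[1], ..."""
    if len(reads1) != len(reads2):
        raise ValueError("mate streams differ in record count")
    out: list[ReadRecord] = []
    for r1, r2 in zip(reads1, reads2):
        if _stem(r1.id) != _stem(r2.id):
            raise ValueError(f"mate id mismatch: {r1.id} vs {r2.id}")
        out.append(r1)
        out.append(r2)
    return out


def assemble_comparative(per_species) -> list[ReadRecord]:
    """Tag each genotype's interlaced reads with its code and concatenate.

    Accepts a mapping code -> reads or a sequence of (code, reads) pairs;
    codes must be unique 7-character strings. Reads keep their
    within-genotype order.
    """
    items = list(per_species.items()) if hasattr(per_species, "items") else list(per_species)
    codes = [code for code, _ in items]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate genotype codes in comparative run")
    out: list[ReadRecord] = []
    for code, reads in items:
        out.extend(affix_prefix(reads, code))
    return out
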