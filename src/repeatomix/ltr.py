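"""Twin-LTR retrotransposon annotation in assembled sequence.

Candidate elements are found by exact shared k-mers between nearby genome
windows (the two LTRs of an element are near-identical direct repeats at a
fixed lag), grouped by lag, and refined by ungapped X-drop extension to the
maximal-scoring direct-repeat pair. The LTR pair identity is an insertion
age proxy: LTRs are identical on insertion and diverge neutrally afterward.

Tandem arrays also contain direct repeats, but at many different lags
(every multiple of the monomer); candidates whose neighbourhood is not
dominated by a single lag are rejected, as are high-occupancy k-mers.

All coordinates are 0-based half-open; the GFF3 writer converts to 1-based
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from . import _kmers
from .satellites import dimer_periodicity_check
from .simulate import DOMAIN_MARKERS, DOMAIN_ORDER

log = logging.getLogger(__name__)

SEED_K = 17
MIN_LTR = 100
MAX_ELEMENT = 25_000
MIN_PAIR_IDENTITY = 70.0     # percent
MIN_LAG = 200
MAX_KMER_OCC = 50
XDROP = 25
LAG_SLACK = 20
GROUP_GAP = 1000
MIN_DOMINANT_LAG_FRAC = 0.5
DOMAIN_MIN_IDENTITY = 0.70


@dataclass
class DomainHit:
    label: str
    start: int
    end: int
    identity: float


@dataclass
class LTRAnnotation:
    seq_id: str
    element: tuple[int, int]
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_identity: float                    # percent
    domains: list[DomainHit] = field(default_factory=list)
    canonical_order: bool = False
    lineage: str = "Unknown"

    def __post_init__(self) -> None:
        (es, ee), (a5, b5), (a3, b3) = self.element, self.ltr5, self.ltr3
        if not (es <= a5 < b5 <= a3 < b3 <= ee):
            raise ValueError("LTR intervals must nest inside the element, 5' first")
        if not (0 <= self.ltr_identity <= 100):
            raise ValueError("identity out of range")


@dataclass
class LineageAgeProfile:
    lineage: str
    counts: np.ndarray        # 101 one-percent bins, [0,1) ... [99,100]
    n: int
    bimodal: bool
    peaks: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pair identity
# ---------------------------------------------------------------------------


def ltr_identity(ltr5: str, ltr3: str) -> float:
    """Global alignment identity in percent (edit distance over the longer
    sequence length; exact for the gap-free case)."""
    if not ltr5 or not ltr3:
        raise ValueError("empty LTR sequence")
    res = edlib.align(ltr5, ltr3, mode="NW", task="distance")
    return 100.0 * (1.0 - res["editDistance"] / max(len(ltr5), len(ltr3)))


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------


def _direct_repeat_matches(codes: np.ndarray, k: int, max_element: int, max_occ: int):
    """(p1, lag) pairs of same-strand exact k-mer matches within range."""
    kmers = _kmers.kmer_codes(codes, k)
    order = np.argsort(kmers, kind="stable")
    sk = kmers[order]
    boundaries = np.nonzero(np.diff(sk))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(sk)]])
    p1s: list[np.ndarray] = []
    lags: list[np.ndarray] = []
    for s, e in zip(starts, ends):
        occ = e - s
        if occ < 2 or occ > max_occ:
            continue
        pos = np.sort(order[s:e])
        for i in range(len(pos) - 1):
            js = pos[i + 1 :]
            near = js[js - pos[i] <= max_element]
            if near.size:
                p1s.append(np.full(near.size, pos[i]))
                lags.append(near - pos[i])
    if not p1s:
        return np.empty(0, int), np.empty(0, int)
    return np.concatenate(p1s), np.concatenate(lags)


def _xdrop_extend(codes: np.ndarray, lo: int, hi: int, lag: int, xdrop: int):
    """Extend the matched region [lo, hi) against [lo+lag, hi+lag) both ways.

    Ungapped, match +1 / mismatch -2; returns refined (lo, hi) maximizing the
    extension score on each side.
    """
    n = len(codes)
    # right
    best_score, score, best_hi = 0, 0, hi
    p = hi
    while p + lag < n and score > best_score - xdrop:
        score += 1 if codes[p] == codes[p + lag] else -2
        p += 1
        if score > best_score:
            best_score, best_hi = score, p
    # left
    best_score, score, best_lo = 0, 0, lo
    p = lo - 1
    while p >= 0 and score > best_score - xdrop:
        score += 1 if codes[p] == codes[p + lag] else -2
        if score > best_score:
            best_score, best_lo = score, p
        p -= 1
    return best_lo, best_hi


def find_ltr_pairs(
    sequence: str,
    seq_id: str = "seq",
    min_ltr: int = MIN_LTR,
    max_element: int = MAX_ELEMENT,
    min_pair_identity: float = MIN_PAIR_IDENTITY,
    k: int = SEED_K,
) -> list[LTRAnnotation]:
    """Detect twin-LTR elements in an assembled sequence."""
    if len(sequence) < 2 * min_ltr:
        return []
    codes = _kmers.encode(sequence)
    p1, lag = _direct_repeat_matches(codes, k, max_element, MAX_KMER_OCC)
    sel = lag >= MIN_LAG
    p1, lag = p1[sel], lag[sel]
    if p1.size == 0:
        return []
    order = np.lexsort((p1, lag))
    p1, lag = p1[order], lag[order]
    new_group = np.concatenate(
        [[True], (np.diff(lag) > LAG_SLACK) | (np.diff(p1) > GROUP_GAP)]
    )
    group_ids = np.cumsum(new_group)
    all_p1_sorted = np.sort(p1)

    candidates: list[LTRAnnotation] = []
    for gid in np.unique(group_ids):
        sel = group_ids == gid
        gp, gl = p1[sel], lag[sel]
        L = int(np.median(gl))
        lo, hi = int(gp.min()), int(gp.max()) + k
        lo, hi = _xdrop_extend(codes, lo, hi, L, XDROP)
        ltr_len = hi - lo
        if ltr_len < min_ltr or ltr_len > L:
            continue
        span = L + ltr_len
        if span > max_element:
            continue
        # lag dominance in the neighbourhood (tandem arrays have many lags)
        n_region = np.searchsorted(all_p1_sorted, hi) - np.searchsorted(
            all_p1_sorted, lo
        )
        if n_region > 0 and len(gp) / n_region < MIN_DOMINANT_LAG_FRAC:
            continue
        seq5 = sequence[lo:hi]
        seq3 = sequence[lo + L : hi + L]
        identity = ltr_identity(seq5, seq3)
        if identity < min_pair_identity:
            continue
        # tandem-array guard: a genuine LTR has no internal periodicity,
        # whereas a satellite array matching itself at a monomer-multiple
        # lag does
        periodic, _ = dimer_periodicity_check(seq5[:2048])
        if periodic:
            continue
        candidates.append(
            LTRAnnotation(
                seq_id=seq_id,
                element=(lo, hi + L),
                ltr5=(lo, hi),
                ltr3=(lo + L, hi + L),
                ltr_identity=identity,
            )
        )
    # resolve overlaps: highest identity, then longest element
    candidates.sort(
        key=lambda a: (-a.ltr_identity, -(a.element[1] - a.element[0]), a.element)
    )
    chosen: list[LTRAnnotation] = []
    occupied: list[tuple[int, int]] = []
    for cand in candidates:
        s, e = cand.element
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        chosen.append(cand)
        occupied.append((s, e))
    chosen.sort(key=lambda a: a.element)
    return chosen


# ---------------------------------------------------------------------------
# domains and lineage
# ---------------------------------------------------------------------------


def domain_scan(
    internal: str,
    domain_refs: Optional[dict[str, str]] = None,
    min_identity: float = DOMAIN_MIN_IDENTITY,
) -> tuple[list[DomainHit], bool]:
    """Locate domain markers in an internal region; the canonical flag is
    true when found labels appear as a subsequence of GAG-PROT-INT-RT-RH-CHD."""
    refs = domain_refs or DOMAIN_MARKERS
    hits: list[DomainHit] = []
    rc = _kmers.revcomp(internal)
    for label, marker in refs.items():
        best = None
        for strand, seq in (("+", internal), ("-", rc)):
            res = edlib.align(marker, seq, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            identity = 1.0 - res["editDistance"] / len(marker)
            if identity < min_identity:
                continue
            s, e = res["locations"][0]
            if strand == "-":
                s, e = len(internal) - e - 1, len(internal) - s - 1
            if best is None or identity > best.identity:
                best = DomainHit(label, int(s), int(e) + 1, identity)
        if best is not None:
            hits.append(best)
    hits.sort(key=lambda h: h.start)
    found = [h.label for h in hits]
    order = {lab: i for i, lab in enumerate(DOMAIN_ORDER)}
    canonical = all(lab in order for lab in found) and all(
        order[found[i]] < order[found[i + 1]] for i in range(len(found) - 1)
    )
    return hits, canonical


def build_lineage_index(
    library_entries: Sequence[tuple[str, str]], k: int = 17
) -> dict[int, int]:
    index: dict[int, int] = {}
    for ei, (_, seq) in enumerate(library_entries):
        codes = _kmers.encode(seq)
        canon = np.minimum(_kmers.kmer_codes(codes, k), _kmers.kmer_codes_rc(codes, k))
        for km in canon:
            index.setdefault(int(km), ei)
    return index


def assign_lineage(
    element_seq: str,
    library_entries: Sequence[tuple[str, str]],
    k: int = 17,
    min_hits: int = 10,
    _index: Optional[dict[int, int]] = None,
) -> str:
    """Lineage of the best k-mer-sharing library exemplar (or 'Unknown')."""
    index = _index if _index is not None else build_lineage_index(library_entries, k)
    codes = _kmers.encode(element_seq)
    canon = np.minimum(_kmers.kmer_codes(codes, k), _kmers.kmer_codes_rc(codes, k))
    counts: dict[int, int] = {}
    for km in canon[::4]:
        ei = index.get(int(km))
        if ei is not None:
            counts[ei] = counts.get(ei, 0) + 1
    if not counts:
        return "Unknown"
    best, n = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    if n < min_hits:
        return "Unknown"
    return library_entries[best][0]


# ---------------------------------------------------------------------------
# age histograms
# ---------------------------------------------------------------------------


def age_histogram(
    annotations: Sequence[LTRAnnotation],
    peak_separation: int = 5,
    peak_mass: float = 0.2,
    peak_window: int = 3,
) -> list[LineageAgeProfile]:
    """Per-lineage 1%-bin histograms of LTR pair identity with a bimodality
    flag: two local maxima >= `peak_separation` bins apart, each holding >=
    `peak_mass` of the lineage's elements within `peak_window` bins."""
    by_lineage: dict[str, list[float]] = {}
    for ann in annotations:
        by_lineage.setdefault(ann.lineage, []).append(ann.ltr_identity)
    profiles = []
    for lineage in sorted(by_lineage):
        idents = np.asarray(by_lineage[lineage])
        counts, _ = np.histogram(idents, bins=np.arange(0, 102.0))
        n = len(idents)
        sm = np.convolve(counts, np.ones(3) / 3.0, mode="same")
        peaks = [
            i for i in range(1, 100)
            if sm[i] > 0 and sm[i] >= sm[i - 1] and sm[i] >= sm[i + 1]
        ]
        strong = []
        for p in sorted(peaks, key=lambda i: -sm[i]):
            lo, hi = max(0, p - peak_window), min(101, p + peak_window + 1)
            if counts[lo:hi].sum() / n >= peak_mass:
                if all(abs(p - q) >= peak_separation for q in strong):
                    strong.append(p)
        bimodal = len(strong) >= 2
        profiles.append(
            LineageAgeProfile(
                lineage=lineage, counts=counts, n=n, bimodal=bimodal,
                peaks=sorted(strong),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_gff3(annotations: Sequence[LTRAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ann in enumerate(annotations, 1):
            eid = f"LTRRT{i:05d}"
            es, ee = ann.element
            attrs = (
                f"ID={eid};ltr_identity={ann.ltr_identity:.2f};"
                f"lineage={ann.lineage};canonical_domains={str(ann.canonical_order).lower()}"
            )
            fh.write(
                f"{ann.seq_id}\trepeatomix\trepeat_region\t{es + 1}\t{ee}\t.\t+\t.\t{attrs}\n"
            )
            for tag, (s, e) in (("ltr_5p", ann.ltr5), ("ltr_3p", ann.ltr3)):
                fh.write(
                    f"{ann.seq_id}\trepeatomix\tlong_terminal_repeat\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"Parent={eid};type={tag}\n"
                )
            for hit in ann.domains:
                fh.write(
                    f"{ann.seq_id}\trepeatomix\tprotein_match\t{es + ann.ltr5[1] - ann.ltr5[0] + hit.start + 1}\t"
                    f"{es + ann.ltr5[1] - ann.ltr5[0] + hit.end}\t{hit.identity:.2f}\t+\t.\t"
                    f"Parent={eid};Name={hit.label}\n"
                )


def write_histograms(profiles: Sequence[LineageAgeProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("lineage\tbin_low\tbin_high\tcount\tn\tbimodal\n")
        for prof in profiles:
            for b, c in enumerate(prof.counts):
                if c:
                    fh.write(
                        f"{prof.lineage}\t{b}\t{b + 1}\t{int(c)}\t{prof.n}\t{prof.bimodal}\n"
                    )
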