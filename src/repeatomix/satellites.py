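"""Tandem repeat detection, monomer reconstruction and satDNA family
classification.

Detection follows the k-mer-circularity idea: a cluster's reads are
decomposed into k-mers joined into a de Bruijn multigraph; in a tandem
repeat essentially all k-mer mass lies on one dominant cycle whose spelling
is the consensus monomer. The maximum-mean-weight cycle is found exactly
(Karp's algorithm) on pruned graphs up to 5,000 nodes and greedily beyond.
The circularity score — the fraction of total k-mer occurrence mass lying
on the cycle (either strand) — grades confidence: high >= 0.8, putative in
[0.4, 0.8), otherwise no satellite is reported.

Twin-LTR elements also form a k-mer cycle (through their terminal repeats),
so cycles whose depth profile shows a contiguous high-depth arc (the LTR
traversed twice per element) are rejected as tandem candidates.

Families are grouped by circular identity (best over all rotations and both
strands) with single-linkage tiers: >95% variants of one consensus monomer,
80-95% variants of one family, lower-identity links one superfamily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from . import _kmers
from .io import ReadRecord

log = logging.getLogger(__name__)

DETECT_K = 11
MIN_CLUSTER_READS = 20
HIGH_CONFIDENCE = 0.8
MIN_CIRCULARITY = 0.4
KARP_MAX_NODES = 5000
PRUNE_FRACTION = 0.05
# twin-LTR rejection: ratio of the deepest contiguous depth window to the
# median window along the cycle (an LTR is traversed twice per element, so
# its arc runs at ~2x the median; satellite bubbles only dip BELOW median)
MAX_DEPTH_RATIO = 1.6

TIER_MONOMER = 95.0
TIER_FAMILY = 80.0
TIER_SUPERFAMILY = 50.0


@dataclass
class MonomerConsensus:
    sequence: str
    length: int
    at_content: float            # percent
    circularity_score: float
    confidence: str              # high | putative
    cluster_id: str = ""
    abundance: float = 0.0       # percent of the genome

    @classmethod
    def build(cls, sequence: str, score: float, cluster_id: str = "") -> "MonomerConsensus":
        seq = canonical_monomer(sequence)
        return cls(
            sequence=seq,
            length=len(seq),
            at_content=at_content(seq),
            circularity_score=score,
            confidence="high" if score >= HIGH_CONFIDENCE else "putative",
            cluster_id=cluster_id,
        )


@dataclass
class SatFamilyRecord:
    name: str = ""
    members: list[str] = field(default_factory=list)       # monomer ids
    monomer_variant_groups: list[list[str]] = field(default_factory=list)
    genotypes_present: set[str] = field(default_factory=set)
    abundance: dict[str, float] = field(default_factory=dict)  # genotype -> percent
    monomer_length: int = 0
    representative: str = ""

    def total_abundance(self) -> float:
        return sum(self.abundance.values())


def at_content(seq: str) -> float:
    if not seq:
        return 0.0
    at = sum(1 for c in seq.upper() if c in "AT")
    return 100.0 * at / len(seq)


def canonical_monomer(seq: str) -> str:
    """Deterministic representative: lexicographically smallest rotation of
    the strand with the higher GC skew."""
    rc = _kmers.revcomp(seq)

    def skew(s: str) -> float:
        g = s.count("G")
        c = s.count("C")
        return 0.0 if g + c == 0 else (g - c) / (g + c)

    strand = seq if (skew(seq), seq) >= (skew(rc), rc) else rc
    doubled = strand + strand
    return min(doubled[i : i + len(strand)] for i in range(len(strand)))


# ---------------------------------------------------------------------------
# maximum-mean-weight cycle
# ---------------------------------------------------------------------------


def _karp_max_mean_cycle(
    nodes: np.ndarray, eu: np.ndarray, ev: np.ndarray, ew: np.ndarray
) -> Optional[list[int]]:
    """Exact maximum-mean cycle via Karp's recurrence (maximization form).

    Nodes are 0..V-1; returns the node sequence of one optimal cycle or None
    when the graph is acyclic.
    """
    V = len(nodes)
    NEG = -np.inf
    order = np.argsort(ev, kind="stable")
    eu, ev, ew = eu[order], ev[order], ew[order]
    tgt, tstart = np.unique(ev, return_index=True)
    # float32 keeps the (V+1) x V table compact for element-scale graphs
    dmat = np.full((V + 1, V), NEG, dtype=np.float32)
    dmat[0] = 0.0
    for step in range(1, V + 1):
        cand = dmat[step - 1][eu] + ew
        seg = np.maximum.reduceat(cand, tstart)
        row = np.full(V, NEG)
        row[tgt] = seg
        dmat[step] = row
    finite = np.isfinite(dmat[V])
    if not finite.any():
        return None
    ks = np.arange(V)[:, None]
    with np.errstate(invalid="ignore"):
        ratios = (dmat[V] - dmat[:V]) / (V - ks)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mins = np.nanmin(np.where(np.isfinite(ratios), ratios, np.nan), axis=0)
    mins = np.where(finite, mins, np.nan)
    if np.all(np.isnan(mins)):
        return None
    v_star = int(np.nanargmax(mins))
    # backtrack a V-step optimal walk ending at v_star
    in_edges: dict[int, list[int]] = {}
    for idx in range(len(eu)):
        in_edges.setdefault(int(ev[idx]), []).append(idx)
    walk = [v_star]
    v = v_star
    for step in range(V, 0, -1):
        target_val = dmat[step][v]
        pred = None
        for idx in in_edges.get(v, []):
            if np.isfinite(dmat[step - 1][eu[idx]]) and np.isclose(
                dmat[step - 1][eu[idx]] + ew[idx], target_val
            ):
                pred = int(eu[idx])
                break
        if pred is None:
            return None
        walk.append(pred)
        v = pred
    walk.reverse()
    # extract the best-mean simple cycle contained in the walk
    best_cycle = None
    best_mean = -np.inf
    seen: dict[int, int] = {}
    wmap = {(int(a), int(b)): w for a, b, w in zip(eu, ev, ew)}
    i = 0
    pos: dict[int, int] = {}
    for i, node in enumerate(walk):
        if node in pos:
            cyc = walk[pos[node] : i]
            if cyc:
                ws = [
                    wmap[(cyc[t], cyc[(t + 1) % len(cyc)])]
                    for t in range(len(cyc))
                ]
                mean = float(np.mean(ws))
                if mean > best_mean:
                    best_mean = mean
                    best_cycle = cyc
            # restart position tracking from here
            pos = {n: j for j, n in enumerate(walk[pos[node]: i + 1], start=pos[node])}
        pos[node] = i
    return best_cycle


def _greedy_cycle(
    V: int, eu: np.ndarray, ev: np.ndarray, ew: np.ndarray
) -> Optional[list[int]]:
    """Heaviest-out-edge walk from the heaviest edge until a node repeats."""
    out: dict[int, tuple[int, float]] = {}
    for a, b, w in zip(eu, ev, ew):
        a, b = int(a), int(b)
        if a not in out or w > out[a][1]:
            out[a] = (b, w)
    start = int(eu[int(np.argmax(ew))])
    walk = [start]
    pos = {start: 0}
    v = start
    for _ in range(2 * V):
        nxt = out.get(v)
        if nxt is None:
            return None
        v = nxt[0]
        if v in pos:
            return walk[pos[v]:]
        pos[v] = len(walk)
        walk.append(v)
    return None


# ---------------------------------------------------------------------------
# tandem detection
# ---------------------------------------------------------------------------


def detect_tandem(
    reads: Sequence[ReadRecord],
    k: int = DETECT_K,
    cluster_id: str = "",
    verify_k_offset: int = 4,
    ltr_guard: bool = True,
) -> Optional[MonomerConsensus]:
    """TAREAN-style satellite monomer reconstruction from a cluster's reads.

    Returns None for clusters without a dominant k-mer cycle (circularity
    below 0.4) or with a twin-repeat depth signature. A monomer containing
    an exact repeated (k-1)-mer folds the true cycle into two shorter ones;
    to catch this the consensus is re-derived at k + `verify_k_offset` and,
    when the two lengths disagree, the larger-k consensus (fewer spurious
    k-mer coincidences) is reported.
    """
    result = _detect_tandem_at_k(reads, k, cluster_id, ltr_guard)
    if result is not None and verify_k_offset:
        check = _detect_tandem_at_k(reads, k + verify_k_offset, cluster_id, ltr_guard)
        if check is not None and abs(check.length - result.length) > 1:
            log.info(
                "%s: consensus length %d at k=%d vs %d at k=%d; using larger k",
                cluster_id, result.length, k, check.length, k + verify_k_offset,
            )
            result = check
    return result


def _detect_tandem_at_k(
    reads: Sequence[ReadRecord],
    k: int,
    cluster_id: str = "",
    ltr_guard: bool = True,
) -> Optional[MonomerConsensus]:
    if len(reads) < MIN_CLUSTER_READS:
        return None
    if k >= len(reads[0].sequence):
        raise ValueError("k must be smaller than the read length")
    kmer_arrays = []
    for r in reads:
        kmer_arrays.append(_kmers.kmer_codes(_kmers.encode(r.sequence), k))
    allk = np.concatenate(kmer_arrays)
    total_mass = allk.shape[0]
    kmers_unique, counts = np.unique(allk, return_counts=True)
    keep_min = max(2, int(PRUNE_FRACTION * counts.max()))
    kept = kmers_unique[counts >= keep_min]
    if len(kept) < 3:
        return None
    node_of = {int(km): i for i, km in enumerate(kept)}
    # (k+1)-mer edges between kept nodes
    edge_list = []
    for r in reads:
        e = _kmers.kmer_codes(_kmers.encode(r.sequence), k + 1)
        edge_list.append(e)
    alle = np.concatenate(edge_list)
    e_unique, e_counts = np.unique(alle, return_counts=True)
    mask_k = np.uint64((1 << (2 * k)) - 1)
    src = (e_unique >> np.uint64(2)).astype(np.uint64)
    dst = (e_unique & mask_k).astype(np.uint64)
    eu, ev, ew = [], [], []
    for s, d, c in zip(src, dst, e_counts):
        si = node_of.get(int(s))
        di = node_of.get(int(d))
        if si is not None and di is not None:
            eu.append(si)
            ev.append(di)
            ew.append(float(c))
    if not eu:
        return None
    eu = np.array(eu)
    ev = np.array(ev)
    ew = np.array(ew)
    V = len(kept)
    if V <= KARP_MAX_NODES:
        cycle = _karp_max_mean_cycle(kept, eu, ev, ew)
    else:
        cycle = _greedy_cycle(V, eu, ev, ew)
    if not cycle or len(cycle) < 7:
        return None
    # spell the monomer from the cycle's k-mers
    cyc_kmers = kept[cycle]
    bases = [(int(km) & 3) for km in cyc_kmers]
    seq = _kmers.decode(np.array(bases, dtype=np.uint8))
    # circularity: mass of cycle k-mers plus their reverse complements
    count_of = dict(zip((int(x) for x in kmers_unique), (int(c) for c in counts)))
    cyc_set = set(int(x) for x in cyc_kmers)
    codes = _kmers.encode(seq)
    rc_kmers = _kmers.kmer_codes(
        _kmers.revcomp_codes(np.concatenate([codes, codes[: k - 1]])), k
    )
    for km in rc_kmers:
        cyc_set.add(int(km))
    on_mass = sum(count_of.get(km, 0) for km in cyc_set)
    score = on_mass / total_mass
    if score < MIN_CIRCULARITY:
        return None
    # twin-repeat depth signature: contiguous over-deep arc along the cycle.
    # Only meaningful at decent depth; callers re-deriving a monomer from a
    # subset of an already-validated tandem cluster disable it.
    depth = np.array([count_of.get(int(km), 0) for km in cyc_kmers], float)
    win = max(5, min(len(depth) // 8, 50))
    if ltr_guard and len(depth) >= 2 * win:
        smoothed = np.convolve(
            np.concatenate([depth, depth[:win]]), np.ones(win) / win, mode="valid"
        )
        med = float(np.median(smoothed))
        if med > 0 and smoothed.max() / med >= MAX_DEPTH_RATIO:
            return None
    return MonomerConsensus.build(seq, score, cluster_id)


def dimer_periodicity_check(consensus: str, min_period: int = 7) -> tuple[bool, Optional[int]]:
    """Detect internal periodicity of a putative dimer consensus.

    Scans lags up to half the sequence length; true when some lag matches at
    >= 80% of compared positions (band tolerance for diverged monomers).
    """
    if not consensus:
        raise ValueError("empty consensus")
    codes = _kmers.encode(consensus)
    L = len(codes)
    best_lag, best_frac = None, 0.0
    for lag in range(min_period, L // 2 + 1):
        frac = float(np.mean(codes[:-lag] == codes[lag:]))
        if frac > best_frac:
            best_frac, best_lag = frac, lag
    if best_frac >= 0.8:
        return True, best_lag
    return False, None


# ---------------------------------------------------------------------------
# circular identity and family classification
# ---------------------------------------------------------------------------


def circular_identity(monomer_a: str, monomer_b: str) -> float:
    """Percent identity maximized over all rotations of either monomer and
    both strands; symmetric by construction."""
    if not monomer_a or not monomer_b:
        raise ValueError("empty monomer")

    def one_way(x: str, y: str) -> float:
        # best infix alignment of the shorter in the doubled longer
        best = 0.0
        for q in (x, _kmers.revcomp(x)):
            res = edlib.align(q, y + y, mode="HW", task="distance")
            if res["editDistance"] >= 0:
                ident = 1.0 - res["editDistance"] / len(q)
                best = max(best, ident)
        return best

    a, b = sorted((monomer_a, monomer_b), key=len)
    score = one_way(a, b)
    if len(a) == len(b):
        score = max(score, one_way(b, a))
    return 100.0 * score


def _single_linkage(n: int, pairs_ok) -> list[list[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if pairs_ok(i, j):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [sorted(v) for _, v in sorted(groups.items())]


@dataclass
class TierCounts:
    monomer_variants: int       # sequences merged into another at >95%
    family_variants: int        # additional merges in 80-95%
    families: int               # distinct families (80% single-linkage groups)
    superfamilies: int


def classify_families(
    monomers: dict[str, MonomerConsensus],
    identity=circular_identity,
) -> tuple[list[SatFamilyRecord], TierCounts, np.ndarray]:
    """Group monomers into variant/family/superfamily tiers (single linkage).

    `monomers` maps a monomer id (e.g. "<genotype>:<cluster>") to its
    consensus. Chained merges are possible at every tier (logged); the tier
    hierarchy is consistent by construction: variant groups nest inside
    families, families inside superfamilies.
    """
    ids = sorted(monomers)
    n = len(ids)
    ident = np.zeros((n, n))
    for i in range(n):
        ident[i, i] = 100.0
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = identity(
                monomers[ids[i]].sequence, monomers[ids[j]].sequence
            )
    g95 = _single_linkage(n, lambda i, j: ident[i, j] > TIER_MONOMER)
    g80 = _single_linkage(n, lambda i, j: ident[i, j] >= TIER_FAMILY)
    g50 = _single_linkage(n, lambda i, j: ident[i, j] >= TIER_SUPERFAMILY)
    for grp in g95:
        if len(grp) > 2:
            pairs = [
                (ids[a], ids[b], ident[a, b])
                for x, a in enumerate(grp) for b in grp[x + 1:]
                if ident[a, b] <= TIER_MONOMER
            ]
            if pairs:
                log.info("chained monomer-tier merges: %s", pairs)
    records: list[SatFamilyRecord] = []
    for grp in g80:
        rec = SatFamilyRecord(members=[ids[i] for i in grp])
        rec.monomer_variant_groups = [
            [ids[i] for i in sub] for sub in g95 if set(sub) <= set(grp)
        ]
        for i in grp:
            mid = ids[i]
            genotype = mid.split(":")[0] if ":" in mid else mid
            rec.genotypes_present.add(genotype)
            mono = monomers[mid]
            rec.abundance[genotype] = rec.abundance.get(genotype, 0.0) + mono.abundance
        rep = max(grp, key=lambda i: (monomers[ids[i]].abundance, -len(monomers[ids[i]].sequence), ids[i]))
        rec.representative = ids[rep]
        rec.monomer_length = monomers[ids[rep]].length
        records.append(rec)
    tiers = TierCounts(
        monomer_variants=n - len(g95),
        family_variants=len(g95) - len(g80),
        families=len(g80),
        superfamilies=len(g50),
    )
    return records, tiers, ident


def name_families(
    records: Sequence[SatFamilyRecord], species_prefix_of=None
) -> list[SatFamilyRecord]:
    """Assign names: 4-letter prefix + 'Sat' + 2-digit rank (by decreasing
    total abundance) + '-' + consensus monomer length.

    `species_prefix_of` maps a genotype code to its 4-letter prefix; default
    takes the code's first four characters. Ties break by shorter monomer,
    then by representative sequence.
    """
    if species_prefix_of is None:
        species_prefix_of = lambda code: code[:4]
    ordered = sorted(
        records,
        key=lambda r: (
            -r.total_abundance(),
            r.monomer_length,
            r.representative,
        ),
    )
    for rank, rec in enumerate(ordered, start=1):
        top_genotype = max(
            rec.abundance, key=lambda g: (rec.abundance[g], g)
        )
        prefix = species_prefix_of(top_genotype)
        if len(prefix) != 4:
            raise ValueError(f"species prefix must have 4 letters: {prefix!r}")
        rec.name = f"{prefix}Sat{rank:02d}-{rec.monomer_length}"
    return ordered


# ---------------------------------------------------------------------------
# presence/absence summaries
# ---------------------------------------------------------------------------


def presence_absence(
    records: Sequence[SatFamilyRecord], genotypes: Sequence[str]
) -> pd.DataFrame:
    """Boolean genotype x satDNA-family matrix (no empty columns)."""
    cols = {}
    for rec in records:
        if rec.genotypes_present:
            cols[rec.name or rec.representative] = [
                g in rec.genotypes_present for g in genotypes
            ]
    return pd.DataFrame(cols, index=list(genotypes))


def jaccard_matrix(pa: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard similarity of genotype satDNA family sets."""
    if pa.empty:
        raise ValueError("empty presence/absence matrix")
    genotypes = list(pa.index)
    m = pa.to_numpy(bool)
    n = len(genotypes)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.sum(m[i] & m[j])
            union = np.sum(m[i] | m[j])
            if union == 0:
                val = 1.0
                log.warning("two genotypes share no satDNA families at all")
            elif m[i].sum() == 0 or m[j].sum() == 0:
                val = 0.0
            else:
                val = inter / union
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=genotypes, columns=genotypes)


def shared_counts(pa: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-family genotype counts and UpSet-style exact-set tallies."""
    fam_counts = pa.sum(axis=0).astype(int)
    sets = pa.apply(lambda col: frozenset(pa.index[col]), axis=0)
    tallies = sets.value_counts()
    tallies.index = [",".join(sorted(s)) for s in tallies.index]
    return fam_counts, tallies
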