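"""Similarity-based clustering of reads into repeat clusters.

Reads (uniform length after trimming) are compared with an anchored,
strand-aware overlap alignment: an edge joins two reads when the best
forward- or reverse-complement alignment covers at least
``min_overlap_frac`` of the read length at ``min_identity`` identity, with
score = identity x coverage_fraction. Candidate pairs come from a shared
minimizer index so the stage stays near-linear in read count; candidate
verification always uses the full alignment kernel, so the index only
affects which pairs are *considered*, never how they are scored.

Clusters are connected components of the resulting graph; a component is
split by greedy modularity only when the gain is substantial AND the cut
removes almost no edges (a pure bridge). Read-overlap graphs of long
elements are elongated, and balanced cuts of elongated graphs always carry
modularity gain, so an unguarded modularity rule would shred genuine
families; the bridge guard limits splitting to chimeric merges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import networkx as nx
import numpy as np

from . import _kmers
from .io import ReadRecord
from .readprep import parse_prefix

log = logging.getLogger(__name__)

# similarity kernel defaults (documented constants)
MIN_IDENTITY = 0.90
MIN_OVERLAP_FRAC = 0.55
KMER_SIZE = 17
MINIMIZER_WINDOW = 10
MAX_KMER_OCC = 100

# component splitting (see module docstring)
MODULARITY_GAIN = 0.05
MAX_CUT_FRACTION = 0.002

MIN_REPORT_PROPORTION = 0.01  # percent of the genome


@dataclass
class Edge:
    a: int
    b: int
    score: float


@dataclass
class Cluster:
    cluster_id: str
    read_ids: list[str]
    species_counts: dict[str, int]
    annotation: str = "Unknown_repeats"
    genome_proportion: float = 0.0
    edge_count: int = 0
    # observed inter-species edge counts, keyed by sorted (code_a, code_b)
    inter_species_edges: dict[tuple[str, str], int] = field(default_factory=dict)
    discordant: bool = False

    @property
    def size(self) -> int:
        return len(self.read_ids)


@dataclass
class Supercluster:
    members: list[str]                 # cluster ids
    link_counts: dict[tuple[str, str], int]
    annotation: str = "Unknown_repeats"
    dissolved: bool = False


@dataclass
class ReferenceLibrary:
    """Exemplar sequences with hierarchical lineage labels."""

    entries: list[tuple[str, str]]      # (lineage, sequence)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceLibrary":
        from .io import iter_fasta

        entries = []
        for name, seq in iter_fasta(path):
            lineage = "Unknown_repeats"
            for part in name.split("#"):
                if part.startswith("lineage="):
                    lineage = part[len("lineage="):]
            entries.append((lineage, seq))
        return cls(entries)


# ---------------------------------------------------------------------------
# pairwise similarity
# ---------------------------------------------------------------------------


def _mix(h: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer — decorrelates minimizer selection from sequence."""
    h = h.copy()
    h ^= h >> np.uint64(30)
    h *= np.uint64(0xBF58476D1CE4E5B9)
    h ^= h >> np.uint64(27)
    h *= np.uint64(0x94D049BB133111EB)
    h ^= h >> np.uint64(31)
    return h


def _read_matrix(reads: Sequence[ReadRecord]) -> np.ndarray:
    L = len(reads[0])
    mat = np.empty((len(reads), L), dtype=np.uint8)
    for i, r in enumerate(reads):
        if len(r) != L:
            raise ValueError("reads must have uniform length after trimming")
        mat[i] = _kmers.encode(r.sequence)
    return mat


def _minimizers(mat: np.ndarray, k: int, w: int):
    """Windowed-minimum canonical k-mer selection for every read.

    Returns (hashes, read_index, position, is_rc) arrays of selected sites.
    """
    n, L = mat.shape
    if k >= L:
        raise ValueError("k-mer size must be smaller than the read length")
    m = L - k + 1
    fwd = np.empty((n, m), dtype=np.uint64)
    rev = np.empty((n, m), dtype=np.uint64)
    for i in range(n):          # row loop keeps memory flat; still vector inner ops
        fwd[i] = _kmers.kmer_codes(mat[i], k)
        rev[i] = _kmers.kmer_codes_rc(mat[i], k)
    is_rc = rev < fwd
    canon = np.where(is_rc, rev, fwd)
    hashes = _mix(canon)
    if m <= w:
        sel = hashes.argmin(axis=1)[:, None]
    else:
        from numpy.lib.stride_tricks import sliding_window_view

        windows = sliding_window_view(hashes, w, axis=1)
        sel = windows.argmin(axis=2) + np.arange(m - w + 1)[None, :]
    reads_idx = np.repeat(np.arange(n), sel.shape[1])
    pos = sel.ravel()
    # deduplicate repeated selections within a read
    key = reads_idx.astype(np.uint64) * np.uint64(m) + pos.astype(np.uint64)
    _, keep = np.unique(key, return_index=True)
    reads_idx, pos = reads_idx[keep], pos[keep]
    return hashes[reads_idx, pos], reads_idx, pos, is_rc[reads_idx, pos]


def _overlap_alignment(
    seq_a: str, seq_b_oriented: str, offset: int, L: int,
    min_identity: float, min_overlap_frac: float,
) -> Optional[float]:
    """Identity x coverage score of the anchored overlap at `offset`.

    `offset` is the position of seq_b's start on seq_a's coordinates (may be
    negative). Returns None when the implied overlap is too short or too
    diverged.
    """
    if offset >= 0:
        a_part = seq_a[offset:]
        b_part = seq_b_oriented[: L - offset]
    else:
        a_part = seq_a[: L + offset]
        b_part = seq_b_oriented[-offset:]
    ovl = min(len(a_part), len(b_part))
    if ovl < int(np.ceil(min_overlap_frac * L)):
        return None
    res = edlib.align(a_part[:ovl], b_part[:ovl], task="distance")
    identity = 1.0 - res["editDistance"] / ovl
    if identity < min_identity:
        return None
    return identity * (ovl / L)


def pairwise_similarity(
    reads: Sequence[ReadRecord],
    k: int = KMER_SIZE,
    min_identity: float = MIN_IDENTITY,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
    window: int = MINIMIZER_WINDOW,
    max_occ: int = MAX_KMER_OCC,
) -> list[Edge]:
    """Edge list of the read similarity graph (indices into `reads`)."""
    if not reads:
        return []
    L = len(reads[0])
    mat = _read_matrix(reads)
    hashes, ridx, pos, is_rc = _minimizers(mat, k, window)
    order = np.lexsort((ridx, hashes))
    hashes, ridx, pos, is_rc = hashes[order], ridx[order], pos[order], is_rc[order]

    seqs = [r.sequence for r in reads]
    rcs = [_kmers.revcomp(s) for s in seqs]

    candidates: set[tuple[int, int, bool, int]] = set()
    boundaries = np.nonzero(np.diff(hashes))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [hashes.shape[0]]])
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue
        grp = slice(s, e)
        g_reads = ridx[grp]
        g_pos = pos[grp]
        g_rc = is_rc[grp]
        # group-specific deterministic shuffle, so different groups propose
        # different neighbour pairs and family graphs stay well connected;
        # over-occupied groups are capped AFTER the shuffle so the subsample
        # is unbiased with respect to input (and species) order
        sub = np.argsort(
            _mix(g_reads.astype(np.uint64) ^ hashes[s]), kind="stable"
        )
        if len(sub) > max_occ:
            sub = sub[:max_occ]
        g_reads, g_pos, g_rc = g_reads[sub], g_pos[sub], g_rc[sub]
        n_grp = len(g_reads)
        for t in range(n_grp - 1):
            for step in (1, 2):
                if t + step >= n_grp:
                    break
                i, j = int(g_reads[t]), int(g_reads[t + step])
                if i == j:
                    continue
                pi, pj = int(g_pos[t]), int(g_pos[t + step])
                ri, rj = bool(g_rc[t]), bool(g_rc[t + step])
                if i > j:
                    i, j, pi, pj, ri, rj = j, i, pj, pi, rj, ri
                same_strand = ri == rj
                if same_strand:
                    off = pi - pj
                else:
                    off = pi - (L - k - pj)
                candidates.add((i, j, same_strand, off))

    best: dict[tuple[int, int], float] = {}
    for i, j, same_strand, off in sorted(candidates):
        b_seq = seqs[j] if same_strand else rcs[j]
        score = _overlap_alignment(
            seqs[i], b_seq, off, L, min_identity, min_overlap_frac
        )
        if score is None:
            continue
        key = (i, j)
        if score > best.get(key, 0.0):
            best[key] = score
    return [Edge(a, b, s) for (a, b), s in sorted(best.items())]


# ---------------------------------------------------------------------------
# graph clustering
# ---------------------------------------------------------------------------


def _split_component(sub: nx.Graph) -> list[set]:
    """Greedy-modularity split accepted only for near-disconnected cuts."""
    m = sub.number_of_edges()
    if m < 4 or sub.number_of_nodes() < 4:
        return [set(sub.nodes)]
    parts = list(nx.community.greedy_modularity_communities(sub))
    if len(parts) < 2:
        return [set(sub.nodes)]
    gain = nx.community.modularity(sub, parts)   # one community has modularity 0
    if gain <= MODULARITY_GAIN:
        return [set(sub.nodes)]
    node_part = {n: i for i, p in enumerate(parts) for n in p}
    cut = sum(1 for u, v in sub.edges if node_part[u] != node_part[v])
    if cut / m >= MAX_CUT_FRACTION:
        return [set(sub.nodes)]
    return [set(p) for p in parts]


def build_graph(reads: Sequence[ReadRecord], edges: Sequence[Edge]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(reads)))
    g.add_weighted_edges_from((e.a, e.b, e.score) for e in edges)
    return g


def cluster_graph(
    graph: nx.Graph,
    reads: Sequence[ReadRecord],
    species: Optional[Sequence[str]] = None,
) -> list[Cluster]:
    """Partition the similarity graph into ranked clusters.

    Singletons are excluded. Cluster ids CL1, CL2, ... are assigned by
    decreasing read count, ties broken by the smallest member read id.
    """
    groups: list[set] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        groups.extend(g for g in _split_component(sub) if len(g) >= 2)
    keyed = sorted(
        groups, key=lambda g: (-len(g), min(reads[i].id for i in g))
    )
    clusters: list[Cluster] = []
    for rank, group in enumerate(keyed, start=1):
        members = sorted(group)
        ids = [reads[i].id for i in members]
        sub = graph.subgraph(group)
        inter: dict[tuple[str, str], int] = {}
        for u, v in sub.edges:
            su = _code_of(reads[u])
            sv = _code_of(reads[v])
            if su is None or sv is None:
                continue
            if su != sv:
                key = (su, sv) if su < sv else (sv, su)
                inter[key] = inter.get(key, 0) + 1
        clusters.append(
            Cluster(
                cluster_id=f"CL{rank}",
                read_ids=ids,
                species_counts=species_counts(ids, species),
                edge_count=sub.number_of_edges(),
                inter_species_edges=inter,
            )
        )
    return clusters


def genome_proportion(cluster_size: int, total_reads: int) -> float:
    """Cluster size as percent of all analyzed reads."""
    if total_reads <= 0:
        raise ValueError("total reads must be positive")
    return 100.0 * cluster_size / total_reads


def filter_clusters(
    clusters: Sequence[Cluster], min_prop: float = MIN_REPORT_PROPORTION
) -> list[Cluster]:
    """Clusters at or above the reporting threshold (percent of the genome)."""
    return [c for c in clusters if c.genome_proportion >= min_prop]


def _code_of(read: ReadRecord) -> Optional[str]:
    if read.species_prefix:
        return read.species_prefix
    return read.id[:7] if len(read.id) >= 7 else None


def species_counts(
    read_ids: Sequence[str], species: Optional[Sequence[str]] = None
) -> dict[str, int]:
    """Per-species read counts by 7-character prefix; `species` lists the
    codes that must appear (zero counts included). In a comparative run
    (species given) every read must be tagged; otherwise short untagged ids
    are pooled under 'untagged'."""
    counts: dict[str, int] = {code: 0 for code in (species or [])}
    for rid in read_ids:
        if len(rid) >= 7:
            code = parse_prefix(rid)
        elif species:
            raise ValueError(f"untagged read in comparative mode: {rid}")
        else:
            code = "untagged"
        counts[code] = counts.get(code, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _library_index(library: ReferenceLibrary, k: int = KMER_SIZE):
    index: dict[int, set[int]] = {}
    for ei, (_, seq) in enumerate(library.entries):
        codes = _kmers.encode(seq)
        kf = _kmers.kmer_codes(codes, k)
        kr = _kmers.kmer_codes_rc(codes, k)
        for kmer in np.minimum(kf, kr):
            index.setdefault(int(kmer), set()).add(ei)
    return index


def annotate_cluster(
    cluster: Cluster,
    reads_by_id: dict[str, ReadRecord],
    library: ReferenceLibrary,
    vote_frac: float = 0.6,
    min_identity: float = MIN_IDENTITY,
    max_reads: int = 40,
    _index=None,
    k: int = KMER_SIZE,
) -> Cluster:
    """Assign a lineage by majority vote of read-vs-exemplar matches.

    A read matches an exemplar when its best infix alignment (either strand)
    reaches `min_identity` over the full read. The cluster label is the
    lineage holding at least `vote_frac` of matched reads; with no matches
    the cluster is 'Unknown_repeats'; two lineages above 0.3 flag the
    cluster as discordant.
    """
    if not library.entries:
        raise ValueError("reference library is empty")
    index = _index if _index is not None else _library_index(library, k)
    sample = cluster.read_ids[:: max(1, len(cluster.read_ids) // max_reads)][:max_reads]
    votes: dict[str, int] = {}
    matched = 0
    for rid in sample:
        read = reads_by_id[rid]
        codes = _kmers.encode(read.sequence)
        kf = _kmers.kmer_codes(codes, k)
        kr = _kmers.kmer_codes_rc(codes, k)
        cand: set[int] = set()
        for kmer in np.minimum(kf, kr)[::8]:
            cand |= index.get(int(kmer), set())
        best_lineage = None
        best_identity = 0.0
        for ei in sorted(cand):
            lineage, exemplar = library.entries[ei]
            for q in (read.sequence, _kmers.revcomp(read.sequence)):
                res = edlib.align(q, exemplar, mode="HW", task="distance")
                if res["editDistance"] < 0:
                    continue
                identity = 1.0 - res["editDistance"] / len(q)
                if identity >= min_identity and identity > best_identity:
                    best_identity = identity
                    best_lineage = lineage
        if best_lineage is not None:
            matched += 1
            votes[best_lineage] = votes.get(best_lineage, 0) + 1
    if matched == 0:
        cluster.annotation = "Unknown_repeats"
        cluster.discordant = False
        return cluster
    fracs = {lin: n / matched for lin, n in votes.items()}
    top_lineage, top_frac = max(fracs.items(), key=lambda kv: (kv[1], kv[0]))
    cluster.annotation = top_lineage if top_frac >= vote_frac else "Unknown_repeats"
    cluster.discordant = sum(1 for f in fracs.values() if f >= 0.3) >= 2
    return cluster


# ---------------------------------------------------------------------------
# superclusters
# ---------------------------------------------------------------------------


def mate_stem(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def build_superclusters(
    clusters: Sequence[Cluster],
    min_links: int = 5,
) -> list[Supercluster]:
    """Join clusters connected by at least `min_links` read mate pairs."""
    # count links between distinct clusters via shared mate stems
    by_stem: dict[str, list[str]] = {}
    for c in clusters:
        for rid in c.read_ids:
            by_stem.setdefault(mate_stem(rid), []).append(c.cluster_id)
    links: dict[tuple[str, str], int] = {}
    for stem, cl in by_stem.items():
        if len(cl) == 2 and cl[0] != cl[1]:
            key = tuple(sorted(cl))
            links[key] = links.get(key, 0) + 1
    parent = {c.cluster_id: c.cluster_id for c in clusters}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), n in sorted(links.items()):
        if n >= min_links:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for c in clusters:
        groups.setdefault(find(c.cluster_id), []).append(c.cluster_id)
    ann = {c.cluster_id: c.annotation for c in clusters}
    out = []
    for root, members in sorted(groups.items()):
        members = sorted(members, key=lambda cid: int(cid[2:]))
        sub_links = {
            key: n for key, n in links.items()
            if key[0] in members and key[1] in members
        }
        sc = Supercluster(members=members, link_counts=sub_links)
        labels = {ann[m] for m in members}
        real = {l for l in labels if l != "Unknown_repeats"}
        if len(real) > 1:
            sc.dissolved = True   # discordant: members keep their own annotation
        else:
            sc.annotation = next(iter(real)) if real else "Unknown_repeats"
        out.append(sc)
    return out


def resolve_discordant(
    superclusters: Sequence[Supercluster], clusters: Sequence[Cluster]
) -> list[tuple[str, str]]:
    """Reported (entry, annotation) pairs after dissolving discordant
    superclusters: concordant superclusters report once, discordant ones
    report each member cluster under its own annotation."""
    ann = {c.cluster_id: c.annotation for c in clusters}
    out: list[tuple[str, str]] = []
    for sc in superclusters:
        if sc.dissolved:
            out.extend((m, ann[m]) for m in sc.members)
        else:
            out.append(("+".join(sc.members), sc.annotation))
    return out
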