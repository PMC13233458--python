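"""Repeat-based phylogeny from comparative read clusters.

For each abundant cluster the observed/expected (O/E) count of inter-species
similarity edges is a species-pair similarity: under random pairing the
expected number of edges between species s and t is

    e_st = E_total * 2 * n_s * n_t / (N * (N - 1))

where n_s, n_t are the species' read counts in the cluster, N the cluster
size and E_total its edge count — this is the uniform-random-placement
expectation, which normalizes the observed count by each species' read
contribution. Similarities are inverted (distance = 1/similarity), one NJ
tree is built per qualifying cluster, and all trees are summarized in a
consensus split network keeping splits above a frequency threshold.
Clusters missing any species-pair similarity are excluded outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .clustering import Cluster
from .trees import Node, internal_splits, parse_newick, to_newick

log = logging.getLogger(__name__)

CONSENSUS_THRESHOLD = 0.2
TOP_N_CLUSTERS = 100


@dataclass
class OEMatrix:
    cluster_id: str
    species: list[str]
    # symmetric matrix of O/E values; NaN marks missing pairs
    values: np.ndarray

    def pair(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        return float(self.values[i, j])


@dataclass
class DistanceMatrix:
    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.species), len(self.species)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        self.values = v


@dataclass
class Excluded:
    cluster_id: str
    reason: str


@dataclass
class SplitSystem:
    taxa: list[str]
    # split (canonical frozenset side) -> frequency across input trees
    frequencies: dict[frozenset, float]
    threshold: float

    def retained(self) -> dict[frozenset, float]:
        return {s: f for s, f in self.frequencies.items() if f >= self.threshold}

    def incompatible_pairs(self) -> list[tuple[frozenset, frozenset]]:
        """Pairs of retained splits that cannot coexist in a single tree."""
        taxa = set(self.taxa)
        ret = sorted(self.retained(), key=sorted)
        out = []
        for i in range(len(ret)):
            for j in range(i + 1, len(ret)):
                a, b = set(ret[i]), set(ret[j])
                if not (
                    a <= b or b <= a
                    or a <= taxa - b or b <= taxa - a
                ):
                    out.append((ret[i], ret[j]))
        return out


# ---------------------------------------------------------------------------
# O/E similarity
# ---------------------------------------------------------------------------


def oe_edges(cluster: Cluster, species: Sequence[str]) -> OEMatrix:
    """O/E inter-species edge matrix for one cluster.

    Pairs where either species contributes fewer than 2 reads are missing
    (NaN). A cluster without edges yields an all-missing matrix.
    """
    species = list(species)
    n = len(species)
    counts = np.array([cluster.species_counts.get(s, 0) for s in species], float)
    N = counts.sum()
    E = cluster.edge_count
    vals = np.full((n, n), np.nan)
    if E > 0 and N >= 2:
        for i in range(n):
            for j in range(i + 1, n):
                if counts[i] < 2 or counts[j] < 2:
                    continue
                expected = E * 2.0 * counts[i] * counts[j] / (N * (N - 1.0))
                key = (
                    (species[i], species[j])
                    if species[i] < species[j]
                    else (species[j], species[i])
                )
                observed = cluster.inter_species_edges.get(key, 0)
                vals[i, j] = vals[j, i] = observed / expected
    return OEMatrix(cluster.cluster_id, species, vals)


def top_clusters(clusters: Sequence[Cluster], n: int = TOP_N_CLUSTERS) -> list[Cluster]:
    """The n most abundant clusters (input is already ranked by size)."""
    ordered = sorted(clusters, key=lambda c: int(c.cluster_id[2:]))
    if len(ordered) < n:
        log.warning("only %d clusters available (requested %d)", len(ordered), n)
    return ordered[:n]


def to_distance(oe: OEMatrix):
    """Invert similarities (d = 1/s); exclude the cluster when any pair is
    missing or zero."""
    n = len(oe.species)
    vals = oe.values
    iu = np.triu_indices(n, 1)
    if np.isnan(vals[iu]).any():
        return Excluded(oe.cluster_id, "missing pairwise similarity")
    if (vals[iu] == 0).any():
        return Excluded(oe.cluster_id, "zero similarity (no inter-species edges)")
    d = 1.0 / vals
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(oe.species, d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj(dist: DistanceMatrix) -> Node:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Deterministic: among tied Q values the lexicographically smallest taxon
    pair (by the smallest leaf name under each node) is joined. Negative
    branch lengths are clamped to zero (deficit logged). Returns the unrooted
    tree rooted at the final three-way join.
    """
    taxa = dist.species
    if len(taxa) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    nodes: list[Node] = [Node(name=t) for t in taxa]
    labels: list[str] = list(taxa)       # min leaf name under each active node
    D = dist.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        totals = D.sum(axis=1)
        best: Optional[tuple] = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - totals[i] - totals[j]
                tie = tuple(sorted((labels[i], labels[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        for val, which in ((li, "left"), (lj, "right")):
            if val < -1e-12:
                log.debug("clamped negative NJ branch (%s, %.3g)", which, val)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        new = Node(children=[child_i, child_j])
        new_dists = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_dists[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[x] for x in keep] + [new]
        labels = [labels[x] for x in keep] + [min(labels[i], labels[j])]
        D = D2

    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    return Node(children=[a, b, c])


# ---------------------------------------------------------------------------
# consensus network
# ---------------------------------------------------------------------------


def consensus_network(
    trees: Sequence[Node], threshold: float = CONSENSUS_THRESHOLD
) -> SplitSystem:
    """Split system of all input trees, retaining splits whose frequency
    (fraction of trees containing them) is at least `threshold`.

    The retained system may contain mutually incompatible splits — boxes in
    the drawn network. Split weight equals frequency.
    """
    if not trees:
        raise ValueError("no input trees")
    taxa = sorted(trees[0].leaf_names())
    counts: dict[frozenset, int] = {}
    for t in trees:
        if sorted(t.leaf_names()) != taxa:
            raise ValueError("trees must share one taxon set")
        for split in internal_splits(t):
            counts[split] = counts.get(split, 0) + 1
    freqs = {s: c / len(trees) for s, c in counts.items()}
    return SplitSystem(taxa=taxa, frequencies=freqs, threshold=threshold)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_tree(tree: Node, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def read_tree(path) -> Node:
    return parse_newick(open(path).read())


def write_splits(system: SplitSystem, path) -> None:
    """NEXUS file with TAXA and SPLITS blocks (weights = frequencies)."""
    taxa = system.taxa
    idx = {t: i + 1 for i, t in enumerate(taxa)}
    retained = sorted(system.retained().items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    with open(path, "w") as fh:
        fh.write("#nexus\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)};\n")
        fh.write("TAXLABELS\n")
        for i, t in enumerate(taxa, 1):
            fh.write(f"[{i}] '{t}'\n")
        fh.write(";\nEND; [Taxa]\n\n")
        fh.write("BEGIN Splits;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)} nsplits={len(retained)};\n")
        fh.write("FORMAT labels=no weights=yes confidences=no intervals=no;\n")
        fh.write("MATRIX\n")
        for split, freq in retained:
            members = " ".join(str(idx[t]) for t in sorted(split))
            fh.write(f"\t{freq:.6g}\t{members},\n")
        fh.write(";\nEND; [Splits]\n")


def tree_from_compatible_splits(system: SplitSystem) -> Optional[Node]:
    """Reconstruct the tree implied by a compatible split system.

    Returns None when the retained splits are incompatible. Used for
    round-trip checks; branch lengths are the split weights.
    """
    if system.incompatible_pairs():
        return None
    taxa = sorted(system.taxa)
    root = Node(children=[Node(name=t) for t in taxa])
    for split, freq in sorted(
        system.retained().items(), key=lambda kv: len(kv[0]), reverse=True
    ):
        # find the node whose children cover the split side
        side = set(split)

        def place(node: Node) -> bool:
            covered = [c for c in node.children if set(c.leaf_names()) <= side]
            names = set()
            for c in covered:
                names |= set(c.leaf_names())
            if names == side:
                newnode = Node(length=freq, children=covered)
                node.children = [c for c in node.children if c not in covered]
                node.children.append(newnode)
                return True
            for c in node.children:
                if not c.is_leaf and place(c):
                    return True
            return False

        place(root)
    return root
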