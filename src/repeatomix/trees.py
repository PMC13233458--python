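"""Minimal phylogenetic tree structure with Newick round-trip.

Used both by the genome simulator (to evolve repeat templates along a known
species tree) and by the repeat-phylogeny stage (NJ trees, split extraction).
Trees are stored rooted; an unrooted tree is represented by rooting at an
arbitrary internal node, which is sufficient for split enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class Node:
    name: Optional[str] = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def walk(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()


def parse_newick(text: str) -> Node:
    """Parse a Newick string (names, branch lengths; no comments/quoting)."""
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"malformed newick at position {pos}")
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",();":
            pos += 1
        label = s[start:pos]
        if ":" in label:
            name, _, length = label.partition(":")
            node.name = name or None
            node.length = float(length)
        elif label:
            node.name = label
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError("trailing characters in newick string")
    return root


def to_newick(root: Node, include_lengths: bool = True) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            base = node.name or ""
        else:
            base = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                base += node.name
        if include_lengths:
            base += f":{node.length:.10g}"
        return base

    # the root itself carries no meaningful branch
    if root.is_leaf:
        body = root.name or ""
    else:
        body = "(" + ",".join(fmt(c) for c in root.children) + ")"
    return body + ";"


def patristic_distances(root: Node) -> dict[tuple[str, str], float]:
    """Pairwise path lengths between all leaves."""
    dists: dict[tuple[str, str], float] = {}

    def recurse(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        below: list[dict[str, float]] = []
        for child in node.children:
            d = recurse(child)
            below.append({k: v + child.length for k, v in d.items()})
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a, da in below[i].items():
                    for b, db in below[j].items():
                        key = (a, b) if a < b else (b, a)
                        dists[key] = da + db
        merged: dict[str, float] = {}
        for d in below:
            merged.update(d)
        return merged

    recurse(root)
    return dists


def internal_splits(root: Node) -> set[frozenset[str]]:
    """Nontrivial splits of the unrooted tree, each as the canonical side.

    The canonical side of a split is the one NOT containing the
    lexicographically smallest taxon.
    """
    taxa = frozenset(root.leaf_names())
    anchor = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in root.walk():
        if node is root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        canon = side if anchor not in side else taxa - side
        if len(canon) >= 2 and len(taxa - canon) >= 2:
            splits.add(canon)
    return splits
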