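"""O/E edge statistics, neighbor joining (with dendropy as independent
oracle), consensus split networks and tree IO."""

import dendropy
import numpy as np
import pytest

from repeatomix.clustering import Cluster
from repeatomix.phylogeny import (
    DistanceMatrix,
    Excluded,
    OEMatrix,
    SplitSystem,
    consensus_network,
    nj,
    oe_edges,
    read_tree,
    to_distance,
    top_clusters,
    tree_from_compatible_splits,
    write_splits,
    write_tree,
)
from repeatomix.trees import Node, internal_splits, parse_newick, patristic_distances, to_newick


def random_additive_tree(rng, n):
    """Random binary tree with positive branch lengths; returns the distance
    matrix, its internal splits and the patristic distances (the oracle)."""
    names = [f"T{i}" for i in range(n)]
    nodes = [Node(name=names[0], length=rng.uniform(0.1, 1)),
             Node(name=names[1], length=rng.uniform(0.1, 1))]
    root = Node(children=nodes)
    for nm in names[2:]:
        pcs = []

        def walk(p):
            for c in p.children:
                pcs.append((p, c))
                walk(c)

        walk(root)
        p, c = pcs[rng.integers(len(pcs))]
        mid = Node()
        leaf = Node(name=nm, length=rng.uniform(0.1, 1))
        p.children.remove(c)
        old = c.length
        c.length = rng.uniform(0.05, 0.95) * old
        mid.length = old - c.length
        mid.children = [c, leaf]
        p.children.append(mid)
    pd_ = patristic_distances(root)
    ns = sorted(names)
    D = np.zeros((n, n))
    for i, a in enumerate(ns):
        for j, b in enumerate(ns):
            if i < j:
                D[i, j] = D[j, i] = pd_[(a, b)]
    return DistanceMatrix(ns, D), internal_splits(root), pd_


class TestOE:
    def _cluster(self, counts, edges, inter):
        ids = []
        for code, n in counts.items():
            ids.extend(f"{code}r{i}" for i in range(n))
        return Cluster("CL1", ids, counts, edge_count=edges, inter_species_edges=inter)

    def test_worked_example(self):
        # all 7 edges between two balanced species of 5 reads each:
        # O/E = 2(N-1)/N = 1.8 for N = 10
        c = self._cluster(
            {"AAAAAAA": 5, "BBBBBBB": 5}, 7, {("AAAAAAA", "BBBBBBB"): 7}
        )
        m = oe_edges(c, ["AAAAAAA", "BBBBBBB"])
        assert m.pair("AAAAAAA", "BBBBBBB") == pytest.approx(1.8)

    def test_single_species_all_missing(self):
        c = self._cluster({"AAAAAAA": 10}, 5, {})
        m = oe_edges(c, ["AAAAAAA", "BBBBBBB"])
        assert np.isnan(m.values[0, 1])

    def test_sparse_species_missing(self):
        c = self._cluster({"AAAAAAA": 9, "BBBBBBB": 1}, 4, {})
        m = oe_edges(c, ["AAAAAAA", "BBBBBBB"])
        assert np.isnan(m.pair("AAAAAAA", "BBBBBBB"))

    def test_null_calibration_mean_one(self, rng):
        # uniformly random edges + random labels: mean O/E ~ 1
        vals = []
        for _ in range(200):
            n = 40
            labels = np.array(["AAAAAAA"] * 20 + ["BBBBBBB"] * 20)
            rng.shuffle(labels)
            pairs = set()
            while len(pairs) < 60:
                i, j = rng.integers(0, n, 2)
                if i != j:
                    pairs.add((min(i, j), max(i, j)))
            inter = sum(1 for i, j in pairs if labels[i] != labels[j])
            c = self._cluster({"AAAAAAA": 20, "BBBBBBB": 20}, len(pairs),
                              {("AAAAAAA", "BBBBBBB"): inter})
            c.species_counts = {"AAAAAAA": 20, "BBBBBBB": 20}
            vals.append(oe_edges(c, ["AAAAAAA", "BBBBBBB"]).pair("AAAAAAA", "BBBBBBB"))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * se + 0.02


class TestTopAndDistance:
    def _mk(self, cid, size):
        return Cluster(cid, [f"r{i}" for i in range(size)], {})

    def test_top_n(self):
        clusters = [self._mk(f"CL{i + 1}", 300 - i) for i in range(250)]
        top = top_clusters(clusters, 100)
        assert len(top) == 100 and top[0].cluster_id == "CL1"

    def test_fewer_available_warns(self, caplog):
        clusters = [self._mk(f"CL{i + 1}", 50 - i) for i in range(40)]
        with caplog.at_level("WARNING"):
            top = top_clusters(clusters, 100)
        assert len(top) == 40

    def test_inverse_similarity(self):
        m = OEMatrix("CL1", ["A", "B"], np.array([[np.nan, 0.5], [0.5, np.nan]]))
        d = to_distance(m)
        assert isinstance(d, DistanceMatrix)
        assert d.values[0, 1] == pytest.approx(2.0)
        assert d.values[0, 0] == 0.0

    def test_missing_pair_excludes_cluster(self):
        vals = np.full((3, 3), 1.0)
        vals[0, 2] = vals[2, 0] = np.nan
        out = to_distance(OEMatrix("CL7", ["A", "B", "C"], vals))
        assert isinstance(out, Excluded) and out.cluster_id == "CL7"

    def test_zero_similarity_excludes_cluster(self):
        vals = np.array([[np.nan, 0.0], [0.0, np.nan]])
        assert isinstance(to_distance(OEMatrix("CL8", ["A", "B"], vals)), Excluded)


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj(d)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_recovers_random_additive_trees(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 9))
            dm, true_splits, pd_ = random_additive_tree(rng, n)
            tree = nj(dm)
            assert internal_splits(tree) == true_splits
            rec = patristic_distances(tree)
            assert max(abs(rec[k] - pd_[k]) for k in pd_) < 1e-9

    def test_agrees_with_dendropy_topology(self, rng):
        dm, true_splits, _ = random_additive_tree(rng, 7)
        ours = internal_splits(nj(dm))
        # independent oracle: dendropy NJ on the same matrix
        csv = "," + ",".join(dm.species) + "\n"
        for i, a in enumerate(dm.species):
            csv += a + "," + ",".join(str(x) for x in dm.values[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
        dtree = pdm.nj_tree()
        theirs = set()
        taxa = frozenset(dm.species)
        anchor = min(taxa)
        for edge in dtree.preorder_edge_iter():
            head = edge.head_node
            leaves = frozenset(t.taxon.label for t in head.leaf_iter())
            if 2 <= len(leaves) <= len(taxa) - 2:
                canon = leaves if anchor not in leaves else taxa - leaves
                theirs.add(canon)
        assert ours == theirs

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B", "C"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))


class TestConsensus:
    def _trees(self, newicks):
        return [parse_newick(t) for t in newicks]

    def test_identical_trees_full_frequency(self):
        nwk = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
        system = consensus_network(self._trees([nwk] * 10))
        expected = internal_splits(parse_newick(nwk))
        assert set(system.retained()) == expected
        assert all(f == 1.0 for f in system.retained().values())

    def test_rare_split_excluded_at_20pct(self):
        common = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
        rare = "((A:1,C:1):1,(B:1,D:1):1,E:1);"
        system = consensus_network(self._trees([common] * 9 + [rare]))
        retained = set(system.retained())
        # the 1-in-10 splits sit at frequency 0.1 < 0.2
        for split, freq in system.frequencies.items():
            if freq < 0.2:
                assert split not in retained

    def test_threshold_monotonicity(self):
        a = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
        b = "((A:1,C:1):1,(B:1,D:1):1,E:1);"
        trees = self._trees([a] * 6 + [b] * 4)
        lo = set(consensus_network(trees, 0.2).retained())
        hi = set(consensus_network(trees, 0.5).retained())
        assert hi <= lo

    def test_incompatible_splits_flagged(self):
        a = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
        b = "((A:1,C:1):1,(B:1,D:1):1,E:1);"
        system = consensus_network(self._trees([a] * 4 + [b] * 2), 0.2)
        assert len(system.incompatible_pairs()) >= 1

    def test_taxon_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_network(self._trees(["(A:1,B:1,C:1);", "(A:1,B:1,D:1);"]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            consensus_network([])


class TestIO:
    def test_newick_roundtrip(self, tmp_path, rng):
        dm, _, _ = random_additive_tree(rng, 5)
        tree = nj(dm)
        path = tmp_path / "t.nwk"
        write_tree(tree, path)
        back = read_tree(path)
        assert internal_splits(back) == internal_splits(tree)
        pa, pb = patristic_distances(tree), patristic_distances(back)
        assert max(abs(pa[k] - pb[k]) for k in pa) < 1e-9

    def test_nexus_splits_block(self, tmp_path):
        trees = [parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")] * 4
        system = consensus_network(trees)
        path = tmp_path / "s.nex"
        write_splits(system, path)
        text = path.read_text()
        assert text.startswith("#nexus")
        assert "BEGIN Taxa;" in text and "BEGIN Splits;" in text
        assert "nsplits=2" in text

    def test_empty_split_system_valid_nexus(self, tmp_path):
        system = SplitSystem(taxa=["A", "B", "C", "D"], frequencies={}, threshold=0.2)
        path = tmp_path / "empty.nex"
        write_splits(system, path)
        assert "nsplits=0" in path.read_text()

    def test_tree_reconstructable_from_compatible_splits(self):
        nwk = "((A:1,B:1):1,((C:1,D:1):1,E:1):1,F:1);"
        system = consensus_network([parse_newick(nwk)] * 3)
        back = tree_from_compatible_splits(system)
        assert back is not None
        assert internal_splits(back) == internal_splits(parse_newick(nwk))


class TestEndToEndPhylogeny:
    def test_species_tree_splits_recovered(self, e2e):
        _, ev = e2e
        assert ev["splits"]["all_true_recovered"]
        assert ev["splits"]["n_trees"] >= 30

    def test_sister_pair_split_strongly_supported(self, e2e):
        # the shortest-divergence sister pair must be retained with high
        # frequency (the single most frequent split is typically the most
        # isolated clade under the O/E statistic)
        _, ev = e2e
        assert ev["splits"]["sister_pair_freq"] >= 0.5

    def test_permutation_of_species_order(self, e2e):
        result, _ = e2e
        codes = [sp.code for sp in result.sim.species]
        cluster = next(
            c for c in result.reported
            if all(c.species_counts.get(s, 0) >= 2 for s in codes)
            and c.edge_count > 0
        )
        fwd = oe_edges(cluster, codes)
        rev = oe_edges(cluster, codes[::-1])
        for a in codes:
            for b in codes:
                if a != b:
                    assert fwd.pair(a, b) == pytest.approx(rev.pair(a, b), nan_ok=True)
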