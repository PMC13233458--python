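"""Read-similarity graph and cluster construction, with a brute-force
alignment oracle on small instances."""

import collections

import edlib
import numpy as np
import pytest

from repeatomix import _kmers, clustering
from repeatomix.clustering import (
    Cluster,
    ReferenceLibrary,
    annotate_cluster,
    build_graph,
    build_superclusters,
    cluster_graph,
    filter_clusters,
    genome_proportion,
    pairwise_similarity,
    resolve_discordant,
    species_counts,
)
from repeatomix.io import ReadRecord


def _random_seq(rng, n):
    return _kmers.decode(rng.integers(0, 4, n).astype(np.uint8))


def _mutate(seq, rate, rng):
    codes = _kmers.encode(seq)
    hits = rng.random(len(codes)) < rate
    codes[hits] = (codes[hits] + rng.integers(1, 4, hits.sum()).astype(np.uint8)) % 4
    return _kmers.decode(codes)


def brute_force_edges(reads, min_identity=0.90, min_overlap_frac=0.55):
    """All-pairs best anchored-overlap alignment over every offset/strand."""
    L = len(reads[0].sequence)
    min_ovl = int(np.ceil(min_overlap_frac * L))
    out = {}
    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            best = 0.0
            for b in (reads[j].sequence, _kmers.revcomp(reads[j].sequence)):
                for off in range(-(L - min_ovl), L - min_ovl + 1):
                    a_part = reads[i].sequence[max(0, off):]
                    b_part = b[max(0, -off):]
                    ovl = min(len(a_part), len(b_part))
                    if ovl < min_ovl:
                        continue
                    d = edlib.align(a_part[:ovl], b_part[:ovl], task="distance")["editDistance"]
                    ident = 1 - d / ovl
                    if ident >= min_identity:
                        best = max(best, ident * ovl / L)
            if best > 0:
                out[(i, j)] = best
    return out


class TestPairwiseSimilarity:
    def test_identical_reads_score_one(self, rng):
        seq = _random_seq(rng, 150)
        edges = pairwise_similarity([ReadRecord("a", seq), ReadRecord("b", seq)])
        assert len(edges) == 1 and edges[0].score == pytest.approx(1.0)

    def test_reverse_complement_scores_one(self, rng):
        seq = _random_seq(rng, 150)
        edges = pairwise_similarity(
            [ReadRecord("a", seq), ReadRecord("b", _kmers.revcomp(seq))]
        )
        assert len(edges) == 1 and edges[0].score == pytest.approx(1.0)

    def test_partial_overlap_with_divergence_detected(self, rng):
        # reads overlapping 90 of 150 bp at exactly 95% identity (4 of 90
        # sites substituted) pass both thresholds: 0.95 >= 0.90, 0.60 >= 0.55
        genome = _random_seq(rng, 400)
        a = genome[:150]
        codes = _kmers.encode(genome[60:210])
        for site in (5, 30, 55, 80):        # inside the 90 bp overlap
            codes[site] = (codes[site] + 1) % 4
        b = _kmers.decode(codes)
        edges = pairwise_similarity([ReadRecord("a", a), ReadRecord("b", b)])
        assert len(edges) == 1
        ident = 1 - 4 / 90
        assert edges[0].score == pytest.approx(ident * 0.6, abs=0.01)

    def test_agrees_with_brute_force_oracle(self, rng):
        template = _random_seq(rng, 700)
        reads = []
        for i in range(40):
            s = int(rng.integers(0, 550))
            seq = _mutate(template[s : s + 150], 0.02, rng)
            if rng.random() < 0.5:
                seq = _kmers.revcomp(seq)
            reads.append(ReadRecord(f"r{i:02d}", seq))
        oracle = brute_force_edges(reads)
        found = {(e.a, e.b): e.score for e in pairwise_similarity(reads)}
        # no spurious pairs, and near-complete recall of true overlaps
        assert set(found) <= set(oracle)
        assert len(found) >= 0.9 * len(oracle)
        for pair, score in found.items():
            assert score <= oracle[pair] + 1e-9

    def test_oversized_k_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_similarity([ReadRecord("a", "ACGT")], k=17)


class TestClusterGraph:
    def _clique_reads(self, rng, n, tag):
        seq = _random_seq(rng, 150)
        return [ReadRecord(f"{tag}{i:03d}", seq) for i in range(n)]

    def test_two_disjoint_cliques_two_clusters(self, rng):
        reads = self._clique_reads(rng, 50, "a") + self._clique_reads(rng, 50, "b")
        edges = pairwise_similarity(reads)
        clusters = cluster_graph(build_graph(reads, edges), reads)
        assert len(clusters) == 2
        assert sorted(c.size for c in clusters) == [50, 50]
        assert clusters[0].cluster_id == "CL1"

    def test_empty_graph_no_clusters(self):
        import networkx as nx

        assert cluster_graph(nx.Graph(), []) == []

    def test_singletons_excluded(self, rng):
        reads = [ReadRecord(f"s{i}", _random_seq(rng, 150)) for i in range(10)]
        clusters = cluster_graph(build_graph(reads, []), reads)
        assert clusters == []

    def test_partition_property(self, e2e):
        result, _ = e2e
        seen = collections.Counter()
        for c in result.clusters:
            seen.update(c.read_ids)
        assert not seen or seen.most_common(1)[0][1] == 1

    def test_planted_families_recovered_in_single_clusters(self, e2e):
        _, ev = e2e
        assert ev["min_family_recovery"] >= 0.95


class TestProportions:
    def test_genome_proportion_and_filter(self):
        assert genome_proportion(50, 10_000) == pytest.approx(0.5)
        low = Cluster("CL1", ["r1"], {}, genome_proportion=0.001)
        high = Cluster("CL2", ["r"] * 100, {}, genome_proportion=0.1)
        assert filter_clusters([low, high]) == [high]
        with pytest.raises(ValueError):
            genome_proportion(1, 0)

    def test_reported_proportions_bounded(self, e2e):
        result, _ = e2e
        assert sum(c.genome_proportion for c in result.clusters) <= 100.0 + 1e-9

    def test_species_counts_sum_and_zero_entries(self):
        ids = ["AlbaX01r1/1", "AlbaX01r1/2", "BetaY01r9/1"]
        counts = species_counts(ids, species=["AlbaX01", "BetaY01", "CruxZ01"])
        assert counts == {"AlbaX01": 2, "BetaY01": 1, "CruxZ01": 0}


class TestAnnotation:
    @pytest.fixture()
    def library(self, rng):
        return ReferenceLibrary(
            [
                ("LTR/Ty3/Tekay", _random_seq(rng, 2000)),
                ("LTR/Ty1/SIRE", _random_seq(rng, 2000)),
            ]
        )

    def _cluster_from(self, seqs, tag="AlbaX01"):
        reads = {f"{tag}r{i:03d}/1": ReadRecord(f"{tag}r{i:03d}/1", s) for i, s in enumerate(seqs)}
        cluster = Cluster("CL1", sorted(reads), {})
        return cluster, reads

    def test_unanimous_vote(self, library, rng):
        tekay = library.entries[0][1]
        seqs = [tekay[i : i + 150] for i in range(0, 1500, 100)]
        cluster, reads = self._cluster_from(seqs)
        annotate_cluster(cluster, reads, library)
        assert cluster.annotation == "LTR/Ty3/Tekay"
        assert not cluster.discordant

    def test_no_matches_is_unknown(self, library, rng):
        seqs = [_random_seq(rng, 150) for _ in range(10)]
        cluster, reads = self._cluster_from(seqs)
        annotate_cluster(cluster, reads, library)
        assert cluster.annotation == "Unknown_repeats"

    def test_even_split_flags_discordant(self, library):
        tekay, sire = library.entries[0][1], library.entries[1][1]
        seqs = [tekay[i : i + 150] for i in range(0, 500, 100)] + [
            sire[i : i + 150] for i in range(0, 500, 100)
        ]
        cluster, reads = self._cluster_from(seqs)
        annotate_cluster(cluster, reads, library)
        assert cluster.discordant
        assert cluster.annotation == "Unknown_repeats"  # 50% < 60% vote

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            annotate_cluster(Cluster("CL1", [], {}), {}, ReferenceLibrary([]))


class TestSuperclusters:
    def _cluster(self, cid, stems, mate, ann):
        ids = [f"{s}/{mate}" for s in stems]
        c = Cluster(cid, ids, {}, annotation=ann)
        return c

    def test_concordant_join(self):
        stems = [f"AlbaX01p{i:03d}" for i in range(20)]
        a = self._cluster("CL1", stems, 1, "LTR/Ty3/Tekay")
        b = self._cluster("CL2", stems, 2, "LTR/Ty3/Tekay")
        scs = build_superclusters([a, b], min_links=5)
        assert len(scs) == 1
        assert scs[0].members == ["CL1", "CL2"]
        assert scs[0].annotation == "LTR/Ty3/Tekay" and not scs[0].dissolved

    def test_discordant_join_dissolved(self):
        stems = [f"AlbaX01p{i:03d}" for i in range(20)]
        a = self._cluster("CL1", stems, 1, "LTR/Ty1/SIRE")
        b = self._cluster("CL2", stems, 2, "satDNA")
        scs = build_superclusters([a, b], min_links=5)
        assert len(scs) == 1 and scs[0].dissolved
        entries = resolve_discordant(scs, [a, b])
        assert ("CL1", "LTR/Ty1/SIRE") in entries
        assert ("CL2", "satDNA") in entries

    def test_no_links_no_joins(self):
        a = self._cluster("CL1", [f"x{i}" for i in range(10)], 1, "satDNA")
        b = self._cluster("CL2", [f"y{i}" for i in range(10)], 1, "satDNA")
        scs = build_superclusters([a, b], min_links=5)
        assert [sc.members for sc in scs] == [["CL1"], ["CL2"]]
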