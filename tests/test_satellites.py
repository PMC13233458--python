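"""Tandem detection, circular identity, satDNA family tiers, naming and
presence/absence summaries."""

import edlib
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatomix import _kmers, satellites, simulate
from repeatomix.io import ReadRecord
from repeatomix.satellites import (
    MonomerConsensus,
    SatFamilyRecord,
    canonical_monomer,
    circular_identity,
    classify_families,
    detect_tandem,
    dimer_periodicity_check,
    jaccard_matrix,
    name_families,
    presence_absence,
    shared_counts,
)


def _reads_from(seq, n, rng, read_len=150, tag="x"):
    out = []
    for i in range(n):
        s = int(rng.integers(0, len(seq) - read_len))
        r = seq[s : s + read_len]
        if rng.random() < 0.5:
            r = _kmers.revcomp(r)
        out.append(ReadRecord(f"{tag}{i:04d}", r))
    return out


def exhaustive_circular_identity(a, b):
    """Oracle: best global-alignment identity over every rotation and both
    strands of b."""
    best = 0.0
    for strand in (b, _kmers.revcomp(b)):
        for i in range(len(strand)):
            rot = strand[i:] + strand[:i]
            d = edlib.align(a, rot, mode="NW", task="distance")["editDistance"]
            best = max(best, 1 - d / max(len(a), len(rot)))
    return 100 * best


class TestDetectTandem:
    def test_perfect_short_monomer(self, rng):
        arr = "ACGTTGCAGT" * 40
        reads = [ReadRecord(f"w{i}", arr[s : s + 60]) for i, s in enumerate(range(0, 340, 4))]
        m = detect_tandem(reads, k=5)
        assert m is not None
        assert m.length == 10
        assert m.circularity_score == pytest.approx(1.0, abs=0.05)
        assert m.confidence == "high"

    def test_non_tandem_element_rejected(self, rng):
        elem = _kmers.decode(rng.integers(0, 4, 2400).astype(np.uint8))
        assert detect_tandem(_reads_from(elem, 300, rng)) is None

    def test_twin_ltr_element_rejected(self, rng):
        el = simulate.generate_ltr_family(300, 1800, seed=9)
        assert detect_tandem(_reads_from(el, 400, rng)) is None

    def test_small_cluster_skipped(self, rng):
        arr = simulate.generate_satellite_family(137, seed=1) * 20
        assert detect_tandem(_reads_from(arr, 10, rng)) is None

    def test_planted_137bp_monomer_recovered(self, rng):
        # 2% copy divergence, ~0.2x-coverage-scale read depth
        mono = simulate.generate_satellite_family(137, seed=3)
        arr = simulate.build_array(mono, 60, 0.02, rng)
        m = detect_tandem(_reads_from(arr, 300, rng), cluster_id="CL9")
        assert m is not None
        assert abs(m.length - 137) <= 1
        assert exhaustive_circular_identity(m.sequence, mono) >= 97.0
        assert m.cluster_id == "CL9"

    def test_rotation_invariant_identity_to_truth(self, rng):
        mono = simulate.generate_satellite_family(98, seed=5)
        arr = simulate.build_array(mono, 80, 0.01, rng)
        m = detect_tandem(_reads_from(arr, 250, rng))
        # the reported canonical rotation scores the same as any rotation
        rot = mono[31:] + mono[:31]
        a = exhaustive_circular_identity(m.sequence, mono)
        b = exhaustive_circular_identity(m.sequence, rot)
        assert a == pytest.approx(b, abs=0.5)

    def test_oversized_k_rejected(self):
        reads = [ReadRecord(f"r{i}", "ACGTACGTAC") for i in range(25)]
        with pytest.raises(ValueError):
            detect_tandem(reads, k=11)


class TestDimerPeriodicity:
    def test_perfect_dimer(self):
        mono = simulate.generate_satellite_family(137, seed=3)
        ok, period = dimer_periodicity_check(mono + mono)
        assert ok and period == 137

    def test_random_sequence_aperiodic(self, rng):
        seq = _kmers.decode(rng.integers(0, 4, 274).astype(np.uint8))
        ok, period = dimer_periodicity_check(seq)
        assert not ok and period is None

    def test_noisy_dimer_within_band_tolerance(self, rng):
        mono = _kmers.encode(simulate.generate_satellite_family(137, seed=3))
        noisy = mono.copy()
        hits = rng.random(len(noisy)) < 0.05
        noisy[hits] = (noisy[hits] + 1) % 4
        ok, period = dimer_periodicity_check(
            _kmers.decode(mono) + _kmers.decode(noisy)
        )
        assert ok and abs(period - 137) <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dimer_periodicity_check("")


class TestCircularIdentity:
    MONO = simulate.generate_satellite_family(137, seed=3)

    def test_rotation_full_identity(self):
        rot = self.MONO[13:] + self.MONO[:13]
        assert circular_identity(self.MONO, rot) == pytest.approx(100.0)

    def test_reverse_complement_full_identity(self):
        assert circular_identity(self.MONO, _kmers.revcomp(self.MONO)) == pytest.approx(100.0)

    def test_symmetry(self, rng):
        other = simulate.generate_satellite_family(120, seed=8)
        assert circular_identity(self.MONO, other) == pytest.approx(
            circular_identity(other, self.MONO)
        )

    def test_matches_exhaustive_oracle_under_mutation(self, rng):
        codes = _kmers.encode(self.MONO)
        hits = rng.random(len(codes)) < 0.10
        codes[hits] = (codes[hits] + rng.integers(1, 4, hits.sum()).astype(np.uint8)) % 4
        mutated = _kmers.decode(codes)
        ours = circular_identity(self.MONO, mutated)
        oracle = exhaustive_circular_identity(self.MONO, mutated)
        assert ours == pytest.approx(oracle, abs=3.0)
        assert 85.0 <= ours <= 95.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circular_identity("", "ACGT")


def _mono(seq, abundance=1.0):
    m = MonomerConsensus.build(seq, score=0.9)
    m.abundance = abundance
    return m


class TestClassification:
    def test_three_tier_examples(self):
        # identities injected directly: 97 -> same monomer variants,
        # 85 -> same family, 60 -> same superfamily only
        idmat = {
            ("a", "b"): 97.0,
            ("a", "c"): 85.0,
            ("b", "c"): 85.0,
            ("a", "d"): 60.0,
            ("b", "d"): 60.0,
            ("c", "d"): 60.0,
        }
        monomers = {
            name: _mono(seq)
            for name, seq in zip(
                ["a:CL1", "b:CL2", "c:CL3", "d:CL4"],
                ["ACGTACGTAC", "ACGTACGTAT", "ACGAACGTAC", "TTTTACGTAC"],
            )
        }
        # identity callable receives sequences; map back via first char trick
        seq_to_key = {m.sequence: name[0] for name, m in monomers.items()}

        def metric(x, y):
            return idmat[tuple(sorted((seq_to_key[x], seq_to_key[y])))]

        records, tiers, _ = classify_families(monomers, identity=metric)
        assert tiers.families == 2           # {a,b,c} and {d}
        assert tiers.monomer_variants == 1   # b merged into a at >95
        assert tiers.family_variants == 1    # c's variant group joins {a,b}
        assert tiers.superfamilies == 1
        fam_members = sorted(sorted(r.members) for r in records)
        assert fam_members == [["a:CL1", "b:CL2", "c:CL3"], ["d:CL4"]]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=3, max_size=21))
    def test_tier_nesting_property(self, flat):
        # for any symmetric identity matrix, variant groups nest inside
        # families, which nest inside superfamilies
        n = int(np.floor((1 + np.sqrt(1 + 8 * len(flat))) / 2))
        if n < 3:
            return
        names = [f"g{i}:CL{i}" for i in range(n)]
        mat = np.zeros((n, n))
        it = iter(flat)
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    mat[i, j] = mat[j, i] = next(it)
                except StopIteration:
                    mat[i, j] = mat[j, i] = 0.0
        monomers = {}
        by_len = {}
        for i, name in enumerate(names):
            # unique lengths survive monomer canonicalization
            seq = "ACGTACG" + "A" * (i + 1) + "CCG"
            monomers[name] = _mono(seq)
            by_len[len(monomers[name].sequence)] = i

        def metric(x, y):
            return mat[by_len[len(x)], by_len[len(y)]]

        records, tiers, _ = classify_families(monomers, identity=metric)
        assert tiers.families >= tiers.superfamilies
        for rec in records:
            for grp in rec.monomer_variant_groups:
                assert set(grp) <= set(rec.members)
        all_members = [m for rec in records for m in rec.members]
        assert sorted(all_members) == sorted(names)


class TestNaming:
    def _record(self, genotype, abundance, length, rep="m"):
        rec = SatFamilyRecord(members=[f"{genotype}:CL1"])
        rec.genotypes_present = {genotype}
        rec.abundance = {genotype: abundance}
        rec.monomer_length = length
        rec.representative = rep
        return rec

    def test_rank_by_abundance_with_monomer_length_suffix(self):
        records = [
            self._record("SoffBla", 1.0, 365, "b"),
            self._record("SoffBla", 3.4, 137, "a"),
        ]
        named = name_families(records)
        assert named[0].name == "SoffSat01-137"
        assert named[1].name == "SoffSat02-365"

    def test_bad_prefix_rejected(self):
        rec = self._record("SoffBla", 1.0, 137)
        with pytest.raises(ValueError):
            name_families([rec], species_prefix_of=lambda g: "So")


class TestSharedContent:
    PA = pd.DataFrame(
        {
            "Sat01-137": [True, True, True],
            "Sat02-365": [True, True, False],
            "Sat03-210": [True, False, False],
        },
        index=["AlbaX01", "BetaY01", "CruxZ01"],
    )

    def test_jaccard_examples(self):
        j = jaccard_matrix(self.PA)
        assert j.loc["AlbaX01", "AlbaX01"] == 1.0
        assert j.loc["AlbaX01", "BetaY01"] == pytest.approx(2 / 3)
        assert j.loc["BetaY01", "CruxZ01"] == pytest.approx(1 / 2)
        assert np.allclose(j.values, j.values.T)
        assert ((j.values >= 0) & (j.values <= 1)).all()

    def test_empty_genotype_convention(self):
        pa = pd.DataFrame({"SatX": [True, False]}, index=["AlbaX01", "BetaY01"])
        j = jaccard_matrix(pa)
        assert j.loc["AlbaX01", "BetaY01"] == 0.0

    def test_shared_counts(self):
        fam_counts, tallies = shared_counts(self.PA)
        assert fam_counts["Sat01-137"] == 3
        assert tallies["AlbaX01,BetaY01,CruxZ01"] == 1

    def test_presence_absence_no_empty_columns(self):
        rec = SatFamilyRecord(members=["AlbaX01:CL2"], genotypes_present=set())
        rec.name = "x"
        pa = presence_absence([rec], ["AlbaX01"])
        assert pa.empty or (pa.sum(axis=0) > 0).all()


def test_canonical_monomer_invariance():
    seq = simulate.generate_satellite_family(53, seed=4)
    rot = seq[17:] + seq[:17]
    assert canonical_monomer(seq) == canonical_monomer(rot)
    assert canonical_monomer(seq) == canonical_monomer(_kmers.revcomp(seq))


def test_universal_satellite_detected_everywhere(e2e):
    result, ev = e2e
    sat = ev["satellites"]["Sat-137"]
    assert sat["species_detected"] == len(result.sim.species)
    assert all(abs(l - 137) <= 1 for l in sat["lengths"])
    assert sat["one_family"]
    members = [m for m in result.monomers if m.endswith(":" + sat["cluster"])]
    assert all(result.monomers[m].confidence == "high" for m in members)
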