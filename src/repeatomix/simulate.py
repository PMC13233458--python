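"""Synthetic repeatome generator.

Builds multi-species genomes with planted repeat families — LTR
retrotransposons with twin terminal repeats and ordered internal domains,
tandem satellite arrays, and generic dispersed elements — plus paired-end
reads, together with a machine-readable truth table. Shared families are
evolved along a known species tree so that downstream similarity-based
analyses have a recoverable phylogenetic signal.

Model assumptions (v1): Jukes-Cantor-like substitution only (per-site Poisson
events, each replacing the base with one of the three alternatives), no
indels, copies placed non-overlapping at uniformly random positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from bisect import bisect_left, insort
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import _kmers
from .io import ReadRecord, write_fasta, write_fastq
from .trees import Node, parse_newick, patristic_distances

DOMAIN_ORDER = ("GAG", "PROT", "INT", "RT", "RH", "CHD")
DOMAIN_MARKER_LEN = 60

# Fixed synthetic nucleotide markers standing in for the conserved core of
# each retrotransposon protein domain. Deterministic across sessions.
_marker_rng = np.random.default_rng(900913)
DOMAIN_MARKERS: dict[str, str] = {
    label: _kmers.decode(_marker_rng.integers(0, 4, DOMAIN_MARKER_LEN).astype(np.uint8))
    for label in DOMAIN_ORDER
}
del _marker_rng


# ---------------------------------------------------------------------------
# specs and truth table
# ---------------------------------------------------------------------------


@dataclass
class RepeatFamilySpec:
    """Generative description of one planted repeat family."""

    family_id: str
    lineage: str                      # hierarchical label, e.g. "LTR/Ty3/Tekay"
    element_length: int               # bp of one placed copy (array length for satellites)
    target_proportion: float          # percent of genome, per carrying species
    ltr_length: int = 0               # 0 for non-LTR kinds
    monomer_length: int = 0           # satellites only
    copy_divergence: float = 0.01     # subs/site among copies within a genome
    ltr_age_rate: float = 0.0         # per-LTR divergence applied to the template pair
    ancestral_ltr: bool = False       # True: cohort inserted before speciation
    species: Optional[list[str]] = None  # None -> present in every species

    def __post_init__(self) -> None:
        if self.ltr_length and self.element_length < 2 * self.ltr_length:
            raise ValueError(f"{self.family_id}: element shorter than its two LTRs")
        if self.monomer_length and self.monomer_length < 7:
            raise ValueError(f"{self.family_id}: monomer length must be >= 7 bp")
        if self.target_proportion < 0:
            raise ValueError(f"{self.family_id}: negative target proportion")


@dataclass
class SpeciesSpec:
    code: str                         # exactly 7 characters
    genome_size: int
    family_proportions: dict[str, float] = field(default_factory=dict)
    background_gc: float = 0.44

    def __post_init__(self) -> None:
        if len(self.code) != 7:
            raise ValueError(f"genotype code must have 7 characters: {self.code!r}")
        if self.genome_size <= 0:
            raise ValueError("genome size must be positive")
        if sum(self.family_proportions.values()) >= 100:
            raise ValueError(f"{self.code}: family proportions sum to >= 100%")


@dataclass
class PhylogenySpec:
    newick: str

    def __post_init__(self) -> None:
        self.root: Node = parse_newick(self.newick)
        names = self.root.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaves in species tree")

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()


@dataclass
class TruthTable:
    """Ground truth emitted alongside each synthetic genome set.

    ``copies`` has one row per planted copy: species, family_id, lineage,
    start, end (0-based half-open), ltr_identity (percent, NaN for non-LTR).
    """

    copies: pd.DataFrame
    realized: dict[str, dict[str, float]]          # species -> family -> percent
    monomers: dict[tuple[str, str], str]           # (species, family) -> monomer
    tree_newick: str

    def total_repeat_fraction(self, species: str) -> float:
        return float(sum(self.realized[species].values()))

    def family_proportion(self, species: str, family_id: str) -> float:
        return self.realized[species].get(family_id, 0.0)

    def write(self, path) -> None:
        self.copies.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence-level generators
# ---------------------------------------------------------------------------


def _random_codes(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply substitutions at an expected `rate` events per site (JC-like).

    Each event replaces the base with one of the other three, so repeated
    hits at a site can revert it; the observed p-distance follows the
    Jukes-Cantor expectation (3/4)(1 - exp(-4 rate / 3)).
    """
    if rate < 0:
        raise ValueError("substitution rate must be >= 0")
    out = codes.copy()
    if rate == 0:
        return out
    hits = rng.poisson(rate, size=out.shape[0])
    rounds = int(hits.max()) if hits.size else 0
    for i in range(rounds):
        idx = np.nonzero(hits > i)[0]
        out[idx] = (out[idx] + rng.integers(1, 4, size=idx.shape[0]).astype(np.uint8)) % 4
    return out


def generate_ltr_family(
    ltr_length: int,
    internal_length: int,
    domain_order: tuple[str, ...] = DOMAIN_ORDER,
    seed: int = 0,
) -> str:
    """Template LTR element: identical 5'/3' LTRs around an internal region
    that embeds the given domain markers in order."""
    if ltr_length < 50:
        raise ValueError("ltr_length must be >= 50 bp")
    if internal_length <= 0:
        raise ValueError("internal_length must be positive")
    for label in domain_order:
        if label not in DOMAIN_MARKERS:
            raise ValueError(f"unknown domain label: {label}")
    need = len(domain_order) * DOMAIN_MARKER_LEN
    if internal_length < need:
        raise ValueError("internal region too short for requested domains")
    rng = np.random.default_rng(seed)
    ltr = _random_codes(rng, ltr_length)
    internal = _random_codes(rng, internal_length)
    # spread the domains evenly through the internal region
    n = len(domain_order)
    gap = (internal_length - need) // (n + 1)
    pos = gap
    for label in domain_order:
        marker = _kmers.encode(DOMAIN_MARKERS[label])
        internal[pos : pos + DOMAIN_MARKER_LEN] = marker
        pos += DOMAIN_MARKER_LEN + gap
    return _kmers.decode(np.concatenate([ltr, internal, ltr]))


def age_ltr_pair(element: str, ltr_length: int, rate: float, rng: np.random.Generator) -> str:
    """Mutate the two terminal repeats independently at `rate` subs/site,
    emulating post-insertion divergence of an LTR pair."""
    codes = _kmers.encode(element)
    codes[:ltr_length] = mutate_codes(codes[:ltr_length], rate, rng)
    codes[-ltr_length:] = mutate_codes(codes[-ltr_length:], rate, rng)
    return _kmers.decode(codes)


def ltr_pair_identity(element: str, ltr_length: int) -> float:
    """Percent identity between the element's terminal repeats (no indels)."""
    a = _kmers.encode(element[:ltr_length])
    b = _kmers.encode(element[-ltr_length:])
    return 100.0 * float(np.mean(a == b))


def generate_satellite_family(monomer_length: int, seed: int = 0) -> str:
    if monomer_length < 7:
        raise ValueError("monomer_length must be >= 7 bp")
    rng = np.random.default_rng(seed)
    return _kmers.decode(_random_codes(rng, monomer_length, gc=0.42))


def build_array(
    monomer: str,
    copies: int,
    copy_divergence: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Tandem array of `copies` monomers, each independently mutated."""
    if copies <= 0:
        raise ValueError("copies must be positive")
    rng = rng or np.random.default_rng(0)
    codes = _kmers.encode(monomer)
    parts = [mutate_codes(codes, copy_divergence, rng) for _ in range(copies)]
    return _kmers.decode(np.concatenate(parts))


def evolve_family_on_tree(
    template: str, tree: PhylogenySpec, seed: int = 0
) -> dict[str, str]:
    """Evolve a template along the species tree; one variant per leaf.

    Substitutions accumulate along each branch at its length (subs/site);
    zero-length paths give identical variants.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}

    def recurse(node: Node, codes: np.ndarray) -> None:
        for child in node.children:
            evolved = mutate_codes(codes, child.length, rng)
            if child.is_leaf:
                out[child.name] = _kmers.decode(evolved)
            else:
                recurse(child, evolved)

    recurse(tree.root, _kmers.encode(template))
    return out


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


class _Placer:
    """Non-overlapping uniform placement with per-family minimum spacing."""

    def __init__(self, genome_size: int, rng: np.random.Generator, family_spacing: int):
        self.G = genome_size
        self.rng = rng
        self.spacing = family_spacing
        self.starts: list[int] = []
        self.ends: list[int] = []
        self.by_family: dict[str, list[int]] = {}

    def place(self, family_id: str, length: int, tries: int = 20000) -> int:
        fam = self.by_family.setdefault(family_id, [])
        for _ in range(tries):
            pos = int(self.rng.integers(0, self.G - length + 1))
            i = bisect_left(self.starts, pos)
            if i > 0 and self.ends[i - 1] > pos:
                continue
            if i < len(self.starts) and self.starts[i] < pos + length:
                continue
            j = bisect_left(fam, pos)
            if j > 0 and pos - fam[j - 1] < self.spacing:
                continue
            if j < len(fam) and fam[j] - pos < self.spacing:
                continue
            self.starts.insert(i, pos)
            self.ends.insert(i, pos + length)
            insort(fam, pos)
            return pos
        raise RuntimeError(
            f"could not place a copy of {family_id}: proportions likely infeasible"
        )


def build_genome(
    spec: SpeciesSpec,
    families: dict[str, tuple[RepeatFamilySpec, str]],
    seed: int = 0,
    family_spacing: int = 30_000,
) -> tuple[str, pd.DataFrame, dict[str, float]]:
    """Assemble one genome from background plus planted family copies.

    ``families`` maps family_id to (spec, species-specific template). Returns
    (genome, per-copy truth rows, realized per-family proportions in percent).
    Satellite templates are monomers; each placed copy is a freshly built
    tandem array. Other templates are placed whole, mutated per copy.
    """
    total = sum(
        spec.family_proportions.get(fid, 0.0) for fid in families
    )
    if total >= 100:
        raise ValueError("total family proportions exceed the genome")
    rng = np.random.default_rng(seed)
    genome = _random_codes(rng, spec.genome_size, gc=spec.background_gc)
    placer = _Placer(spec.genome_size, rng, family_spacing)
    rows: list[dict] = []
    realized: dict[str, float] = {}
    for fid in sorted(families):
        fam, template = families[fid]
        prop = spec.family_proportions.get(fid, 0.0)
        if prop <= 0:
            continue
        n_copies = max(1, round(prop / 100 * spec.genome_size / fam.element_length))
        placed_bp = 0
        for _ in range(n_copies):
            if fam.monomer_length:
                reps = fam.element_length // fam.monomer_length
                copy_seq = _kmers.encode(
                    build_array(template, reps, fam.copy_divergence, rng)
                )
            else:
                copy_seq = mutate_codes(_kmers.encode(template), fam.copy_divergence, rng)
            length = copy_seq.shape[0]
            pos = placer.place(fid, length)
            genome[pos : pos + length] = copy_seq
            placed_bp += length
            ident = (
                100.0 * float(np.mean(copy_seq[: fam.ltr_length] == copy_seq[-fam.ltr_length :]))
                if fam.ltr_length
                else np.nan
            )
            rows.append(
                dict(
                    species=spec.code,
                    family_id=fid,
                    lineage=fam.lineage,
                    start=pos,
                    end=pos + length,
                    length=length,
                    ltr_length=fam.ltr_length,
                    ltr_identity=ident,
                )
            )
        realized[fid] = 100.0 * placed_bp / spec.genome_size
    truth = pd.DataFrame(
        rows,
        columns=[
            "species", "family_id", "lineage", "start", "end",
            "length", "ltr_length", "ltr_identity",
        ],
    )
    return _kmers.decode(genome), truth, realized


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadPairSet:
    reads1: list[ReadRecord]
    reads2: list[ReadRecord]
    # per pair: (start1, end1, start2, end2) on the source genome
    coords: list[tuple[int, int, int, int]]


def simulate_reads(
    genome: str,
    coverage: float,
    read_length: int = 150,
    insert: int = 400,
    error_rate: float = 0.0,
    seed: int = 0,
    id_stem: str = "r",
) -> ReadPairSet:
    """Paired-end reads at the requested fold coverage.

    Pair count = round(coverage * G / (2 * read_length)). Error bases are
    substituted at `error_rate` per base and assigned phred 15; correct bases
    get phred 37, so a phred-30 filter removes exactly the errored reads.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if insert < 2 * read_length:
        raise ValueError("insert size smaller than two read lengths")
    G = len(genome)
    n_pairs = round(coverage * G / (2 * read_length))
    rng = np.random.default_rng(seed)
    codes = _kmers.encode(genome)
    inserts = np.clip(
        np.rint(rng.normal(insert, 0.08 * insert, n_pairs)).astype(int),
        2 * read_length,
        G,
    )
    starts = (rng.random(n_pairs) * (G - inserts + 1)).astype(int)
    reads1: list[ReadRecord] = []
    reads2: list[ReadRecord] = []
    coords: list[tuple[int, int, int, int]] = []
    base_q = 37
    err_q = 15
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        f = codes[s : s + read_length].copy()
        r = _kmers.revcomp_codes(codes[s + ins - read_length : s + ins])
        q1 = [base_q] * read_length
        q2 = [base_q] * read_length
        if error_rate > 0:
            for arr, q in ((f, q1), (r, q2)):
                errs = np.nonzero(rng.random(read_length) < error_rate)[0]
                if errs.size:
                    arr[errs] = (
                        arr[errs] + rng.integers(1, 4, errs.size).astype(np.uint8)
                    ) % 4
                    for e in errs:
                        q[e] = err_q
        stem = f"{id_stem}{i:06d}"
        reads1.append(ReadRecord(f"{stem}/1", _kmers.decode(f), q1))
        reads2.append(ReadRecord(f"{stem}/2", _kmers.decode(r), q2))
        coords.append((s, s + read_length, s + ins - read_length, s + ins))
    return ReadPairSet(reads1, reads2, coords)


# ---------------------------------------------------------------------------
# the default study scenario
# ---------------------------------------------------------------------------

DEFAULT_TREE = (
    "(((AlbaX01:0.005,AlbaX02:0.005):0.015,(BetaY01:0.01,BetaY02:0.01):0.01):0.005,"
    "(CruxZ01:0.0125,CruxZ02:0.0125):0.0125);"
)
DEFAULT_CODES = ["AlbaX01", "AlbaX02", "BetaY01", "BetaY02", "CruxZ01", "CruxZ02"]
DEFAULT_GENOME_SIZE = 5_000_000
DEFAULT_COVERAGE = 0.35           # raw simulated coverage, before filtering/sampling
DEFAULT_ERROR_RATE = 0.002
SAT_MONOMER_MAIN = 137            # centromere-like satellite, planted in every species
SAT_MONOMER_SECOND = 365


def _default_families() -> list[RepeatFamilySpec]:
    """The fixed family library of the default scenario.

    36 shared dispersed families (12 of them structurally complete LTR
    elements), two shared satellites (137 bp and 365 bp monomers) and a small
    set of lineage-specific families. Proportions sum to ~45% per species.
    """
    fams: list[RepeatFamilySpec] = []

    def ltr(fid, lineage, internal, prop, age, ancestral=False):
        fams.append(
            RepeatFamilySpec(
                family_id=fid, lineage=lineage, element_length=600 + internal,
                target_proportion=prop, ltr_length=300, copy_divergence=0.005,
                ltr_age_rate=age, ancestral_ltr=ancestral,
            )
        )

    def disp(fid, lineage, length, prop, species=None):
        fams.append(
            RepeatFamilySpec(
                family_id=fid, lineage=lineage, element_length=length,
                target_proportion=prop, copy_divergence=0.015, species=species,
            )
        )

    # LTR retrotransposon families (young unless noted). Element lengths
    # scale with target proportion so every family plants ~25 copies per
    # genome: at desk scale this preserves the per-template read depth that
    # real high-copy families have, which is what read-overlap connectivity
    # depends on.
    ltr("SIRE-1", "LTR/Ty1/SIRE", 3400, 2.0, 0.005)
    ltr("SIRE-2", "LTR/Ty1/SIRE", 1600, 1.1, 0.005)
    ltr("SIRE-3", "LTR/Ty1/SIRE", 1200, 0.9, 0.010)
    ltr("Ale-1", "LTR/Ty1/Ale", 1000, 0.8, 0.005)
    ltr("Angela-1", "LTR/Ty1/Angela", 1800, 1.2, 0.010)
    ltr("Tekay-1", "LTR/Ty3/Tekay", 3800, 2.2, 0.005)
    ltr("Tekay-2", "LTR/Ty3/Tekay", 2800, 1.7, 0.005)
    ltr("Tekay-3", "LTR/Ty3/Tekay", 1400, 1.0, 0.010)
    ltr("Retand-1", "LTR/Ty3/Retand", 2400, 1.5, 0.040, ancestral=True)
    ltr("Ogre-1", "LTR/Ty3/Ogre", 1000, 0.8, 0.020)
    ltr("Athila-1", "LTR/Ty3/Athila", 1800, 1.2, 0.005)   # young cohort
    ltr("Athila-2", "LTR/Ty3/Athila", 1800, 1.2, 0.075, ancestral=True)  # old cohort
    # dispersed non-LTR families
    disp("LINE-1", "LINE/L1", 2800, 1.4)
    disp("LINE-2", "LINE/RTE", 1400, 0.7)
    disp("CACTA-1", "DNA/EnSpm_CACTA", 2400, 1.2)
    disp("CACTA-2", "DNA/EnSpm_CACTA", 1200, 0.6)
    disp("hAT-1", "DNA/hAT", 1200, 0.6)
    disp("PararetroV-1", "Pararetrovirus", 1000, 0.5)
    disp("rDNA-45S", "rDNA/45S", 2800, 1.4)
    disp("rDNA-5S", "rDNA/5S", 800, 0.4)
    disp("SIRE-d1", "LTR/Ty1/SIRE", 3600, 1.8)
    disp("SIRE-d2", "LTR/Ty1/SIRE", 1600, 0.8)
    disp("Ale-d1", "LTR/Ty1/Ale", 1200, 0.6)
    disp("Angela-d1", "LTR/Ty1/Angela", 1400, 0.7)
    disp("Tekay-d1", "LTR/Ty3/Tekay", 4000, 2.0)
    disp("Tekay-d2", "LTR/Ty3/Tekay", 2000, 1.0)
    disp("Retand-d1", "LTR/Ty3/Retand", 1800, 0.9)
    disp("Ogre-d1", "LTR/Ty3/Ogre", 2400, 1.2)
    disp("LINE-3", "LINE/L1", 1200, 0.6)
    disp("CACTA-3", "DNA/EnSpm_CACTA", 1200, 0.6)
    disp("Unknown-1", "__novel__", 2600, 1.3)
    disp("Unknown-2", "__novel__", 1400, 0.7)
    disp("Unknown-3", "__novel__", 1200, 0.6)
    disp("Unknown-4", "__novel__", 2400, 1.2)
    disp("Unknown-5", "__novel__", 1200, 0.6)
    disp("Unknown-6", "__novel__", 1200, 0.6)
    # shared satellites
    fams.append(
        RepeatFamilySpec(
            family_id="Sat-137", lineage="satDNA", element_length=137 * 29,
            target_proportion=2.4, monomer_length=SAT_MONOMER_MAIN,
            copy_divergence=0.01,
        )
    )
    fams.append(
        RepeatFamilySpec(
            family_id="Sat-365", lineage="satDNA", element_length=365 * 11,
            target_proportion=1.0, monomer_length=SAT_MONOMER_SECOND,
            copy_divergence=0.01,
        )
    )
    # lineage-specific families
    fams.append(
        RepeatFamilySpec(
            family_id="Sat-Alba", lineage="satDNA", element_length=210 * 19,
            target_proportion=0.8, monomer_length=210, copy_divergence=0.01,
            species=["AlbaX01", "AlbaX02"],
        )
    )
    fams.append(
        RepeatFamilySpec(
            family_id="Sat-Crux", lineage="satDNA", element_length=156 * 26,
            target_proportion=0.8, monomer_length=156, copy_divergence=0.01,
            species=["CruxZ01", "CruxZ02"],
        )
    )
    fams.append(
        RepeatFamilySpec(
            family_id="Sat-BetaY01", lineage="satDNA", element_length=98 * 41,
            target_proportion=0.6, monomer_length=98, copy_divergence=0.01,
            species=["BetaY01"],
        )
    )
    disp("Unknown-Beta", "__novel__", 500, 0.7, species=["BetaY01", "BetaY02"])
    return fams


@dataclass
class SimulationResult:
    species: list[SpeciesSpec]
    families: list[RepeatFamilySpec]
    tree: PhylogenySpec
    genomes: dict[str, str]
    truth: TruthTable
    pairs: dict[str, ReadPairSet]
    templates: dict[str, dict[str, str]]   # family_id -> species -> variant

    def read_family_labels(self, species: str) -> list[Optional[str]]:
        """Truth family per read (both mates, interleaved r1,r2 order).

        A read belongs to the family whose planted copy contains its
        midpoint; background reads map to None.
        """
        sub = self.truth.copies[self.truth.copies.species == species]
        starts = sub.start.to_numpy()
        order = np.argsort(starts)
        starts = starts[order]
        ends = sub.end.to_numpy()[order]
        fids = sub.family_id.to_numpy()[order]
        labels: list[Optional[str]] = []
        for (s1, e1, s2, e2) in self.pairs[species].coords:
            for s, e in ((s1, e1), (s2, e2)):
                mid = (s + e) // 2
                i = np.searchsorted(starts, mid, side="right") - 1
                if i >= 0 and mid < ends[i]:
                    labels.append(str(fids[i]))
                else:
                    labels.append(None)
        return labels


def default_scenario(
    seed: int = 0,
    genome_size: int = DEFAULT_GENOME_SIZE,
    coverage: float = DEFAULT_COVERAGE,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> SimulationResult:
    """Generate the default six-species study scenario.

    Every source of randomness derives from `seed` via numpy SeedSequence
    spawning, so identical seeds give byte-identical genomes and reads.
    """
    families = _default_families()
    tree = PhylogenySpec(DEFAULT_TREE)
    species = [
        SpeciesSpec(
            code=code,
            genome_size=genome_size,
            family_proportions={
                f.family_id: f.target_proportion
                for f in families
                if f.species is None or code in f.species
            },
        )
        for code in DEFAULT_CODES
    ]
    ss_templates, ss_genomes, ss_reads = np.random.SeedSequence(seed).spawn(3)
    template_seeds = ss_templates.generate_state(len(families))
    genome_seeds = ss_genomes.generate_state(len(species))
    read_seeds = ss_reads.generate_state(len(species))

    # family templates, evolved on the species tree
    templates: dict[str, dict[str, str]] = {}
    for fam, tseed in zip(families, template_seeds):
        tseed = int(tseed % (2**31))
        rng = np.random.default_rng(tseed)
        if fam.monomer_length:
            template = generate_satellite_family(fam.monomer_length, tseed)
        elif fam.ltr_length:
            internal = fam.element_length - 2 * fam.ltr_length
            template = generate_ltr_family(fam.ltr_length, internal, DOMAIN_ORDER, tseed)
            if fam.ancestral_ltr:
                # pre-speciation cohort: the LTR pair had already diverged in
                # the common ancestor, so the divergence is shared by all
                # descendant species
                template = age_ltr_pair(template, fam.ltr_length, fam.ltr_age_rate, rng)
        else:
            template = _kmers.decode(_random_codes(rng, fam.element_length))
        variants = evolve_family_on_tree(template, tree, seed=tseed)
        if fam.ltr_length and not fam.ancestral_ltr:
            # post-speciation cohort: each species carries its own insertions,
            # whose LTR pairs start identical and then diverge by the cohort
            # age — species divergence must not leak into the pair identity
            L = fam.ltr_length
            for i, code in enumerate(sorted(variants)):
                codes = _kmers.encode(variants[code])
                codes[-L:] = codes[:L]
                aged = age_ltr_pair(
                    _kmers.decode(codes), L, fam.ltr_age_rate,
                    np.random.default_rng([tseed, i]),
                )
                variants[code] = aged
        if fam.species is not None:
            variants = {c: v for c, v in variants.items() if c in fam.species}
        templates[fam.family_id] = variants

    genomes: dict[str, str] = {}
    truth_frames: list[pd.DataFrame] = []
    realized: dict[str, dict[str, float]] = {}
    monomers: dict[tuple[str, str], str] = {}
    pairs: dict[str, ReadPairSet] = {}
    fam_by_id = {f.family_id: f for f in families}
    for sp, gseed, rseed in zip(species, genome_seeds, read_seeds):
        fams_here = {
            fid: (fam_by_id[fid], templates[fid][sp.code])
            for fid in sp.family_proportions
        }
        genome, copy_rows, real = build_genome(sp, fams_here, seed=int(gseed % (2**31)))
        genomes[sp.code] = genome
        truth_frames.append(copy_rows)
        realized[sp.code] = real
        for fid, (fam, variant) in fams_here.items():
            if fam.monomer_length:
                monomers[(sp.code, fid)] = variant
        pairs[sp.code] = simulate_reads(
            genome, coverage, error_rate=error_rate, seed=int(rseed % (2**31)),
            id_stem=f"{sp.code}_",
        )
    truth = TruthTable(
        copies=pd.concat(truth_frames, ignore_index=True),
        realized=realized,
        monomers=monomers,
        tree_newick=DEFAULT_TREE,
    )
    return SimulationResult(
        species=species, families=families, tree=tree, genomes=genomes,
        truth=truth, pairs=pairs, templates=templates,
    )


def write_scenario(result: SimulationResult, outdir, seed: int) -> None:
    """Write genomes (FASTA), reads (gzip FASTQ), truth table (TSV) and a
    JSON manifest recording seeds and parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for code, genome in result.genomes.items():
        write_fasta([(code, genome)], outdir / f"{code}.genome.fasta")
        write_fastq(result.pairs[code].reads1, outdir / f"{code}_R1.fastq.gz")
        write_fastq(result.pairs[code].reads2, outdir / f"{code}_R2.fastq.gz")
    result.truth.write(outdir / "truth_copies.tsv")
    manifest = {
        "seed": seed,
        "tree": result.tree.newick,
        "species": [
            {"code": s.code, "genome_size": s.genome_size, "background_gc": s.background_gc}
            for s in result.species
        ],
        "families": [
            {
                "family_id": f.family_id, "lineage": f.lineage,
                "element_length": f.element_length, "ltr_length": f.ltr_length,
                "monomer_length": f.monomer_length,
                "target_proportion": f.target_proportion,
                "copy_divergence": f.copy_divergence,
                "ltr_age_rate": f.ltr_age_rate, "species": f.species,
            }
            for f in result.families
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
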