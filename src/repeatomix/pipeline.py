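"""Run orchestration: simulate -> prep -> cluster -> satellites -> phylogeny
-> LTR structure -> consolidated report.

A run is described by a :class:`RunConfig`; all randomness flows from its
root seed. The comparative mode pools all genotypes (reads tagged with their
7-character codes) into one clustering; the individual mode analyzes each
genotype separately. Outputs are plain TSV/FASTA/Newick/NEXUS/GFF3 files
plus a JSON manifest recording parameters, seeds, stage wall-clock and
output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clustering, ltr, phylogeny, readprep, satellites, simulate
from .clustering import Cluster, ReferenceLibrary
from .io import ReadRecord, write_fasta
from .trees import Node, to_newick

log = logging.getLogger(__name__)

# lineage label -> abundance-table category
def lineage_category(lineage: str) -> str:
    if lineage.startswith("LTR/Ty1/"):
        sub = lineage.split("/")[2]
        return sub if sub in ("SIRE", "Ale") else "Ty1_other"
    if lineage.startswith("LTR/Ty3/"):
        sub = lineage.split("/")[2]
        return sub if sub in ("Tekay", "Retand", "Athila") else "Ty3_other"
    if lineage.startswith("LINE"):
        return "LINE"
    if lineage.startswith("Pararetrovirus"):
        return "Pararetrovirus"
    if lineage.startswith("DNA/EnSpm_CACTA"):
        return "EnSpm_CACTA"
    if lineage.startswith("DNA/"):
        return "DNA_other"
    if lineage.startswith("rDNA"):
        return "rDNA"
    if lineage.startswith("satDNA"):
        return "satDNA"
    return "Unclassified"


@dataclass
class RunConfig:
    mode: str = "comparative"            # or "individual"
    seed: int = 0
    outdir: Optional[str] = None
    reads_per_genotype: int = 6000       # analyzed reads (half that many pairs)
    genome_size: int = simulate.DEFAULT_GENOME_SIZE
    coverage: float = simulate.DEFAULT_COVERAGE
    error_rate: float = simulate.DEFAULT_ERROR_RATE
    target_read_length: int = 150
    min_phred: int = 30
    top_n_phylo: int = phylogeny.TOP_N_CLUSTERS
    consensus_threshold: float = phylogeny.CONSENSUS_THRESHOLD
    run_ltr: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("comparative", "individual"):
            raise ValueError("mode must be 'comparative' or 'individual'")
        if self.reads_per_genotype % 2:
            raise ValueError("reads_per_genotype must be even")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(open(path)) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    config: RunConfig
    sim: simulate.SimulationResult
    analyzed: dict[str, list[ReadRecord]]
    clusters: list[Cluster]
    reported: list[Cluster]
    superclusters: list
    library: ReferenceLibrary
    monomers: dict[str, satellites.MonomerConsensus]
    sat_records: list[satellites.SatFamilyRecord]
    sat_tiers: Optional[satellites.TierCounts]
    presence_absence: pd.DataFrame
    jaccard: pd.DataFrame
    oe_matrices: list
    nj_trees: dict[str, Node]
    splits: Optional[phylogeny.SplitSystem]
    excluded: list
    ltr_annotations: list[ltr.LTRAnnotation]
    age_profiles: list[ltr.LineageAgeProfile]
    abundance: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def build_reference_library(sim: simulate.SimulationResult) -> ReferenceLibrary:
    """REXdb-style exemplar library from the scenario's known (non-novel)
    family templates; satellites are represented by tripled monomers so that
    150 bp reads align as infixes."""
    entries: list[tuple[str, str]] = []
    for fam in sim.families:
        if fam.lineage == "__novel__":
            continue
        variants = sim.templates[fam.family_id]
        code = sorted(variants)[0]
        seq = variants[code]
        if fam.monomer_length:
            reps = max(3, (350 // fam.monomer_length) + 2)
            seq = seq * reps
        entries.append((fam.lineage, seq))
    return ReferenceLibrary(entries)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    timings: dict[str, float] = {}
    t0 = time.time()

    sim = simulate.default_scenario(
        seed=config.seed,
        genome_size=config.genome_size,
        coverage=config.coverage,
        error_rate=config.error_rate,
    )
    timings["simulate"] = time.time() - t0

    # --- read prep -------------------------------------------------------
    t0 = time.time()
    analyzed: dict[str, list[ReadRecord]] = {}
    prep_seed = np.random.SeedSequence(config.seed).spawn(1)[0]
    sample_seeds = prep_seed.generate_state(len(sim.species))
    for sp, sseed in zip(sim.species, sample_seeds):
        pairs = sim.pairs[sp.code]
        r1, r2 = readprep.trim_and_filter(
            pairs.reads1, pairs.reads2,
            target_length=config.target_read_length, min_phred=config.min_phred,
        )
        interlaced = readprep.interlace(r1, r2)
        sampled = readprep.sample_reads(
            interlaced, config.reads_per_genotype,
            seed=int(sseed % (2**31)), genome_size=sp.genome_size,
        )
        analyzed[sp.code] = readprep.affix_prefix(sampled.records, sp.code)
    timings["read_prep"] = time.time() - t0

    # --- clustering ------------------------------------------------------
    t0 = time.time()
    species_codes = [sp.code for sp in sim.species]
    if config.mode == "comparative":
        allreads: list[ReadRecord] = []
        for code in species_codes:
            allreads.extend(analyzed[code])
    else:
        allreads = analyzed[species_codes[0]]
    edges = clustering.pairwise_similarity(allreads)
    graph = clustering.build_graph(allreads, edges)
    clusters = clustering.cluster_graph(graph, allreads, species=species_codes)
    total_reads = len(allreads)
    for c in clusters:
        c.genome_proportion = clustering.genome_proportion(c.size, total_reads)
    reported = clustering.filter_clusters(clusters)
    timings["clustering"] = time.time() - t0

    # --- annotation ------------------------------------------------------
    t0 = time.time()
    library = build_reference_library(sim)
    reads_by_id = {r.id: r for r in allreads}
    lib_index = clustering._library_index(library)
    for c in reported:
        clustering.annotate_cluster(c, reads_by_id, library, _index=lib_index)
    superclusters = clustering.build_superclusters(reported)
    timings["annotation"] = time.time() - t0

    # --- satellites ------------------------------------------------------
    t0 = time.time()
    monomers: dict[str, satellites.MonomerConsensus] = {}
    species_totals = {code: len(analyzed[code]) for code in species_codes}
    for c in reported:
        if c.size < satellites.MIN_CLUSTER_READS:
            continue
        cluster_reads = [reads_by_id[rid] for rid in c.read_ids]
        hit = satellites.detect_tandem(cluster_reads, cluster_id=c.cluster_id)
        if hit is None:
            continue
        for code in species_codes:
            sp_reads = [
                r for r in cluster_reads if r.id.startswith(code)
            ]
            if len(sp_reads) < satellites.MIN_CLUSTER_READS:
                continue
            mono = satellites.detect_tandem(
                sp_reads, cluster_id=c.cluster_id, ltr_guard=False
            )
            if mono is None:
                continue
            mono.abundance = 100.0 * len(sp_reads) / species_totals[code]
            monomers[f"{code}:{c.cluster_id}"] = mono
    if monomers:
        sat_records, sat_tiers, _ = satellites.classify_families(monomers)
        sat_records = satellites.name_families(sat_records)
        pa = satellites.presence_absence(sat_records, species_codes)
        jac = satellites.jaccard_matrix(pa) if not pa.empty else pd.DataFrame()
    else:
        sat_records, sat_tiers = [], None
        pa, jac = pd.DataFrame(), pd.DataFrame()
    timings["satellites"] = time.time() - t0

    # --- repeat phylogeny ------------------------------------------------
    t0 = time.time()
    top = phylogeny.top_clusters(reported, config.top_n_phylo)
    oe_matrices = []
    nj_trees: dict[str, Node] = {}
    excluded = []
    for c in top:
        oe = phylogeny.oe_edges(c, species_codes)
        oe_matrices.append(oe)
        dist = phylogeny.to_distance(oe)
        if isinstance(dist, phylogeny.Excluded):
            excluded.append(dist)
            continue
        nj_trees[c.cluster_id] = phylogeny.nj(dist)
    splits = (
        phylogeny.consensus_network(
            list(nj_trees.values()), config.consensus_threshold
        )
        if nj_trees
        else None
    )
    timings["phylogeny"] = time.time() - t0

    # --- LTR structure ---------------------------------------------------
    t0 = time.time()
    annotations: list[ltr.LTRAnnotation] = []
    age_profiles: list[ltr.LineageAgeProfile] = []
    if config.run_ltr:
        lin_index = ltr.build_lineage_index(library.entries)
        for code in species_codes:
            genome = sim.genomes[code]
            for ann in ltr.find_ltr_pairs(genome, seq_id=code):
                internal = genome[ann.ltr5[1] : ann.ltr3[0]]
                ann.domains, ann.canonical_order = ltr.domain_scan(internal)
                element_seq = genome[ann.element[0] : ann.element[1]]
                ann.lineage = ltr.assign_lineage(
                    element_seq, library.entries, _index=lin_index
                )
                annotations.append(ann)
        age_profiles = ltr.age_histogram(annotations)
    timings["ltr"] = time.time() - t0

    # --- consolidated abundance table ------------------------------------
    rows = {}
    for code in species_codes:
        per_cat = {cat: 0.0 for cat in
                   ["SIRE", "Ale", "Ty1_other", "Tekay", "Retand", "Athila",
                    "Ty3_other", "LINE", "Pararetrovirus", "EnSpm_CACTA",
                    "DNA_other", "rDNA", "satDNA", "Unclassified"]}
        n_sp = species_totals[code]
        for c in reported:
            n = c.species_counts.get(code, 0)
            if n:
                per_cat[lineage_category(c.annotation)] += 100.0 * n / n_sp
        per_cat["Total"] = sum(per_cat.values())
        rows[code] = per_cat
    abundance = pd.DataFrame(rows).T

    result = PipelineResult(
        config=config, sim=sim, analyzed=analyzed, clusters=clusters,
        reported=reported, superclusters=superclusters, library=library,
        monomers=monomers, sat_records=sat_records, sat_tiers=sat_tiers,
        presence_absence=pa, jaccard=jac, oe_matrices=oe_matrices,
        nj_trees=nj_trees, splits=splits, excluded=excluded,
        ltr_annotations=annotations, age_profiles=age_profiles,
        abundance=abundance,
    )
    result.manifest = {
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "stages": sorted(timings),
        "wall_clock_s": {k: round(v, 2) for k, v in timings.items()},
        "n_reads_analyzed": total_reads,
        "n_clusters": len(clusters),
        "n_reported_clusters": len(reported),
        "n_satellite_monomers": len(monomers),
        "n_nj_trees": len(nj_trees),
        "n_ltr_elements": len(annotations),
    }
    if config.outdir:
        write_outputs(result, Path(config.outdir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    # cluster table
    rows = []
    for c in result.reported:
        row = {
            "cluster_id": c.cluster_id, "size": c.size,
            "proportion_pct": round(c.genome_proportion, 4),
            "annotation": c.annotation, "edges": c.edge_count,
            "discordant": c.discordant,
        }
        row.update({f"n_{k}": v for k, v in sorted(c.species_counts.items())})
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    # satellites
    if result.monomers:
        write_fasta(
            (
                (
                    f"{mid}#len={m.length}#AT={m.at_content:.1f}"
                    f"#abundance={m.abundance:.2f}#confidence={m.confidence}",
                    m.sequence,
                )
                for mid, m in sorted(result.monomers.items())
            ),
            outdir / "satellite_monomers.fasta",
        )
    if not result.presence_absence.empty:
        result.presence_absence.to_csv(outdir / "satellite_presence.tsv", sep="\t")
        result.jaccard.to_csv(outdir / "satellite_jaccard.tsv", sep="\t")
    # phylogeny
    treedir = outdir / "nj_trees"
    treedir.mkdir(exist_ok=True)
    for cid, tree in result.nj_trees.items():
        phylogeny.write_tree(tree, treedir / f"{cid}.nwk")
    if result.splits is not None:
        phylogeny.write_splits(result.splits, outdir / "consensus_splits.nex")
    with open(outdir / "excluded_clusters.tsv", "w") as fh:
        fh.write("cluster_id\treason\n")
        for ex in result.excluded:
            fh.write(f"{ex.cluster_id}\t{ex.reason}\n")
    # LTR
    if result.ltr_annotations:
        ltr.write_gff3(result.ltr_annotations, outdir / "ltr_elements.gff3")
        ltr.write_histograms(result.age_profiles, outdir / "ltr_age_histograms.tsv")
    # abundance
    result.abundance.to_csv(outdir / "abundance.tsv", sep="\t")
    # manifest with checksums
    checksums = {
        p.name: _sha256(p) for p in sorted(outdir.rglob("*")) if p.is_file()
    }
    result.manifest["checksums"] = checksums
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


# ---------------------------------------------------------------------------
# truth-based evaluation of a synthetic run
# ---------------------------------------------------------------------------


def evaluate_run(result: PipelineResult) -> dict:
    """Compare a synthetic comparative run against its generator truth table.

    Returns recovery metrics: per-family read recovery, per-species total
    repeat error, satellite monomer recovery, species-tree split recovery and
    LTR identity accuracy.
    """
    sim = result.sim
    species_codes = [sp.code for sp in sim.species]

    # truth family per analyzed read
    truth_label: dict[str, Optional[str]] = {}
    for code in species_codes:
        pairs = sim.pairs[code]
        labels = sim.read_family_labels(code)
        interlaced = readprep.interlace(pairs.reads1, pairs.reads2)
        by_id = {r.id: l for r, l in zip(interlaced, labels)}
        for read in result.analyzed[code]:
            truth_label[read.id] = by_id[read.id[len(code):]]

    fam_total: dict[str, int] = {}
    for lab in truth_label.values():
        if lab:
            fam_total[lab] = fam_total.get(lab, 0) + 1
    best_in_one: dict[str, int] = {}
    fam_main_cluster: dict[str, str] = {}
    for c in result.clusters:
        comp: dict[str, int] = {}
        for rid in c.read_ids:
            lab = truth_label.get(rid)
            if lab:
                comp[lab] = comp.get(lab, 0) + 1
        for fam, n in comp.items():
            if n > best_in_one.get(fam, 0):
                best_in_one[fam] = n
                fam_main_cluster[fam] = c.cluster_id
    family_recovery = {
        fam: best_in_one.get(fam, 0) / tot for fam, tot in sorted(fam_total.items())
    }

    total_errors = {
        code: float(
            result.abundance.loc[code, "Total"] - sim.truth.total_repeat_fraction(code)
        )
        for code in species_codes
    }

    # satellite recovery for the two universal planted satellites
    sat_eval = {}
    for fam_id in ("Sat-137", "Sat-365"):
        cid = fam_main_cluster.get(fam_id)
        entry = {"cluster": cid, "species_detected": 0, "lengths": [],
                 "identity_to_truth": [], "one_family": False}
        if cid is not None:
            members = [
                mid for mid in result.monomers if mid.endswith(":" + cid)
            ]
            entry["species_detected"] = len(members)
            for mid in members:
                code = mid.split(":")[0]
                mono = result.monomers[mid]
                entry["lengths"].append(mono.length)
                truth_mono = sim.truth.monomers.get((code, fam_id))
                if truth_mono:
                    entry["identity_to_truth"].append(
                        satellites.circular_identity(mono.sequence, truth_mono)
                    )
            entry["one_family"] = bool(members) and any(
                set(members) <= set(rec.members) for rec in result.sat_records
            )
        sat_eval[fam_id] = entry

    # species-tree splits
    from .trees import internal_splits as _splits

    true_splits = _splits(sim.tree.root)
    retained = set(result.splits.retained()) if result.splits else set()
    split_eval = {
        "n_true": len(true_splits),
        "n_recovered": len(true_splits & retained),
        "all_true_recovered": true_splits <= retained,
        "n_trees": len(result.nj_trees),
    }
    if result.splits and true_splits:
        sister = min(true_splits, key=len)  # shortest-divergence pair by design
        freqs = result.splits.frequencies
        sister_freq = freqs.get(sister, 0.0)
        best_nontrivial = max(freqs.values()) if freqs else 0.0
        split_eval["sister_pair_top"] = sister_freq >= best_nontrivial
        split_eval["sister_pair_freq"] = sister_freq

    # LTR identity accuracy
    ltr_truth = sim.truth.copies
    ltr_truth = ltr_truth[ltr_truth.ltr_length > 0]
    errs = []
    matched = 0
    eligible = 0
    by_species: dict[str, list] = {}
    for ann in result.ltr_annotations:
        by_species.setdefault(ann.seq_id, []).append(ann)
    for code, group in ltr_truth.groupby("species"):
        anns = sorted(by_species.get(code, []), key=lambda a: a.element)
        starts = [a.element[0] for a in anns]
        used = set()
        for _, row in group.iterrows():
            if row.ltr_identity < 80:
                continue
            eligible += 1
            import bisect as _bisect

            i0 = _bisect.bisect_left(starts, row.start - 30000)
            for i in range(i0, len(anns)):
                a = anns[i]
                if a.element[0] > row.end:
                    break
                if i in used:
                    continue
                ov = min(a.element[1], row.end) - max(a.element[0], row.start)
                if ov > 0.5 * (row.end - row.start):
                    used.add(i)
                    matched += 1
                    errs.append(abs(a.ltr_identity - row.ltr_identity))
                    break
    ltr_eval = {
        "eligible": eligible,
        "matched": matched,
        "recovery": matched / eligible if eligible else 0.0,
        "identity_mae": float(np.mean(errs)) if errs else float("nan"),
    }
    bimodal_lineages = [p.lineage for p in result.age_profiles if p.bimodal]
    ltr_eval["bimodal_lineages"] = bimodal_lineages

    return {
        "family_recovery": family_recovery,
        "min_family_recovery": min(family_recovery.values()) if family_recovery else 0.0,
        "total_errors_pp": total_errors,
        "max_abs_total_error_pp": max(abs(v) for v in total_errors.values()),
        "satellites": sat_eval,
        "splits": split_eval,
        "ltr": ltr_eval,
    }
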