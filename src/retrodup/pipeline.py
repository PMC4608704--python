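"""End-to-end orchestration of the RDV analysis stages.

Stages run in dependency order::

    simulate -> annotate -> rdv -> conserve -> discover -> express -> stats

``simulate`` writes a complete synthetic input bundle (genome, gene models,
retrocopy-bearing contigs, deletion VCF + panel, alignment blocks + species
tree, per-individual unmapped reads + filter databases, count matrices and
qPCR tables) with truth files alongside; every later stage reads only files,
so the pipeline runs identically on real inputs with the same formats.

A JSON manifest records parameters, input hashes and outputs; reruns with
the same config and seed are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import expression as expr
from . import io_formats as io
from . import novel_discovery as nd
from . import rdv_detection as rdv
from . import retrocopy_annotation as ann
from . import synthetic_data as syn
from . import validation_stats as vs
from .core import DeletionVariant, GenomicInterval

STAGES = ("simulate", "annotate", "rdv", "conserve", "discover",
          "express", "stats")


@dataclass
class PipelineConfig:
    """Every path and threshold of the pipeline, with the defaults used
    throughout (150 bp span / 50% identity / 50% coverage / 2 introns;
    100 bp RDV overlap; 50% reciprocal overlap; 500 bp contigs; 95%/70%
    clustering; 1 RPM; 50 mean reads; 2-fold and adjusted p 0.05; Ct
    cutoff 32; efficiency bound 1.8)."""

    workdir: str = "pipeline_out"
    seed: int = 0

    # retrocopy calling
    min_span_bp: int = 150
    min_identity_pct: float = 50.0
    min_coverage_pct: float = 50.0
    min_introns_lost: int = 2
    # rdv
    min_overlap_bp: int = 100
    # conservation
    min_reciprocal_overlap: float = 0.5
    # discovery
    min_contig_len: int = 500
    min_assembly_overlap_bp: int = 31
    cluster_min_identity: float = 0.95
    cluster_min_coverage: float = 0.70
    filter_min_identity: float = 0.90
    filter_min_coverage: float = 0.50
    min_anchor_bp: int = 40
    # expression
    rpm_threshold: float = 1.0
    min_mean_reads: float = 50.0
    min_fold_change: float = 2.0
    max_adjusted_p: float = 0.05
    # qPCR
    ct_cutoff: float = 32.0
    min_efficiency: float = 1.8

    # synthetic bundle sizes
    n_genes: int = 10
    n_planted_retrocopies: int = 6
    n_rdv_retrocopies: int = 20
    n_rdv_deletions: int = 25
    n_individuals_per_population: int = 20
    populations: Sequence[str] = ("CEU", "GBR", "FIN", "TSI", "YRI")
    n_ortholog_retrocopies: int = 40
    n_novel: int = 3
    n_discovery_individuals: int = 3
    n_expression_loci: int = 300

    def validate(self) -> None:
        checks = [
            self.min_span_bp >= 1,
            0 <= self.min_identity_pct <= 100,
            0 <= self.min_coverage_pct <= 100,
            self.min_introns_lost >= 0,
            self.min_overlap_bp >= 1,
            0 < self.min_reciprocal_overlap <= 1,
            self.min_contig_len >= 1,
            0 < self.cluster_min_identity <= 1,
            0 < self.cluster_min_coverage <= 1,
            self.rpm_threshold >= 0,
            self.min_fold_change >= 1,
            0 < self.max_adjusted_p <= 1,
            self.ct_cutoff > 0,
            1 < self.min_efficiency <= 2,
        ]
        if not all(checks):
            raise ValueError("pipeline config outside valid ranges")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, d: Path) -> List[Path]:
    rng_seed = cfg.seed
    out: List[Path] = []

    def w(path: Path):
        out.append(path)
        return path

    # genome + genes + planted retrocopy contigs
    genome, models, proteins = syn.simulate_genome_with_genes(
        cfg.n_genes, (3, 6), 60_000 + 6_000 * cfg.n_genes, seed=rng_seed)
    io.write_fasta(genome, w(d / "genome.fa"))
    io.write_gene_models_gtf(models, w(d / "genes.gtf"))
    io.write_fasta(proteins, w(d / "proteome.fa"))
    targets: Dict[str, str] = {}
    truth_rows = []
    for i in range(cfg.n_planted_retrocopies):
        gene = models[i % len(models)]
        cid, contig, truth = syn.retropose(
            gene, divergence=0.08, seed=rng_seed + 100 + i,
            contig_id=f"target{i:02d}")
        targets[cid] = contig
        truth_rows.append({
            "contig": cid, "parent": truth.parent_gene_id,
            "start": truth.insertion_locus.start,
            "end": truth.insertion_locus.end,
            "introns_lost": truth.introns_lost})
    io.write_fasta(targets, w(d / "targets.fa"))
    pd.DataFrame(truth_rows).to_csv(w(d / "truth_retrocopies.tsv"),
                                    sep="\t", index=False)

    # RDV inputs: retrocopy loci + deletions + panel
    rng = np.random.default_rng(rng_seed + 1)
    loci = {}
    for i in range(cfg.n_rdv_retrocopies):
        start = 5_000 + i * 3_000
        loci[f"retro_{i:03d}"] = GenomicInterval(
            "chr1", start, start + int(rng.integers(300, 1500)))
    io.write_bed(loci, w(d / "retro_loci.bed"))
    panel = syn.make_panel(cfg.populations, cfg.n_individuals_per_population)
    io.write_panel(panel, w(d / "panel.tsv"))
    deletions, freqs = [], {}
    names = sorted(loci)
    for i in range(cfg.n_rdv_deletions):
        target = loci[names[i % len(names)]]
        start = target.start + int(rng.integers(-200, len(target) - 150))
        length = int(rng.integers(120, 4000))
        deletions.append(DeletionVariant(
            f"del_{i:03d}", GenomicInterval("chr1", max(0, start),
                                            max(0, start) + length)))
        n_pops = int(rng.integers(1, len(cfg.populations) + 1))
        chosen = rng.choice(len(cfg.populations), size=n_pops, replace=False)
        for j in chosen:
            freqs[(f"del_{i:03d}", cfg.populations[j])] = float(
                rng.uniform(0.02, 0.5))
    gdel, pop_truth = syn.simulate_population_genotypes(
        deletions, panel, freqs, seed=rng_seed + 2)
    io.write_sv_vcf(gdel, panel.individuals, w(d / "deletions.vcf"))
    pd.DataFrame(
        [{"deletion": k[0], "population": k[1], "frequency": v}
         for k, v in sorted(pop_truth.frequencies.items())]
    ).to_csv(w(d / "truth_frequencies.tsv"), sep="\t", index=False)

    # conservation inputs
    blocks, sp_loci, otruths = syn.simulate_ortholog_blocks(
        n_retrocopies=cfg.n_ortholog_retrocopies, seed=rng_seed + 3,
        n_decoy_pairs=4)
    io.write_maf_blocks(blocks, w(d / "alignment.maf"))
    for sp, sl in sorted(sp_loci.items()):
        io.write_bed(sl, w(d / f"retro_{sp}.bed"))
    with open(w(d / "species_tree.nwk"), "w") as fh:
        fh.write(syn.EUTHERIA_NEWICK + "\n")
    pd.DataFrame([{
        "retrocopy": t.retrocopy_id, "planted_origin": t.planted_origin,
        "presence": ",".join(sorted(t.presence)),
        "inferable_origin": t.inferable_origin or "NA",
        "decoy": t.is_decoy_pair} for t in otruths]).to_csv(
        w(d / "truth_orthologs.tsv"), sep="\t", index=False)

    # discovery inputs: novel retrocopy contigs + reads + dbs + genomes
    rng2 = np.random.default_rng(rng_seed + 4)
    novel: Dict[str, str] = {}
    ref_parts, outg_parts = [], []
    site_truth = []
    ref_pos = outg_pos = 0
    for i in range(cfg.n_novel):
        gene = models[(i + 2) % len(models)]
        _, contig, truth = syn.retropose(
            gene, divergence=0.12, seed=rng_seed + 300 + i,
            flank_range=(50, 100), contig_id=f"novel{i}")
        seq = contig[truth.insertion_locus.start:truth.insertion_locus.end]
        if len(seq) < cfg.min_contig_len + 150:
            seq = seq + syn.random_dna(rng2, cfg.min_contig_len + 150
                                       - len(seq))
        novel[f"novel{i}"] = seq
        left = syn.random_dna(rng2, 700)
        right = syn.random_dna(rng2, 700)
        scar = syn.random_dna(rng2, int(rng2.integers(0, 150)))
        outg_parts.append(left + seq + right)
        ref_parts.append(left + scar + right)
        site_truth.append({
            "contig": f"novel{i}",
            "ref_start": ref_pos + len(left),
            "ref_end": ref_pos + len(left) + max(len(scar), 1)})
        ref_pos += len(ref_parts[-1])
        outg_pos += len(outg_parts[-1])
    io.write_fasta({"ref_chr1": "".join(ref_parts)}, w(d / "reference.fa"))
    io.write_fasta({"outg_chr1": "".join(outg_parts)}, w(d / "outgroup.fa"))
    pd.DataFrame(site_truth).to_csv(w(d / "truth_deletion_sites.tsv"),
                                    sep="\t", index=False)
    contaminant = {"virus1": syn.random_dna(rng2, 900)}
    patch = {"patch1": syn.random_dna(rng2, 900)}
    io.write_fasta(contaminant, w(d / "db_contaminant.fa"))
    io.write_fasta(patch, w(d / "db_patch.fa"))
    for ind in range(cfg.n_discovery_individuals):
        pool = dict(novel)
        pool[f"contam_copy"] = contaminant["virus1"]
        reads = syn.simulate_reads(pool, 100, 20.0, 0.0,
                                   seed=rng_seed + 500 + ind)
        io.write_fasta(reads, w(d / f"reads_ind{ind:02d}.fa"))

    # expression inputs
    cm, de_truth = syn.simulate_counts_nb(
        cfg.n_expression_loci, {"GBR": 10, "YRI": 10}, dispersion=0.1,
        de_fraction=0.05, log2fc=2.0, seed=rng_seed + 6,
        baseline_mean=300.0, baseline_sd_log=0.6)
    io.write_count_matrix(cm, w(d / "counts.tsv"), w(d / "groups.tsv"))
    pd.DataFrame([{"locus": k, "log2fc": v[0], "dispersion": v[1]}
                  for k, v in sorted(de_truth.effects.items())]).to_csv(
        w(d / "truth_de.tsv"), sep="\t", index=False)

    # qPCR inputs
    rows = []
    curve_rows = []
    rng3 = np.random.default_rng(rng_seed + 7)
    for i in range(6):
        ct_ref = float(rng3.uniform(18, 22))
        ct_tgt = float(rng3.uniform(24, 36))
        rows.append({"sample": f"tissue{i}", "target": "retro_q",
                     "ct_target": round(ct_tgt, 2),
                     "ct_reference": round(ct_ref, 2)})
        eff = float(rng3.uniform(1.75, 2.0))
        df, _ = syn.simulate_qpcr_curves(1e-6, eff, 40, 0.01,
                                         seed=rng_seed + 700 + i)
        df["well"] = f"well{i}"
        df["true_efficiency"] = eff
        curve_rows.append(df)
    pd.DataFrame(rows).to_csv(w(d / "ct_table.tsv"), sep="\t", index=False)
    pd.concat(curve_rows)[["well", "cycle", "fluorescence",
                           "true_efficiency"]].to_csv(
        w(d / "curves.tsv"), sep="\t", index=False)
    return out


def stage_annotate(cfg: PipelineConfig, d: Path) -> List[Path]:
    genome = io.read_fasta(d / "genome.fa")
    models = io.read_gene_models(d / "genes.gtf", genome,
                                 io.read_fasta(d / "proteome.fa"))
    targets = io.read_fasta(d / "targets.fa")
    thr = ann.Thresholds(
        min_span_bp=cfg.min_span_bp,
        min_identity_pct=cfg.min_identity_pct,
        min_coverage_pct=cfg.min_coverage_pct,
        min_introns_lost=cfg.min_introns_lost)
    calls = ann.call_retrocopies(models, targets, thr)
    by_tx = {m.gene_id: m for m in models}
    rows = []
    bed = {}
    for c in calls:
        parent = by_tx[c.parent_gene_id]
        retro_seq = targets[c.locus.chrom][c.locus.start:c.locus.end]
        if c.locus.strand == "-":
            retro_seq = syn.revcomp(retro_seq)
        c.orf_conserved = ann.conserved_orf(retro_seq, parent.mrna)
        rows.append({
            "retrocopy": c.retrocopy_id, "contig": c.locus.chrom,
            "start": c.locus.start, "end": c.locus.end,
            "parent": c.parent_gene_id,
            "identity_pct": round(c.identity_pct, 2),
            "coverage_pct": round(c.protein_coverage_pct, 2),
            "span_bp": c.genomic_span_bp, "introns_lost": c.introns_lost,
            "orf_conserved": c.orf_conserved})
        bed[c.retrocopy_id] = c.locus
    pd.DataFrame(rows).to_csv(d / "retrocopy_calls.tsv", sep="\t",
                              index=False)
    io.write_bed(bed, d / "retrocopy_calls.bed")
    return [d / "retrocopy_calls.tsv", d / "retrocopy_calls.bed"]


def stage_rdv(cfg: PipelineConfig, d: Path) -> List[Path]:
    loci = io.read_bed(d / "retro_loci.bed")
    panel = io.read_panel(d / "panel.tsv")
    deletions = io.read_sv_vcf(d / "deletions.vcf", panel)
    records = rdv.build_rdv_table(loci, deletions, panel,
                                  cfg.min_overlap_bp)
    io.write_rdv_table(records, d / "rdv_table.tsv", panel.populations)
    rdv.write_spread_summary(records, d / "rdv_spread.json")
    return [d / "rdv_table.tsv", d / "rdv_spread.json"]


def stage_conserve(cfg: PipelineConfig, d: Path) -> List[Path]:
    blocks = io.read_maf_blocks(d / "alignment.maf")
    tree = io.read_species_tree(d / "species_tree.nwk")
    sp_loci = {}
    for bed in sorted(d.glob("retro_*.bed")):
        sp = bed.stem.replace("retro_", "")
        if sp == "loci":
            continue
        sp_loci[sp] = io.read_bed(bed)
    groups = cons.map_orthologs(blocks, sp_loci, cfg.min_reciprocal_overlap)
    cons.annotate_groups(groups, tree)
    cons.write_groups_tsv(groups, d / "ortholog_groups.tsv")
    with open(d / "lineage_counts.json", "w") as fh:
        json.dump(cons.summarize_lineage_counts(groups, tree), fh, indent=2)
    return [d / "ortholog_groups.tsv", d / "lineage_counts.json"]


def stage_discover(cfg: PipelineConfig, d: Path) -> List[Path]:
    contigs: List[nd.Contig] = []
    for reads_fa in sorted(d.glob("reads_ind*.fa")):
        ind = reads_fa.stem.replace("reads_", "")
        reads = io.read_fasta(reads_fa)
        contigs.extend(nd.assemble_contigs(
            reads, ind, cfg.min_assembly_overlap_bp, cfg.min_contig_len))
    clusters = nd.cluster_contigs(contigs, cfg.cluster_min_identity,
                                  cfg.cluster_min_coverage)
    consensi = {}
    cluster_rows = []
    for cl in clusters:
        cl.consensus_sequence = nd.consensus(cl)
        consensi[cl.representative.id] = cl.consensus_sequence
        cluster_rows.append({
            "cluster": cl.representative.id, "n_members": len(cl.members),
            "n_individuals": cl.n_individuals,
            "singleton": cl.is_singleton})
    pd.DataFrame(cluster_rows).to_csv(d / "clusters.tsv", sep="\t",
                                      index=False)
    dbs = [("contaminant", io.read_fasta(d / "db_contaminant.fa")),
           ("patch", io.read_fasta(d / "db_patch.fa"))]
    retained, filtered = nd.filter_sequences(
        consensi, dbs, cfg.filter_min_identity, cfg.filter_min_coverage)
    io.write_fasta(retained, d / "retained_consensi.fa")
    reference = io.read_fasta(d / "reference.fa")
    outgroup = io.read_fasta(d / "outgroup.fa")
    rows = []
    for cid in sorted(retained):
        site = nd.locate_deletion_site(
            nd.Contig(cid, retained[cid], "consensus"), outgroup,
            reference, cfg.min_anchor_bp)
        if isinstance(site, nd.DeletionSiteCall):
            loc = site.reference_interval
            rows.append({"consensus": cid, "length": len(retained[cid]),
                         "deletion_site":
                             f"{loc.chrom}:{loc.start}-{loc.end}"})
        else:
            rows.append({"consensus": cid, "length": len(retained[cid]),
                         "deletion_site": f"none({site.reason})"})
    pd.DataFrame(rows).to_csv(d / "novel_retrocopies.tsv", sep="\t",
                              index=False)
    with open(d / "discovery_summary.json", "w") as fh:
        json.dump({"n_contigs": len(contigs), "n_clusters": len(clusters),
                   "n_retained": len(retained),
                   "filtered_by_label":
                       {lbl: sum(1 for v in filtered.values() if v == lbl)
                        for lbl in {"contaminant", "patch"}}}, fh, indent=2)
    return [d / "clusters.tsv", d / "retained_consensi.fa",
            d / "novel_retrocopies.tsv", d / "discovery_summary.json"]


def stage_express(cfg: PipelineConfig, d: Path) -> List[Path]:
    cm = io.read_count_matrix(d / "counts.tsv", d / "groups.tsv")
    rpm = expr.rpm_normalize(cm)
    flags = expr.flag_expressed(rpm, cm.loci, cfg.rpm_threshold)
    pd.DataFrame([{"locus": k, "expressed": v}
                  for k, v in flags.items()]).to_csv(
        d / "expressed_flags.tsv", sep="\t", index=False)
    results = expr.nb_differential_test(cm, cfg.min_mean_reads)
    expr.call_differential(results, cfg.min_fold_change, cfg.max_adjusted_p)
    pd.DataFrame([{
        "locus": r.locus, "base_mean": round(r.base_mean, 2),
        "log2_fold_change": round(r.log2_fold_change, 4),
        "fold_change": round(r.fold_change, 4),
        "pvalue": r.pvalue, "padj": r.padj,
        "significant": r.significant} for r in results]).to_csv(
        d / "differential_expression.tsv", sep="\t", index=False)
    return [d / "expressed_flags.tsv", d / "differential_expression.tsv"]


def stage_stats(cfg: PipelineConfig, d: Path) -> List[Path]:
    ct = io.read_ct_table(d / "ct_table.tsv")
    rows = []
    for _, r in ct.iterrows():
        q = vs.qpcr_relative_quantity(vs.CtRecord(
            r["sample"], r["target"], r["ct_target"], r["ct_reference"],
            cutoff=cfg.ct_cutoff))
        rows.append({"sample": r["sample"], "target": r["target"],
                     "quantity": "not_expressed" if q is None
                     else round(q, 3)})
    pd.DataFrame(rows).to_csv(d / "qpcr_quantities.tsv", sep="\t",
                              index=False)
    curves = io.read_fluorescence_table(d / "curves.tsv")
    eff_rows = []
    for well, grp in curves.groupby("well"):
        grp = grp.sort_values("cycle")
        est = vs.estimate_efficiency(grp["fluorescence"].to_numpy())
        eff_rows.append({"well": well,
                         "efficiency": round(est.efficiency, 4),
                         "acceptable": est.efficiency > cfg.min_efficiency,
                         "r_squared": round(est.r_squared, 6)})
    pd.DataFrame(eff_rows).to_csv(d / "efficiencies.tsv", sep="\t",
                                  index=False)
    return [d / "qpcr_quantities.tsv", d / "efficiencies.tsv"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "annotate": stage_annotate,
    "rdv": stage_rdv,
    "conserve": stage_conserve,
    "discover": stage_discover,
    "express": stage_express,
    "stats": stage_stats,
}

_STAGE_INPUTS = {
    "annotate": ["genome.fa", "genes.gtf", "proteome.fa", "targets.fa"],
    "rdv": ["retro_loci.bed", "panel.tsv", "deletions.vcf"],
    "conserve": ["alignment.maf", "species_tree.nwk"],
    "discover": ["reference.fa", "outgroup.fa", "db_contaminant.fa",
                 "db_patch.fa"],
    "express": ["counts.tsv", "groups.tsv"],
    "stats": ["ct_table.tsv", "curves.tsv"],
}


def run(cfg: PipelineConfig,
        stage_selection: Optional[Sequence[str]] = None) -> Dict:
    """Run the selected stages in dependency order; returns the manifest."""
    cfg.validate()
    stages = [s for s in STAGES
              if stage_selection is None or s in stage_selection]
    if not stages:
        raise ValueError("no stages selected")
    d = Path(cfg.workdir)
    d.mkdir(parents=True, exist_ok=True)
    # check inputs before running anything
    for s in stages:
        for req in _STAGE_INPUTS.get(s, []):
            if "simulate" not in stages and not (d / req).exists():
                raise FileNotFoundError(
                    f"stage '{s}' requires missing input {d / req}")
    manifest: Dict = {"config": asdict(cfg), "stages": {}}
    for s in stages:
        outputs = _STAGE_FUNCS[s](cfg, d)
        manifest["stages"][s] = {
            "inputs": {req: _sha256(d / req)
                       for req in _STAGE_INPUTS.get(s, [])
                       if (d / req).exists()},
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
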