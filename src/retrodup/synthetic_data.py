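"""Synthetic input generation with known ground truth.

Every input the pipeline consumes can be generated here: a genome with
multi-exon genes, in-silico retroposed copies with controlled divergence and
truncation, diploid deletion genotypes at planted per-population
frequencies, ortholog presence/absence on a fixed eutherian species tree,
negative-binomial count matrices with planted fold changes, error-bearing
short reads over planted contigs, and exponential qPCR fluorescence curves.

All generators are deterministic for a fixed seed and emit machine-readable
truth records so downstream stages can be scored without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import (
    CountMatrix,
    DeletionVariant,
    GeneModel,
    GenomicInterval,
    PopulationPanel,
)
from .io_formats import MAFBlock, MAFRow

BASES = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Fixed 14-species eutherian tree with named internal clades, mirroring the
#: lineages relevant to retrocopy origin dating (Hominidae, Catarrhini,
#: Primates, Euarchontoglires, Eutheria, plus the mouse-rat ancestor).
EUTHERIA_NEWICK = (
    "((((((((human,chimpanzee),gorilla),orangutan)Hominidae,macaque)"
    "Catarrhini,marmoset)Primates,((mouse,rat)Murinae,rabbit)Glires)"
    "Euarchontoglires,((cow,pig),(dog,horse))Laurasiatheria)Boreoeutheria,"
    "elephant)Eutheria;"
)

PRIMATE_OUTGROUPS = ("chimpanzee", "gorilla", "orangutan", "macaque",
                     "marmoset")


# ---------------------------------------------------------------------------
# low-level sequence helpers
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator,
                    indel_rate: float = 0.0) -> str:
    """Point-mutate *seq* at a per-site substitution *rate*; optional short
    (1-2 bp) indels at *indel_rate* per site for frameshift/ORF testing."""
    out: List[str] = []
    for ch in seq:
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:  # deletion
                continue
            out.append(random_dna(rng, int(rng.integers(1, 3))))
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(ch)
    return "".join(out)


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    """Random CDS of *n_aa* codons with no stop codons (and no trailing
    stop; the transcript is modelled as fully coding)."""
    codons = []
    while len(codons) < n_aa:
        c = random_dna(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)


# ---------------------------------------------------------------------------
# genome + gene models
# ---------------------------------------------------------------------------

def simulate_genome_with_genes(
    n_genes: int,
    exons_per_gene_range: Tuple[int, int] = (3, 8),
    genome_length: int = 200_000,
    seed: int = 0,
    protein_length_range: Tuple[int, int] = (150, 350),
    intron_length_range: Tuple[int, int] = (80, 400),
    chrom: str = "chr1",
) -> Tuple[Dict[str, str], List[GeneModel], Dict[str, str]]:
    """Simulate a genome carrying *n_genes* non-overlapping multi-exon genes.

    Returns ``(genome, gene_models, proteins)``.  Exon boundaries fall at
    arbitrary (not codon-aligned) positions so that intron junctions can sit
    mid-codon, as they do in real genes.  Raises when the genes cannot be
    placed without overlap.
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    genome = list(random_dna(rng, genome_length))
    models: List[GeneModel] = []
    proteins: Dict[str, str] = {}
    cursor = 100
    for g in range(n_genes):
        n_exons = int(rng.integers(exons_per_gene_range[0],
                                   exons_per_gene_range[1] + 1))
        n_aa = int(rng.integers(*protein_length_range))
        cds = _random_cds(rng, n_aa)
        # split CDS into n_exons pieces, each >= 30 bp
        if len(cds) < 30 * n_exons:
            n_exons = max(1, len(cds) // 30)
        cuts = sorted(rng.choice(
            np.arange(30, len(cds) - 29), size=n_exons - 1,
            replace=False)) if n_exons > 1 else []
        # enforce >= 30 bp between cuts
        ok_cuts: List[int] = []
        for c in cuts:
            if not ok_cuts or c - ok_cuts[-1] >= 30:
                ok_cuts.append(int(c))
        bounds = [0] + ok_cuts + [len(cds)]
        exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
        intron_seqs = ["GT" + random_dna(
            rng, int(rng.integers(*intron_length_range))) + "AG"
            for _ in range(len(exon_seqs) - 1)]
        layout = []  # plus-strand layout: exon/intron alternation
        offsets = []
        pos = 0
        for i, ex in enumerate(exon_seqs):
            offsets.append((pos, pos + len(ex)))
            layout.append(ex)
            pos += len(ex)
            if i < len(intron_seqs):
                layout.append(intron_seqs[i])
                pos += len(intron_seqs[i])
        gene_seq = "".join(layout)
        glen = len(gene_seq)
        gap = int(rng.integers(200, 600))
        start = cursor + gap
        if start + glen > genome_length - 100:
            raise ValueError(
                f"genome_length={genome_length} too small to place "
                f"{n_genes} genes without overlap (failed at gene {g})")
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            genome[start:start + glen] = gene_seq
            exons = [GenomicInterval(chrom, start + a, start + b, "+")
                     for a, b in offsets]
        else:
            genome[start:start + glen] = revcomp(gene_seq)
            exons = [GenomicInterval(chrom, start + glen - b,
                                     start + glen - a, "-")
                     for a, b in offsets]
        cursor = start + glen
        gene_id = f"gene{g:04d}"
        tx_id = f"tx{g:04d}"
        protein = str(Seq(cds).translate())
        proteins[tx_id] = protein
        models.append(GeneModel(
            gene_id=gene_id, transcript_id=tx_id, chrom=chrom,
            strand=strand, exons=exons, protein=protein, mrna=cds))
    return {chrom: "".join(genome)}, models, proteins


# ---------------------------------------------------------------------------
# retroposition
# ---------------------------------------------------------------------------

@dataclass
class RetropositionTruth:
    """Ground truth for one in-silico retroposition event."""

    parent_gene_id: str
    parent_transcript_id: str
    insertion_locus: GenomicInterval  # within the emitted host contig
    divergence: float
    introns_lost: int
    truncation_fraction: float
    orf_intact: bool
    short_warning: bool = False  # post-truncation length < 150 bp

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence outside [0, 0.5]")


def retropose(
    gene: GeneModel,
    divergence: float = 0.05,
    n_introns_lost: Optional[int] = None,
    truncate_frac: float = 0.0,
    seed: int = 0,
    flank_range: Tuple[int, int] = (300, 800),
    indel_rate: float = 0.0,
    contig_id: Optional[str] = None,
) -> Tuple[str, str, RetropositionTruth]:
    """Create a retrocopy of *gene* and embed it in a random host contig.

    The retroposed sequence is the gene's mRNA with a contiguous run of
    *n_introns_lost* junctions spliced out; the remaining introns are
    retained as genomic sequence (modelling incomplete processing).  The
    copy is point-mutated at *divergence* per site, truncated by
    *truncate_frac* from the 5' end, and inserted between random flanks.

    Returns ``(contig_id, contig_sequence, truth)``.
    """
    rng = np.random.default_rng(seed)
    if n_introns_lost is None:
        n_introns_lost = gene.n_introns
    if n_introns_lost > gene.n_introns:
        raise ValueError("n_introns_lost exceeds parent intron count")
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence outside [0, 0.5]")

    exons_m = gene.exons_mrna_order
    # mRNA-oriented exon sequences
    exon_seqs = []
    pos = 0
    for e in exons_m:
        exon_seqs.append(gene.mrna[pos:pos + len(e)])
        pos += len(e)
    # retained introns: fresh random sequence of plausible length is enough
    # to disrupt the junction for alignment purposes
    n_j = gene.n_introns
    if n_j > 0 and n_introns_lost < n_j:
        run_start = int(rng.integers(0, n_j - n_introns_lost + 1)) \
            if n_introns_lost > 0 else -1
    else:
        run_start = 0
    lost = set(range(run_start, run_start + n_introns_lost)) \
        if n_introns_lost > 0 else set()
    parts = [exon_seqs[0]]
    for j in range(n_j):
        if j not in lost:
            parts.append("GT" + random_dna(rng, int(rng.integers(80, 300)))
                         + "AG")
        parts.append(exon_seqs[j + 1])
    retro = "".join(parts)
    retro = mutate_sequence(retro, divergence, rng, indel_rate=indel_rate)
    cut = int(round(truncate_frac * len(retro)))
    retro = retro[cut:]
    short = len(retro) < 150

    left = random_dna(rng, int(rng.integers(*flank_range)))
    right = random_dna(rng, int(rng.integers(*flank_range)))
    contig = left + retro + right
    cid = contig_id or f"retro_of_{gene.gene_id}"
    locus = GenomicInterval(cid, len(left), len(left) + max(len(retro), 1))

    orf_intact = False
    if (n_introns_lost == n_j and truncate_frac == 0.0 and indel_rate == 0.0
            and not short):
        from Bio.Seq import Seq
        aa = str(Seq(retro[: 3 * (len(retro) // 3)]).translate())
        orf_intact = "*" not in aa
    truth = RetropositionTruth(
        parent_gene_id=gene.gene_id,
        parent_transcript_id=gene.transcript_id,
        insertion_locus=locus, divergence=divergence,
        introns_lost=n_introns_lost, truncation_fraction=truncate_frac,
        orf_intact=orf_intact, short_warning=short)
    return cid, contig, truth


# ---------------------------------------------------------------------------
# population genotypes
# ---------------------------------------------------------------------------

@dataclass
class PopulationTruth:
    """Planted per-population deletion allele frequencies."""

    frequencies: Dict[Tuple[str, str], float]  # (deletion id, pop) -> f


def make_panel(populations: Sequence[str], n_per_population: int
               ) -> PopulationPanel:
    assignments = {}
    for pop in populations:
        for i in range(n_per_population):
            assignments[f"{pop}_{i:03d}"] = pop
    return PopulationPanel(assignments)


def simulate_population_genotypes(
    deletions: Sequence[DeletionVariant],
    panel: PopulationPanel,
    frequencies: Dict[Tuple[str, str], float],
    seed: int = 0,
    missing_rate: float = 0.0,
) -> Tuple[List[DeletionVariant], PopulationTruth]:
    """Draw diploid genotypes: each allele is an independent
    Bernoulli(f_pop) draw (Hardy-Weinberg).  *frequencies* maps
    ``(deletion id, population)`` to the planted deletion-allele frequency.
    """
    rng = np.random.default_rng(seed)
    pops = set(panel.populations)
    for (_, pop) in frequencies:
        if pop not in pops:
            raise ValueError(f"unknown population in frequencies: {pop}")
    out = []
    for d in deletions:
        genotypes = {}
        for ind in panel.individuals:
            pop = panel.assignments[ind]
            f = frequencies.get((d.id, pop), 0.0)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency outside [0,1]: {f}")
            a = int(rng.random() < f)
            b = int(rng.random() < f)
            gt = (a, b)
            if missing_rate > 0 and rng.random() < missing_rate:
                gt = (None, None)
            genotypes[ind] = gt
        out.append(DeletionVariant(d.id, d.locus, genotypes))
    return out, PopulationTruth(dict(frequencies))


# ---------------------------------------------------------------------------
# ortholog blocks on the species tree
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    name: str
    children: List["_Node"] = field(default_factory=list)

    def leaves(self) -> List[str]:
        if not self.children:
            return [self.name]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _parse_newick(newick: str) -> _Node:
    """Minimal newick parser (names + topology only) used for truth
    bookkeeping, independent of the dendropy-based analysis path."""
    s = newick.strip().rstrip(";")
    pos = 0

    def parse() -> _Node:
        nonlocal pos
        node = _Node(name="")
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse())
                if s[pos] == ",":
                    pos += 1
                elif s[pos] == ")":
                    pos += 1
                    break
        name = ""
        while pos < len(s) and s[pos] not in ",()":
            name += s[pos]
            pos += 1
        node.name = name.split(":")[0]
        return node

    return parse()


def _mrca_name(root: _Node, species: frozenset) -> Optional[str]:
    """Name of the smallest *named* clade containing all of *species* (own
    traversal; serves as the truth oracle for origin assignment).  Unnamed
    internal nodes are transparent: a presence set whose strict MRCA is
    unnamed maps to the nearest named ancestor lineage."""
    if not species:
        return None
    best: Optional[_Node] = None

    def visit(node: _Node):
        nonlocal best
        leaves = frozenset(node.leaves())
        if species <= leaves:
            if node.name and (best is None
                              or len(leaves) < len(frozenset(best.leaves()))):
                best = node
            for c in node.children:
                visit(c)

    visit(root)
    return best.name if best is not None else None


@dataclass
class OrthologTruth:
    retrocopy_id: str
    planted_origin: str
    presence: frozenset  # surviving species
    inferable_origin: Optional[str]  # MRCA of presence (None if < 2 species)
    is_decoy_pair: bool = False


def simulate_ortholog_blocks(
    newick: str = EUTHERIA_NEWICK,
    loss_probability: float = 0.2,
    n_retrocopies: int = 100,
    seed: int = 0,
    locus_length: int = 600,
    jitter: int = 50,
    n_decoy_pairs: int = 0,
    decoy_shift_frac: float = 0.7,
) -> Tuple[List[MAFBlock], Dict[str, Dict[str, GenomicInterval]],
           List[OrthologTruth]]:
    """Plant retrocopies on a species tree and emit alignment blocks.

    Each retrocopy gets a true origin node; each branch below the origin
    loses the copy independently with *loss_probability* (a loss removes
    the whole subtree — no homoplasy).  Surviving species receive a locus
    and a shared ungapped block whose per-species offsets are jittered by at
    most *jitter* bp, keeping reciprocal overlap above
    ``1 - 2*jitter/locus_length``.  Decoy pairs are shifted by
    *decoy_shift_frac* of the locus so their reciprocal overlap falls below
    50% and they must *not* be grouped.

    Returns ``(blocks, loci_by_species, truths)``.
    """
    rng = np.random.default_rng(seed)
    root = _parse_newick(newick)
    nodes: List[_Node] = []

    def collect(n: _Node):
        nodes.append(n)
        for c in n.children:
            collect(c)

    collect(root)
    named_nodes = [n for n in nodes if n.name]

    blocks: List[MAFBlock] = []
    loci: Dict[str, Dict[str, GenomicInterval]] = {}
    truths: List[OrthologTruth] = []
    src_size = 10_000_000

    def add_block(rid: str, row_species: List[str], offsets: List[int],
                  base_positions: Dict[str, int]):
        text = "X" * (locus_length + 2 * jitter + locus_length)
        rows = {}
        for sp, off in zip(row_species, offsets):
            start = base_positions[sp] - off
            rows[sp] = MAFRow(
                species=sp,
                interval=GenomicInterval(f"chr_{sp}", start,
                                         start + len(text)),
                maf_strand="+", src_size=src_size, text=text)
        blocks.append(MAFBlock(rows))

    slot = 0
    for r in range(n_retrocopies):
        rid = f"retro{r:04d}"
        origin = named_nodes[rng.integers(0, len(named_nodes))]

        surviving: List[str] = []

        def descend(node: _Node):
            for child in node.children:
                if rng.random() >= loss_probability:
                    descend(child)
            if not node.children:
                surviving.append(node.name)

        descend(origin)
        base_positions = {}
        for sp in surviving:
            pos = 1000 + slot * (4 * locus_length)
            base_positions[sp] = pos
            loci.setdefault(sp, {})[rid] = GenomicInterval(
                f"chr_{sp}", pos, pos + locus_length)
        slot += 1
        if len(surviving) >= 2:
            offsets = [int(rng.integers(0, jitter + 1)) for _ in surviving]
            add_block(rid, surviving, offsets, base_positions)
        presence = frozenset(surviving)
        truths.append(OrthologTruth(
            retrocopy_id=rid, planted_origin=origin.name, presence=presence,
            inferable_origin=_mrca_name(root, presence)
            if len(presence) >= 2 else None))

    leaf_names = root.leaves()
    for dpair in range(n_decoy_pairs):
        rid_a = f"decoy{dpair:04d}a"
        rid_b = f"decoy{dpair:04d}b"
        sp_a, sp_b = [leaf_names[i] for i in
                      rng.choice(len(leaf_names), size=2, replace=False)]
        base_positions = {}
        for sp, rid in ((sp_a, rid_a), (sp_b, rid_b)):
            pos = 1000 + slot * (4 * locus_length)
            base_positions[sp] = pos
            loci.setdefault(sp, {})[rid] = GenomicInterval(
                f"chr_{sp}", pos, pos + locus_length)
        slot += 1
        shift = int(decoy_shift_frac * locus_length)
        add_block(rid_a, [sp_a, sp_b], [0, shift], base_positions)
        for rid, sp in ((rid_a, sp_a), (rid_b, sp_b)):
            truths.append(OrthologTruth(
                retrocopy_id=rid, planted_origin=sp,
                presence=frozenset([sp]), inferable_origin=None,
                is_decoy_pair=True))
    return blocks, loci, truths


# ---------------------------------------------------------------------------
# negative-binomial count matrices
# ---------------------------------------------------------------------------

@dataclass
class DETruth:
    """Planted log2 fold changes and dispersions per locus (loci absent
    from the map were simulated as null)."""

    effects: Dict[str, Tuple[float, float]]  # locus -> (log2fc, dispersion)


def simulate_counts_nb(
    n_loci: int,
    groups: Dict[str, int],
    size_factors: Optional[Dict[str, float]] = None,
    dispersion: float = 0.1,
    de_fraction: float = 0.0,
    log2fc: float = 2.0,
    seed: int = 0,
    baseline_mean: float = 500.0,
    baseline_sd_log: float = 0.0,
) -> Tuple[CountMatrix, DETruth]:
    """Draw a count matrix: counts ~ NB(mean = baseline x size_factor x
    2^(log2fc x group_indicator), dispersion).  With *dispersion* below
    1e-12 a Poisson draw is used.  The second group (sorted order) carries
    the planted effect; signs alternate so both directions occur.
    """
    rng = np.random.default_rng(seed)
    group_names = sorted(groups)
    if len(group_names) != 2 and de_fraction > 0:
        raise ValueError("planted effects require exactly two groups")
    samples, labels = [], {}
    for gname in group_names:
        if groups[gname] < 2:
            raise ValueError("each group needs >= 2 samples")
        for i in range(groups[gname]):
            s = f"{gname}_{i:02d}"
            samples.append(s)
            labels[s] = gname
    if size_factors is None:
        size_factors = {s: 1.0 for s in samples}
    sf = np.array([size_factors[s] for s in samples])
    indicator = np.array([1.0 if labels[s] == group_names[-1] else 0.0
                          for s in samples])

    loci = [f"locus{i:05d}" for i in range(n_loci)]
    n_de = int(round(de_fraction * n_loci))
    de_idx = rng.choice(n_loci, size=n_de, replace=False) if n_de else []
    effects: Dict[str, Tuple[float, float]] = {}
    lfc = np.zeros(n_loci)
    for k, i in enumerate(sorted(de_idx)):
        s = 1.0 if k % 2 == 0 else -1.0
        lfc[i] = s * log2fc
        effects[loci[i]] = (s * log2fc, dispersion)

    if baseline_sd_log > 0:
        base = baseline_mean * np.exp(
            rng.normal(0.0, baseline_sd_log, size=n_loci))
    else:
        base = np.full(n_loci, baseline_mean)
    mu = base[:, None] * sf[None, :] * np.power(
        2.0, lfc[:, None] * indicator[None, :])
    if dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / dispersion
        p = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p)
    cm = CountMatrix(loci=loci, samples=samples, groups=labels,
                     counts=counts.astype(np.int64))
    return cm, DETruth(effects)


# ---------------------------------------------------------------------------
# short reads
# ---------------------------------------------------------------------------

def simulate_reads(
    sequences: Dict[str, str],
    read_length: int = 100,
    coverage: float = 20.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> Dict[str, str]:
    """Uniformly placed single-end reads at the target coverage, drawn from
    both strands, with per-base substitution errors at *error_rate*."""
    rng = np.random.default_rng(seed)
    reads: Dict[str, str] = {}
    for name, seq in sequences.items():
        if read_length > len(seq):
            raise ValueError(f"read_length > sequence length for {name}")
        n_reads = int(np.ceil(coverage * len(seq) / read_length))
        for i in range(n_reads):
            start = int(rng.integers(0, len(seq) - read_length + 1))
            r = seq[start:start + read_length]
            if rng.random() < 0.5:
                r = revcomp(r)
            if error_rate > 0:
                r = mutate_sequence(r, error_rate, rng)
            reads[f"{name}_read{i:05d}"] = r
    return reads


# ---------------------------------------------------------------------------
# qPCR fluorescence curves
# ---------------------------------------------------------------------------

def simulate_qpcr_curves(
    true_initial_quantity: float,
    efficiency: float,
    n_cycles: int = 40,
    noise: float = 0.0,
    seed: int = 0,
    baseline: float = 0.05,
    plateau: float = 10.0,
    threshold: float = 1.0,
) -> Tuple[pd.DataFrame, float]:
    """Fluorescence = baseline + logistic-clipped q0 * efficiency^cycle,
    with multiplicative log-normal noise on the amplification signal.

    The true Ct is the (fractional) cycle at which the unclipped signal
    crosses *threshold*.  Efficiency is the per-cycle amplification factor
    on the 1-2 scale.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    if n_cycles < 30:
        raise ValueError("n_cycles must be >= 30")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1)
    raw = true_initial_quantity * np.power(efficiency, cycles.astype(float))
    clipped = plateau * raw / (plateau + raw)
    signal = clipped
    if noise > 0:
        signal = clipped * np.exp(rng.normal(0.0, noise, size=n_cycles))
    fluor = baseline + signal
    true_ct = float(np.log(threshold / true_initial_quantity)
                    / np.log(efficiency))
    df = pd.DataFrame({"cycle": cycles, "fluorescence": fluor})
    return df, true_ct


# ---------------------------------------------------------------------------
# contig families for assembly/clustering tests
# ---------------------------------------------------------------------------

def simulate_contig_families(
    n_families: int,
    members_per_family: int = 3,
    length_range: Tuple[int, int] = (600, 1000),
    within_divergence: float = 0.01,
    seed: int = 0,
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Families of near-identical contigs (within-family divergence small,
    families mutually unrelated random sequence).

    Returns ``(contigs, family_of)`` mapping contig id -> sequence and
    contig id -> family id.
    """
    rng = np.random.default_rng(seed)
    contigs: Dict[str, str] = {}
    family_of: Dict[str, str] = {}
    for f in range(n_families):
        fam = f"fam{f:03d}"
        base = random_dna(rng, int(rng.integers(*length_range)))
        for m in range(members_per_family):
            cid = f"{fam}_m{m}"
            contigs[cid] = (base if m == 0 else
                            mutate_sequence(base, within_divergence, rng))
            family_of[cid] = fam
    return contigs, family_of
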