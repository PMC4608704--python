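"""Readers and writers for every external format the pipeline touches.

Coordinate conventions are normalised here and nowhere else:

* VCF is 1-based with a padding anchor base on deletions; the *deleted*
  interval is emitted 0-based half-open (``END`` honoured when present).
* MAF rows are strand-relative; minus-strand rows are converted to
  forward-strand 0-based half-open intervals.
* GTF is 1-based inclusive; exons come out 0-based half-open.

Count matrices are accepted as pre-filtered input (uniquely + concordantly
mapped read pairs, MAPQ >= 50); the reader enforces a ``#prefiltered`` flag
line rather than re-deriving the filter, because read alignment is outside
this package's scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import dendropy
import gffutils
import pysam
from Bio.Seq import Seq

from .core import (
    CountMatrix,
    DeletionVariant,
    GeneModel,
    GenomicInterval,
    PopulationPanel,
    RDVRecord,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` map.

    Sequences are uppercased; duplicate ids and empty records are errors.
    """
    out: Dict[str, str] = {}
    name = None
    chunks: List[str] = []

    def _flush():
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"empty FASTA record: {name}")
        if name in out:
            raise ValueError(f"duplicate FASTA id: {name}")
        out[name] = seq

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError("sequence before first FASTA header")
                chunks.append(line)
    _flush()
    return out


def write_fasta(records: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Population panel
# ---------------------------------------------------------------------------

def read_panel(path) -> PopulationPanel:
    """TSV with columns ``individual`` and ``population``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["individual"].duplicated().any():
        dup = df["individual"][df["individual"].duplicated()].iloc[0]
        raise ValueError(f"individual listed twice in panel: {dup}")
    return PopulationPanel(dict(zip(df["individual"], df["population"])))


def write_panel(panel: PopulationPanel, path) -> None:
    pd.DataFrame(
        {"individual": panel.individuals,
         "population": [panel.assignments[i] for i in panel.individuals]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Structural-variant VCF
# ---------------------------------------------------------------------------

def read_sv_vcf(path, panel: PopulationPanel) -> List[DeletionVariant]:
    """Read deletions from a VCF 4.x file.

    A record is taken as a deletion when ``SVTYPE=DEL`` or ``len(REF) >
    len(ALT)``.  Multi-allelic records are split per ALT.  The deleted
    interval excludes the padding anchor: ``[POS - 1 + len(ALT),
    POS - 1 + len(REF))`` in 0-based terms, with an ``END`` tag taking
    precedence for the right edge.  Phased and unphased separators are
    treated identically; malformed genotypes become missing with a warning.
    """
    panel_ids = set(panel.individuals)
    out: List[DeletionVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for sample in vcf.header.samples:
            if sample not in panel_ids:
                raise ValueError(f"VCF individual not in panel: {sample}")
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            pos0 = rec.pos - 1
            svtype = rec.info.get("SVTYPE", None)
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                symbolic = alt.startswith("<")
                is_del = (svtype == "DEL") or (
                    not symbolic and len(rec.ref) > len(alt)
                )
                if not is_del:
                    continue
                anchor = 1 if symbolic else len(alt)
                start = pos0 + anchor
                # pysam folds INFO/END into rec.stop (0-based exclusive);
                # without END rec.stop is pos0 + len(REF).
                end = rec.stop
                if end <= start:
                    continue
                locus = GenomicInterval(rec.chrom, start, end)
                var_id = rec.id or f"{rec.chrom}_{rec.pos}"
                if len(rec.alts) > 1:
                    var_id = f"{var_id}_alt{alt_idx}"
                genotypes = {}
                for sample, call in rec.samples.items():
                    gt = call.get("GT", (None, None))
                    alleles = []
                    ok = True
                    for a in (gt if gt is not None else (None, None)):
                        if a is None:
                            alleles.append(None)
                        elif a == alt_idx:
                            alleles.append(1)
                        elif isinstance(a, int) and a >= 0:
                            alleles.append(0)
                        else:
                            ok = False
                    if not ok or len(alleles) != 2:
                        logger.warning(
                            "malformed GT for %s at %s; set to missing",
                            sample, var_id,
                        )
                        alleles = [None, None]
                    genotypes[sample] = (alleles[0], alleles[1])
                out.append(DeletionVariant(var_id, locus, genotypes))
    return out


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_sv_vcf(deletions: Sequence[DeletionVariant],
                 individuals: Sequence[str], path) -> None:
    """Write deletions as anchor-style VCF rows (REF spans the deletion plus
    one anchor base, ALT is the anchor).  Bases are placeholder N runs; only
    coordinates and genotypes matter downstream."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom in sorted({d.locus.chrom for d in deletions}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(individuals) + "\n")
        for d in sorted(deletions, key=lambda d: (d.locus.chrom,
                                                  d.locus.start, d.id)):
            pos = d.locus.start  # 1-based anchor base = start (0-based start-1+1)
            ref = "N" * (len(d.locus) + 1)
            info = f"SVTYPE=DEL;END={d.locus.end}"
            gts = []
            for ind in individuals:
                a, b = d.genotypes.get(ind, (None, None))
                gts.append("{}/{}".format(
                    "." if a is None else a, "." if b is None else b))
            fh.write(f"{d.locus.chrom}\t{pos}\t{d.id}\t{ref}\tN\t.\t.\t"
                     f"{info}\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------

def read_gene_models(path_gtf, genome: Dict[str, str],
                     proteins: Optional[Dict[str, str]] = None
                     ) -> List[GeneModel]:
    """Read transcripts (exon + CDS features) from a GTF file.

    The transcript is assumed fully coding (CDS == exons).  The protein is
    taken from *proteins* when supplied, otherwise translated from the CDS;
    a CDS whose length is not divisible by 3 is an error.
    """
    db = gffutils.create_db(
        str(path_gtf), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    by_tx: Dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx = feat.attributes["transcript_id"][0]
        gene = feat.attributes["gene_id"][0]
        entry = by_tx.setdefault(
            tx, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand,
                 "exons": []})
        if feat.featuretype == "exon":
            entry["exons"].append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                                feat.strand))
    models = []
    for tx, entry in sorted(by_tx.items()):
        exons = sorted(entry["exons"], key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in transcript {tx}")
        chrom_seq = genome[entry["chrom"]]
        mrna = "".join(chrom_seq[e.start:e.end] for e in exons)
        if entry["strand"] == "-":
            mrna = str(Seq(mrna).reverse_complement())
        if len(mrna) % 3 != 0:
            raise ValueError(f"CDS length not divisible by 3: {tx}")
        if proteins and tx in proteins:
            protein = proteins[tx]
        else:
            protein = str(Seq(mrna).translate())
            if protein.endswith("*"):
                protein = protein[:-1]
        models.append(GeneModel(
            gene_id=entry["gene"], transcript_id=tx, chrom=entry["chrom"],
            strand=entry["strand"], exons=exons, protein=protein, mrna=mrna))
    return models


def write_gene_models_gtf(models: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for ftype in ("exon", "CDS"):
                for e in m.exons:
                    fh.write("\t".join([
                        m.chrom, "retrodup", ftype, str(e.start + 1),
                        str(e.end), ".", m.strand, "0", attrs]) + "\n")


# ---------------------------------------------------------------------------
# MAF alignment blocks
# ---------------------------------------------------------------------------

@dataclass
class MAFRow:
    species: str
    interval: GenomicInterval  # forward-strand 0-based half-open
    maf_strand: str
    src_size: int
    text: str  # gapped, strand-relative

    def columns_for(self, interval: GenomicInterval) -> Optional[Tuple[int, int]]:
        """Project the overlap of *interval* (forward coords) with this row
        into block-column space; None when there is no overlap."""
        ov_start = max(interval.start, self.interval.start)
        ov_end = min(interval.end, self.interval.end)
        if (interval.chrom != self.interval.chrom) or ov_end <= ov_start:
            return None
        if self.maf_strand == "+":
            rel_start = ov_start - self.interval.start
            rel_end = ov_end - self.interval.start
        else:
            rel_start = self.interval.end - ov_end
            rel_end = self.interval.end - ov_start
        # walk gapped text, mapping strand-relative positions to columns
        col_start = col_end = None
        pos = 0
        for col, ch in enumerate(self.text):
            if ch == "-":
                continue
            if pos == rel_start and col_start is None:
                col_start = col
            if pos == rel_end - 1:
                col_end = col + 1
                break
            pos += 1
        if col_start is None or col_end is None:
            return None
        return (col_start, col_end)


@dataclass
class MAFBlock:
    rows: Dict[str, MAFRow]  # species -> row

    @property
    def species(self) -> List[str]:
        return list(self.rows)


def _parse_src(src: str) -> Tuple[str, str]:
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, src


def read_maf_blocks(path) -> List[MAFBlock]:
    """Parse MAF alignment blocks; minus-strand rows are converted to
    forward-strand 0-based half-open intervals."""
    blocks: List[MAFBlock] = []
    with open(path) as fh:
        rows: Dict[str, MAFRow] = {}
        for line in fh:
            if line.startswith("a"):
                if rows:
                    blocks.append(MAFBlock(rows))
                rows = {}
            elif line.startswith("s"):
                parts = line.split()
                _, src, start, size, strand, src_size, text = parts[:7]
                start, size, src_size = int(start), int(size), int(src_size)
                ungapped = text.replace("-", "")
                if len(ungapped) != size:
                    raise ValueError(
                        f"MAF row size {size} != ungapped length "
                        f"{len(ungapped)} for {src}")
                species, chrom = _parse_src(src)
                if strand == "-":
                    fstart = src_size - start - size
                else:
                    fstart = start
                rows[species] = MAFRow(
                    species=species,
                    interval=GenomicInterval(chrom, fstart, fstart + size),
                    maf_strand=strand, src_size=src_size, text=text)
        if rows:
            blocks.append(MAFBlock(rows))
    for b in blocks:
        if len(b.rows) < 2:
            raise ValueError("MAF block with fewer than 2 species")
    return blocks


def write_maf_blocks(blocks: Iterable[MAFBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("a score=0\n")
            for sp, row in block.rows.items():
                size = len(row.text.replace("-", ""))
                if row.maf_strand == "+":
                    start = row.interval.start
                else:
                    start = row.src_size - row.interval.end
                fh.write(
                    f"s {sp}.{row.interval.chrom} {start} {size} "
                    f"{row.maf_strand} {row.src_size} {row.text}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED6 retrocopy loci
# ---------------------------------------------------------------------------

def read_bed(path) -> Dict[str, GenomicInterval]:
    out: Dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
            strand = f[5] if len(f) > 5 else "."
            out[name] = GenomicInterval(chrom, start, end, strand)
    return out


def write_bed(loci: Dict[str, GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(loci):
            ivl = loci[name]
            fh.write(f"{ivl.chrom}\t{ivl.start}\t{ivl.end}\t{name}\t0\t"
                     f"{ivl.strand if ivl.strand != '.' else '+'}\n")


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

PREFILTER_FLAG = "#prefiltered: unique,concordant,mapq>=50"


def read_count_matrix(counts_path, groups_path) -> CountMatrix:
    """Read a locus x sample TSV of read counts plus a sample->group TSV.

    The first line of the counts file must declare the upstream read filter
    (``#prefiltered: ...``); counts from unfiltered alignments are not
    accepted.
    """
    with open(counts_path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#prefiltered"):
            raise ValueError(
                "counts file lacks the #prefiltered flag line; this reader "
                "only accepts MAPQ>=50 unique/concordant pre-filtered counts")
        df = pd.read_csv(fh, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t", dtype=str)
    groups = dict(zip(groups_df["sample"], groups_df["group"]))
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    return CountMatrix(
        loci=list(df.index), samples=list(df.columns), groups=groups,
        counts=df.to_numpy(dtype=np.int64))


def write_count_matrix(cm: CountMatrix, counts_path, groups_path) -> None:
    with open(counts_path, "w") as fh:
        fh.write(PREFILTER_FLAG + "\n")
        pd.DataFrame(cm.counts, index=cm.loci, columns=cm.samples).to_csv(
            fh, sep="\t")
    pd.DataFrame({"sample": cm.samples,
                  "group": [cm.groups[s] for s in cm.samples]}).to_csv(
        groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RDV frequency tables
# ---------------------------------------------------------------------------

def write_rdv_table(records: Sequence[RDVRecord], path,
                    populations: Optional[Sequence[str]] = None) -> None:
    """Write per-population deletion-allele frequencies as percentages with
    two decimals, one row per (retrocopy, deletion) pair."""
    if populations is None:
        pops = sorted({p for r in records for p in r.frequencies})
    else:
        pops = list(populations)
    cols = ["retrocopy", "deletion", "indel_length"] + pops + [
        "n_populations_affected", "spread_category"]
    rows = []
    for r in sorted(records, key=lambda r: (r.retrocopy_id, r.deletion_id)):
        row = [r.retrocopy_id, r.deletion_id, r.indel_length_bp]
        for p in pops:
            f = r.frequencies.get(p)
            row.append("NA" if f is None or (isinstance(f, float) and
                                             math.isnan(f))
                       else f"{100.0 * f:.2f}")
        row += [r.n_populations_affected, r.spread_category]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_rdv_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# ---------------------------------------------------------------------------
# qPCR tables and species trees
# ---------------------------------------------------------------------------

def read_ct_table(path) -> pd.DataFrame:
    """TSV with columns sample, target, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "target", "ct_target", "ct_reference"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return df


def read_fluorescence_table(path) -> pd.DataFrame:
    """TSV with columns well, cycle, fluorescence (long format)."""
    df = pd.read_csv(path, sep="\t")
    required = {"well", "cycle", "fluorescence"}
    if not required.issubset(df.columns):
        raise ValueError(f"curve table must have columns {sorted(required)}")
    return df


def read_species_tree(path) -> dendropy.Tree:
    """Rooted newick tree with named internal clades."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True)
    tree.is_rooted = True
    return tree
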