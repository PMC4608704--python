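"""Core domain types shared across the RDV analysis pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` on the
forward strand.  VCF (1-based) and MAF (strand-relative) coordinates are
converted at the I/O boundary and never leak into the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A locus: chromosome, 0-based half-open span, strand.

    The unit of all overlap arithmetic in the package.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Length of the intersection with *other*; 0 when on different
        chromosomes.  Strand is ignored."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # chr3:66287175-66287285 style
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class PopulationPanel:
    """Maps each individual to exactly one population code."""

    assignments: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("empty panel")

    @property
    def populations(self) -> List[str]:
        return sorted(set(self.assignments.values()))

    @property
    def individuals(self) -> List[str]:
        return list(self.assignments.keys())

    def members(self, population: str) -> List[str]:
        return [i for i, p in self.assignments.items() if p == population]


MISSING = None  # missing allele call

Genotype = Tuple[Optional[int], Optional[int]]


@dataclass
class DeletionVariant:
    """A deletion structural variant with diploid presence/absence genotypes.

    Alleles: 0 = no deletion, 1 = deletion carried, None = missing call.
    """

    id: str
    locus: GenomicInterval
    genotypes: Dict[str, Genotype] = field(default_factory=dict)

    @property
    def length_bp(self) -> int:
        return len(self.locus)


@dataclass
class GeneModel:
    """A parental gene: ordered exons, CDS and protein.

    ``exons`` are sorted by genomic coordinate; for minus-strand genes the
    mRNA order is the reverse of genomic order.  The model assumes a fully
    coding transcript (CDS spans the exons; protein length x 3 = CDS length).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: List[GenomicInterval]
    protein: str
    mrna: str

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a} / {b}"
                )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def exons_mrna_order(self) -> List[GenomicInterval]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def junction_positions_aa(self) -> List[float]:
        """Exon-junction positions along the protein, in residues.

        Junction k sits after the first k exons' worth of mRNA; mid-codon
        junctions give fractional positions.
        """
        out: List[float] = []
        acc = 0
        for exon in self.exons_mrna_order[:-1]:
            acc += len(exon)
            out.append(acc / 3.0)
        return out

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class RetrocopyCall:
    """A classified retrocopy: where it is, which gene it came from, and how
    it scored against the acceptance criteria."""

    retrocopy_id: str
    locus: GenomicInterval
    parent_gene_id: str
    identity_pct: float
    protein_coverage_pct: float
    genomic_span_bp: int
    introns_lost: int
    orf_conserved: Optional[bool] = None
    score: float = 0.0


@dataclass
class RDVRecord:
    """One retrocopy x deletion event with per-population frequencies."""

    retrocopy_id: str
    deletion_id: str
    overlap_bp: int
    indel_length_bp: int
    frequencies: Dict[str, Optional[float]]
    n_populations_affected: int
    spread_category: str


@dataclass
class CountMatrix:
    """Per-locus, per-sample read counts with sample group labels.

    Counts are expected to be pre-filtered upstream (uniquely and
    concordantly mapped pairs, MAPQ >= 50); ``prefiltered`` records that the
    producer asserted this contract.
    """

    loci: List[str]
    samples: List[str]
    groups: Dict[str, str]
    counts: "np.ndarray"  # shape (n_loci, n_samples)
    prefiltered: bool = True

    def __post_init__(self) -> None:
        import numpy as np

        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.loci), len(self.samples)):
            raise ValueError("count matrix not rectangular with labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")


@dataclass
class OrthologGroup:
    """Cross-species ortholog set for one retrocopy family."""

    group_id: str
    loci: Dict[str, GenomicInterval]  # species -> locus
    members: Dict[str, str] = field(default_factory=dict)  # species -> retrocopy id
    origin_clade: Optional[str] = None
    ancestral: bool = False
    deep_conservation: bool = False

    @property
    def presence(self) -> frozenset:
        return frozenset(self.loci)
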