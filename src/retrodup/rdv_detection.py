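"""Retroduplication-variation (RDV) detection.

An RDV here is a retrocopy locus hit by a long deletion: only deletions
removing at least 100 bp of the retrocopy sequence are kept.  For each
surviving (retrocopy, deletion) pair the deletion-allele frequency is
computed per population, and the pair is binned by how many populations
carry the deletion at any nonzero frequency (population-specific / 2-5 /
6-8 / 9-13 / all).
"""

from __future__ import annotations

import json
from collections import Counter
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .core import (
    DeletionVariant,
    GenomicInterval,
    PopulationPanel,
    RDVRecord,
)

SPREAD_BINS = ("population_specific", "2-5", "6-8", "9-13", "all")


def overlap_deletions(
    retrocopies: Dict[str, GenomicInterval],
    deletions: Sequence[DeletionVariant],
    min_overlap_bp: int = 100,
) -> List[Tuple[str, DeletionVariant, int]]:
    """All (retrocopy, deletion) pairs whose interval intersection is at
    least *min_overlap_bp* (strand ignored)."""
    trees: Dict[str, IntervalTree] = {}
    for name, ivl in retrocopies.items():
        trees.setdefault(ivl.chrom, IntervalTree()).addi(
            ivl.start, ivl.end, name)
    out: List[Tuple[str, DeletionVariant, int]] = []
    for d in deletions:
        tree = trees.get(d.locus.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(d.locus.start, d.locus.end):
            ov = min(hit.end, d.locus.end) - max(hit.begin, d.locus.start)
            if ov >= min_overlap_bp:
                out.append((hit.data, d, ov))
    out.sort(key=lambda t: (t[0], t[1].id))
    return out


def allele_frequency(deletion: DeletionVariant,
                     panel: PopulationPanel) -> Dict[str, Optional[float]]:
    """Per-population deletion-allele frequency.

    Missing alleles are excluded from numerator and denominator; a
    population with no non-missing calls is reported as None (undefined).
    """
    num: Counter = Counter()
    den: Counter = Counter()
    for ind, (a, b) in deletion.genotypes.items():
        pop = panel.assignments.get(ind)
        if pop is None:
            raise ValueError(f"individual not in panel: {ind}")
        for allele in (a, b):
            if allele is None:
                continue
            den[pop] += 1
            num[pop] += allele
    return {pop: (num[pop] / den[pop] if den[pop] else None)
            for pop in panel.populations}


def categorize_spread(frequencies: Dict[str, Optional[float]],
                      n_populations_total: Optional[int] = None
                      ) -> Tuple[int, str]:
    """Number of populations with nonzero deletion frequency, and the
    spread bin used for reporting (1 / 2-5 / 6-8 / 9-13 / all)."""
    if n_populations_total is None:
        n_populations_total = len(frequencies)
    n = sum(1 for f in frequencies.values() if f is not None and f > 0)
    if n >= n_populations_total and n_populations_total > 0:
        return n, "all"
    if n <= 1:
        return n, "population_specific"
    if n <= 5:
        return n, "2-5"
    if n <= 8:
        return n, "6-8"
    return n, "9-13"


def build_rdv_table(
    retrocopies: Dict[str, GenomicInterval],
    deletions: Sequence[DeletionVariant],
    panel: PopulationPanel,
    min_overlap_bp: int = 100,
) -> List[RDVRecord]:
    """One RDVRecord per (retrocopy, deletion) pair surviving the 100 bp
    overlap rule, in deterministic (retrocopy, deletion) order."""
    records: List[RDVRecord] = []
    n_pops = len(panel.populations)
    for rc_id, deletion, ov in overlap_deletions(
            retrocopies, deletions, min_overlap_bp):
        freqs = allele_frequency(deletion, panel)
        n_aff, cat = categorize_spread(freqs, n_pops)
        records.append(RDVRecord(
            retrocopy_id=rc_id, deletion_id=deletion.id, overlap_bp=ov,
            indel_length_bp=deletion.length_bp, frequencies=freqs,
            n_populations_affected=n_aff, spread_category=cat))
    return records


def spread_summary(records: Sequence[RDVRecord]) -> Dict[str, int]:
    """Counts of RDV records per spread category (all bins reported)."""
    counts = Counter(r.spread_category for r in records)
    return {bin_: counts.get(bin_, 0) for bin_ in SPREAD_BINS}


def write_spread_summary(records: Sequence[RDVRecord], path) -> None:
    summary = {
        "n_records": len(records),
        "n_retrocopies_affected": len({r.retrocopy_id for r in records}),
        "spread_categories": spread_summary(records),
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
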