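"""Retrocopy identification from translated protein-to-DNA alignment.

A retrocopy is recognised by aligning the parental protein to genomic (or
contig) sequence over all 3 frames x 2 strands and requiring: a genomic
footprint of at least 150 bp, alignment identity and protein coverage both
strictly greater than 50%, and the loss of at least 2 introns inferred from
the alignment.  An intron counts as lost when the alignment covers both
sides of the corresponding exon junction and the genomic distance between
the flanking codons is (almost) what a spliced mRNA would give.

The translated aligner is a local Smith-Waterman under BLOSUM62 with affine
gaps (open 11, extend 1) and no frameshift states; frameshifted copies are
handled separately by :func:`conserved_orf`, which tests the nucleotide
alignment to the parent CDS for frame-preserving gaps and internal stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .core import GeneModel, GenomicInterval, RetrocopyCall

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class Thresholds:
    """Acceptance criteria for a retrocopy call (defaults 150/50/50/2)."""

    min_span_bp: int = 150
    min_identity_pct: float = 50.0
    min_coverage_pct: float = 50.0
    min_introns_lost: int = 2
    max_junction_gap_bp: int = 30
    min_flank_aa: int = 10


@dataclass
class TranslatedAlignment:
    """Best local alignment of a parent protein to a DNA target.

    ``pairs`` maps aligned parent residues to amino-acid positions within
    the chosen reading frame of the target; genomic coordinates are always
    reported on the forward strand of the target.
    """

    target_id: str
    protein_len: int
    strand: str          # '+' or '-'
    frame: int           # 0..2, offset into the strand-oriented sequence
    target_len: int
    pairs: List[Tuple[int, int]]  # (protein residue, frame aa position)
    matches: int
    score: float
    pair_matches: Optional[List[bool]] = None  # parallel to pairs
    target_seq: Optional[str] = None  # forward-strand target DNA

    @property
    def aligned_columns(self) -> int:
        """Gap-excluded aligned columns (= aligned residue pairs)."""
        return len(self.pairs)

    @property
    def identity_pct(self) -> float:
        if not self.pairs:
            return 0.0
        return 100.0 * self.matches / self.aligned_columns

    @property
    def coverage_pct(self) -> float:
        return 100.0 * len({i for i, _ in self.pairs}) / self.protein_len

    @property
    def protein_span(self) -> Tuple[int, int]:
        qs = [i for i, _ in self.pairs]
        return (min(qs), max(qs) + 1)

    def codon_start_strandlocal(self, frame_aa_pos: int) -> int:
        return self.frame + 3 * frame_aa_pos

    def genomic_span(self) -> GenomicInterval:
        ts = [j for _, j in self.pairs]
        lo = self.codon_start_strandlocal(min(ts))
        hi = self.codon_start_strandlocal(max(ts)) + 3
        if self.strand == "+":
            return GenomicInterval(self.target_id, lo, hi, "+")
        return GenomicInterval(self.target_id, self.target_len - hi,
                               self.target_len - lo, "-")

    @property
    def genomic_span_bp(self) -> int:
        return len(self.genomic_span())


_aligner: Optional[Align.PairwiseAligner] = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = _BLOSUM62
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _frame_translations(dna: str) -> List[Tuple[str, int, str]]:
    """All six (strand, frame, translated protein) triples of *dna*."""
    out = []
    for strand in ("+", "-"):
        s = dna if strand == "+" else _revcomp(dna)
        for frame in range(3):
            n = (len(s) - frame) // 3
            if n < 1:
                continue
            aa = str(Seq(s[frame:frame + 3 * n]).translate())
            out.append((strand, frame, aa))
    return out


def _sanitize(protein: str) -> str:
    return "".join(c if c in _BLOSUM62.alphabet else "X"
                   for c in protein.upper())


def translated_align(protein: str, dna: str,
                     target_id: str = "target"
                     ) -> Optional[TranslatedAlignment]:
    """Best-scoring local alignment of *protein* against the six frame
    translations of *dna* (BLOSUM62, affine gaps open 11 / extend 1).

    Returns ``None`` when no alignment scores above zero.  Identity is
    matches over gap-excluded aligned columns; coverage is aligned parent
    residues over protein length.
    """
    if len(protein) < 20:
        raise ValueError("protein shorter than 20 aa")
    if len(dna) < 60:
        raise ValueError("dna shorter than 60 bp")
    protein = _sanitize(protein)
    dna = dna.upper()
    aligner = _protein_aligner()
    best: Optional[TranslatedAlignment] = None
    for strand, frame, aa in _frame_translations(dna):
        try:
            alns = aligner.align(protein, aa)
            if len(alns) == 0:
                continue
            aln = alns[0]
        except (ValueError, OverflowError):
            continue
        if aln.score <= 0:
            continue
        if best is not None and aln.score < best.score:
            continue
        pairs: List[Tuple[int, int]] = []
        pair_matches: List[bool] = []
        matches = 0
        qblocks, tblocks = aln.aligned
        for (qs, qe), (ts, te) in zip(qblocks, tblocks):
            for q, t in zip(range(qs, qe), range(ts, te)):
                pairs.append((q, t))
                hit = protein[q] == aa[t]
                pair_matches.append(hit)
                if hit:
                    matches += 1
        cand = TranslatedAlignment(
            target_id=target_id, protein_len=len(protein), strand=strand,
            frame=frame, target_len=len(dna), pairs=pairs,
            matches=matches, score=float(aln.score),
            pair_matches=pair_matches, target_seq=dna)
        if (best is None or cand.score > best.score
                or (cand.score == best.score
                    and cand.identity_pct > best.identity_pct)):
            best = cand
    return best


def infer_lost_introns(alignment: TranslatedAlignment,
                       gene_model: GeneModel,
                       max_junction_gap_bp: int = 30,
                       min_flank_aa: int = 10,
                       max_flank_divergence: float = 0.40) -> int:
    """Count parental introns whose junctions are collapsed in the
    alignment's target sequence.

    A junction passes an alignment screen — it lies inside the aligned
    protein span, with at least *min_flank_aa* aligned residues on each
    side of it or, for terminal exons shorter than the flank, every exon
    residue that exists — and is then confirmed at the nucleotide level: the parent mRNA windows immediately left and right
    of the junction are each located in the target (best infix alignment
    on the alignment's strand, at most *max_flank_divergence* edits per
    base), and the junction counts as lost iff the two windows sit
    adjacently — the gap or overlap between them is at most
    *max_junction_gap_bp*.  A retained intron separates the windows by
    the intron length; a frame-disrupting retained intron additionally
    leaves one side of the protein alignment spurious, but the
    nucleotide adjacency test is immune to reading-frame artefacts.
    Single-exon parents return 0.
    """
    import edlib

    if gene_model.n_introns == 0 or not alignment.pairs:
        return 0
    if alignment.target_seq is None:
        raise ValueError("alignment lacks target sequence")
    eps = 1e-9
    covered = sorted({q for q, _ in alignment.pairs})
    target = (alignment.target_seq if alignment.strand == "+"
              else _revcomp(alignment.target_seq))
    mrna = gene_model.mrna
    window_nt = max(60, 6 * min_flank_aa)
    min_window_nt = 24
    junctions_nt = [int(round(3 * x))
                    for x in gene_model.junction_positions_aa()]
    lost = 0
    junctions_aa = gene_model.junction_positions_aa()
    for jidx, x in enumerate(junctions_aa):
        n_left = sum(1 for i in covered if i + 1 <= x + eps)
        n_right = sum(1 for i in covered if i >= x - eps)
        # residues available on each side before hitting the protein end
        avail_left = x
        avail_right = len(gene_model.protein) - x
        need_left = min(min_flank_aa, max(int(avail_left) - 1, 1))
        need_right = min(min_flank_aa, max(int(avail_right) - 1, 1))
        if n_left < need_left or n_right < need_right:
            continue
        if not (covered[0] + 1 <= x + eps and covered[-1] >= x - eps):
            continue
        jpos = junctions_nt[jidx]
        # windows never cross a neighbouring junction: within one exon the
        # parent mRNA is contiguous in the target by construction
        lo = max(0, jpos - window_nt,
                 junctions_nt[jidx - 1] if jidx > 0 else 0)
        hi = min(len(mrna), jpos + window_nt,
                 junctions_nt[jidx + 1] if jidx + 1 < len(junctions_nt)
                 else len(mrna))
        win_a = mrna[lo:jpos]
        win_b = mrna[jpos:hi]
        if len(win_a) < min_window_nt or len(win_b) < min_window_nt:
            continue
        res_a = edlib.align(win_a, target, mode="HW",
                            k=int(max_flank_divergence * len(win_a)),
                            task="locations")
        res_b = edlib.align(win_b, target, mode="HW",
                            k=int(max_flank_divergence * len(win_b)),
                            task="locations")
        if res_a["editDistance"] < 0 or res_b["editDistance"] < 0:
            continue
        # edlib reports every tied best location; the junction is collapsed
        # iff any left/right placement pair is adjacent
        if any(abs(loc_b[0] - (loc_a[1] + 1)) <= max_junction_gap_bp
               for loc_a in res_a["locations"]
               for loc_b in res_b["locations"]):
            lost += 1
    return min(lost, gene_model.n_introns)


_nt_aligner: Optional[Align.PairwiseAligner] = None


def _nucleotide_aligner() -> Align.PairwiseAligner:
    global _nt_aligner
    if _nt_aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 2.0
        a.mismatch_score = -3.0
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        try:
            a.open_end_gap_score = 0.0
            a.extend_end_gap_score = 0.0
        except AttributeError:  # older biopython naming
            a.end_open_gap_score = 0.0
            a.end_extend_gap_score = 0.0
        _nt_aligner = a
    return _nt_aligner


def conserved_orf(retrocopy_dna: str, parent_cds_dna: str) -> bool:
    """True iff the retrocopy-to-parent-CDS alignment has no frameshifting
    gap (every internal gap run divisible by 3) and translating the
    retrocopy in the parent-anchored frame yields no internal stop codon
    over the aligned region."""
    if not retrocopy_dna or not parent_cds_dna:
        raise ValueError("empty sequence")
    retro = retrocopy_dna.upper()
    cds = parent_cds_dna.upper()
    aln = _nucleotide_aligner().align(cds, retro)[0]
    a_cds, a_retro = str(aln[0]), str(aln[1])
    # restrict to the aligned core: trim terminal gap overhangs
    start = 0
    while a_cds[start] == "-" or a_retro[start] == "-":
        start += 1
    end = len(a_cds)
    while a_cds[end - 1] == "-" or a_retro[end - 1] == "-":
        end -= 1
    core_cds = a_cds[start:end]
    core_retro = a_retro[start:end]
    # every internal gap run (either row) must keep frame
    for row in (core_cds, core_retro):
        run = 0
        for ch in row + "X":
            if ch == "-":
                run += 1
            else:
                if run and run % 3 != 0:
                    return False
                run = 0
    # translate the retrocopy in the parent-anchored frame
    parent_pos_at_start = a_cds[:start].replace("-", "").__len__()
    phase = parent_pos_at_start % 3
    retro_core_seq = core_retro.replace("-", "")
    offset = (3 - phase) % 3
    in_frame = retro_core_seq[offset:]
    in_frame = in_frame[: 3 * (len(in_frame) // 3)]
    if not in_frame:
        return True
    aa = str(Seq(in_frame).translate())
    return "*" not in aa


def classify_retrocopy(alignment: Optional[TranslatedAlignment],
                       gene_model: GeneModel,
                       thresholds: Thresholds = Thresholds(),
                       retrocopy_id: Optional[str] = None,
                       ) -> Tuple[Optional[RetrocopyCall], Optional[str]]:
    """Apply the acceptance rule (span >= 150 bp, identity > 50%,
    coverage > 50%, >= 2 introns lost).

    Returns ``(call, None)`` on acceptance, ``(None, reason)`` with the
    first failed criterion otherwise.
    """
    if alignment is None or not alignment.pairs:
        return None, "no_alignment"
    if alignment.genomic_span_bp < thresholds.min_span_bp:
        return None, "min_span"
    if not alignment.identity_pct > thresholds.min_identity_pct:
        return None, "min_identity"
    if not alignment.coverage_pct > thresholds.min_coverage_pct:
        return None, "min_coverage"
    introns_lost = infer_lost_introns(
        alignment, gene_model,
        max_junction_gap_bp=thresholds.max_junction_gap_bp,
        min_flank_aa=thresholds.min_flank_aa)
    if introns_lost < thresholds.min_introns_lost:
        return None, "min_introns_lost"
    locus = alignment.genomic_span()
    call = RetrocopyCall(
        retrocopy_id=retrocopy_id or f"rc_{alignment.target_id}",
        locus=locus, parent_gene_id=gene_model.gene_id,
        identity_pct=alignment.identity_pct,
        protein_coverage_pct=alignment.coverage_pct,
        genomic_span_bp=alignment.genomic_span_bp,
        introns_lost=introns_lost, score=alignment.score)
    return call, None


def _word_set(protein: str, k: int) -> set:
    return {protein[i:i + k] for i in range(len(protein) - k + 1)}


def call_retrocopies(gene_models: Sequence[GeneModel],
                     target_sequences: Dict[str, str],
                     thresholds: Thresholds = Thresholds(),
                     seed_word_aa: int = 5,
                     ) -> List[RetrocopyCall]:
    """Run the caller over every (parent, target) pair.

    A shared exact *seed_word_aa*-mer between the parent protein and any
    frame translation of the target gates the full alignment (set
    ``seed_word_aa=0`` to disable).  Overlapping calls on one locus are
    reduced to the highest-scoring parent (ties: identity, then gene id);
    output is ordered by target then coordinate.
    """
    calls: Dict[str, List[RetrocopyCall]] = {}
    for tid in sorted(target_sequences):
        dna = target_sequences[tid].upper()
        if len(dna) < 60:
            continue
        frame_words: Optional[set] = None
        if seed_word_aa:
            frame_words = set()
            for _, _, aa in _frame_translations(dna):
                frame_words |= _word_set(aa, seed_word_aa)
        accepted: List[RetrocopyCall] = []
        for gm in sorted(gene_models, key=lambda g: g.gene_id):
            if len(gm.protein) < 20:
                continue
            if frame_words is not None and not (
                    _word_set(_sanitize(gm.protein), seed_word_aa)
                    & frame_words):
                continue
            aln = translated_align(gm.protein, dna, target_id=tid)
            call, _ = classify_retrocopy(aln, gm, thresholds)
            if call is not None:
                accepted.append(call)
        # overlap resolution: best score wins, ties by identity then gene id
        accepted.sort(key=lambda c: (-c.score, -c.identity_pct,
                                     c.parent_gene_id))
        kept: List[RetrocopyCall] = []
        for c in accepted:
            if all(c.locus.overlap_bp(k.locus) == 0 for k in kept):
                kept.append(c)
        kept.sort(key=lambda c: (c.locus.chrom, c.locus.start))
        for n, c in enumerate(kept):
            c.retrocopy_id = f"rc_{tid}_{n:03d}"
        calls[tid] = kept
    out: List[RetrocopyCall] = []
    for tid in sorted(calls):
        out.extend(calls[tid])
    return out
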