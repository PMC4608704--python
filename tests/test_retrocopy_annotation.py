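"""Translated alignment, intron-loss inference, ORF conservation and the
retrocopy acceptance rule."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from retrodup import retrocopy_annotation as ann
from retrodup import synthetic_data as syn
from _oracles import sw_protein_dp

BLOSUM62 = substitution_matrices.load("BLOSUM62")

# unambiguous reverse translation (one codon per amino acid)
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


class TestTranslatedAlign:
    def test_self_alignment_perfect(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        protein = models[0].protein
        aln = ann.translated_align(protein, back_translate(protein))
        assert aln.identity_pct == pytest.approx(100.0)
        assert aln.coverage_pct == pytest.approx(100.0)
        assert aln.strand == "+"

    def test_minus_strand_symmetry(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        protein = models[0].protein
        dna = back_translate(protein)
        fwd = ann.translated_align(protein, dna)
        rev = ann.translated_align(protein, syn.revcomp(dna))
        assert rev.strand == "-"
        assert rev.identity_pct == pytest.approx(fwd.identity_pct)
        assert rev.coverage_pct == pytest.approx(fwd.coverage_pct)
        assert rev.score == fwd.score
        # the forward-strand genomic span is mirrored
        assert len(rev.genomic_span()) == len(fwd.genomic_span())

    def test_no_alignment_returns_none(self):
        # proline against poly-Lys/poly-Phe frames: no positive-scoring pair
        protein = "P" * 30
        dna = "A" * 200
        assert ann.translated_align(protein, dna) is None

    @pytest.mark.parametrize("protein,dna", [
        ("MKL", "ATG" * 40),       # protein too short
        ("M" * 25, "ATGATG"),      # dna too short
    ])
    def test_preconditions(self, protein, dna):
        with pytest.raises(ValueError):
            ann.translated_align(protein, dna)

    def test_identity_matches_dp_oracle(self, tiny_gene_bundle):
        """Identity within 5 points of a plain-Python affine SW oracle on
        divergent retrocopies (10% nucleotide divergence)."""
        _, models, _ = tiny_gene_bundle
        n_checked = 0
        for i, gene in enumerate(models * 2):
            if n_checked >= 20:
                break
            _, contig, truth = syn.retropose(
                gene, divergence=0.10, seed=100 + i, flank_range=(30, 60))
            aln = ann.translated_align(gene.protein, contig)
            if aln is None:
                continue
            best = None
            for strand in ("+", "-"):
                s = contig if strand == "+" else syn.revcomp(contig)
                for frame in range(3):
                    n = (len(s) - frame) // 3
                    aa = str(Seq(s[frame:frame + 3 * n]).translate())
                    score, ident, cols = sw_protein_dp(
                        gene.protein, aa, BLOSUM62)
                    if best is None or score > best[0]:
                        best = (score, ident)
            assert best[0] == aln.score
            assert abs(best[1] - aln.identity_pct) <= 5.0
            n_checked += 1
        assert n_checked >= 15


class TestInferLostIntrons:
    def test_single_exon_parent_zero(self):
        _, models, _ = syn.simulate_genome_with_genes(2, (1, 1), 40_000,
                                                      seed=3)
        gene = models[0]
        aln = ann.translated_align(gene.protein,
                                   back_translate(gene.protein))
        assert ann.infer_lost_introns(aln, gene) == 0

    def test_full_intronless_copy_counts_all_junctions(self):
        _, models, _ = syn.simulate_genome_with_genes(4, (5, 5), 90_000,
                                                      seed=5)
        gene = models[0]
        assert gene.n_introns == 4
        aln = ann.translated_align(gene.protein, gene.mrna)
        assert ann.infer_lost_introns(aln, gene) == 4

    def test_count_matches_generator_truth(self, small_gene_bundle):
        """Exact on fully spliced / fully retained copies; never counts a
        retained junction as lost on partially processed copies."""
        _, models, _ = small_gene_bundle
        n_clean = 0
        for i in range(40):
            gene = models[i % len(models)]
            div = 0.05 + 0.01 * (i % 10)
            for k in (0, gene.n_introns):
                _, contig, truth = syn.retropose(
                    gene, divergence=div, n_introns_lost=k, seed=1000 + i)
                aln = ann.translated_align(gene.protein, contig)
                got = ann.infer_lost_introns(aln, gene)
                assert got == truth.introns_lost
                n_clean += 1
            k_mid = i % (gene.n_introns + 1)
            _, contig, truth = syn.retropose(
                gene, divergence=div, n_introns_lost=k_mid, seed=2000 + i)
            aln = ann.translated_align(gene.protein, contig)
            assert ann.infer_lost_introns(aln, gene) <= truth.introns_lost
        assert n_clean == 80

    def test_never_exceeds_parent_intron_count(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        gene = models[3]
        aln = ann.translated_align(gene.protein, gene.mrna)
        assert ann.infer_lost_introns(aln, gene) <= gene.n_introns


class TestConservedOrf:
    def test_identical_true(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        m = models[0].mrna
        assert ann.conserved_orf(m, m) is True

    def test_single_bp_deletion_frameshift(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        m = models[0].mrna
        assert ann.conserved_orf(m[:60] + m[61:], m) is False

    def test_inframe_codon_deletion_true(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        m = models[0].mrna
        assert ann.conserved_orf(m[:60] + m[63:], m) is True

    def test_planned_edits_against_codon_logic(self, small_gene_bundle):
        """100 copies with programmed edits: frame-preserving edits without
        introduced stops stay conserved; frameshifts and nonsense
        substitutions do not."""
        _, models, _ = small_gene_bundle
        rng = np.random.default_rng(17)
        n_pos = n_neg = 0
        for i in range(100):
            gene = models[i % len(models)]
            m = gene.mrna
            kind = i % 4
            codon_i = int(rng.integers(5, len(m) // 3 - 5))
            if kind == 0:  # in-frame codon deletion
                mutant = m[:3 * codon_i] + m[3 * codon_i + 3:]
                expect = True
            elif kind == 1:  # in-frame codon insertion (no stop)
                mutant = m[:3 * codon_i] + "GCT" + m[3 * codon_i:]
                expect = True
            elif kind == 2:  # 1 bp deletion: frameshift
                mutant = m[:3 * codon_i] + m[3 * codon_i + 1:]
                expect = False
            else:  # nonsense substitution: stop codon mid-sequence
                mutant = m[:3 * codon_i] + "TAA" + m[3 * codon_i + 3:]
                expect = False
            got = ann.conserved_orf(mutant, m)
            if kind == 2:
                # a terminal-codon frameshift can align as an end gap; the
                # programmed edits sit mid-sequence so this cannot happen
                assert got is False
            else:
                assert got is expect
            n_pos += expect
            n_neg += not expect
        assert n_pos == 50 and n_neg == 50


def _fake_alignment(span_bp=300, identity=80.0, coverage=80.0,
                    protein_len=100):
    """Construct a TranslatedAlignment with prescribed statistics."""
    n_aligned = int(round(coverage / 100 * protein_len))
    n_matches = int(round(identity / 100 * n_aligned))
    t_max = span_bp // 3 - 1
    pairs = [(i, round(i * t_max / max(n_aligned - 1, 1)))
             for i in range(n_aligned)]
    tlen = max(span_bp, 3 * (t_max + 1))
    return ann.TranslatedAlignment(
        target_id="t", protein_len=protein_len, strand="+", frame=0,
        target_len=tlen, pairs=pairs, matches=n_matches, score=100.0,
        target_seq="A" * tlen)


class TestClassifyRetrocopy:
    def setup_method(self):
        _, models, _ = syn.simulate_genome_with_genes(1, (3, 3), 40_000,
                                                      seed=21)
        self.gene = models[0]

    def test_min_span_boundary(self):
        aln = _fake_alignment(span_bp=149)
        call, reason = ann.classify_retrocopy(aln, self.gene)
        assert call is None and reason == "min_span"

    def test_identity_strictly_greater_than_50(self):
        aln = _fake_alignment(span_bp=300, identity=50.0)
        call, reason = ann.classify_retrocopy(aln, self.gene)
        assert call is None and reason == "min_identity"

    def test_coverage_strictly_greater_than_50(self):
        aln = _fake_alignment(span_bp=300, identity=80.0, coverage=50.0)
        call, reason = ann.classify_retrocopy(aln, self.gene)
        assert call is None and reason == "min_coverage"

    def test_monotone_in_thresholds(self, rng, small_gene_bundle):
        """Raising any threshold never converts a rejection into an
        acceptance, on real alignments and on synthetic statistics."""
        _, models, _ = small_gene_bundle
        alignments = []
        for i in range(8):
            gene = models[i]
            _, contig, _ = syn.retropose(
                gene, divergence=0.05 + 0.03 * i,
                n_introns_lost=i % (gene.n_introns + 1), seed=60 + i)
            aln = ann.translated_align(gene.protein, contig)
            if aln is not None:
                alignments.append((aln, gene))
        for _ in range(100):
            aln = _fake_alignment(
                span_bp=int(rng.integers(60, 600)),
                identity=float(rng.uniform(30, 100)),
                coverage=float(rng.uniform(30, 100)))
            alignments.append((aln, self.gene))
        base = ann.Thresholds()
        for aln, gene in alignments:
            accepted_base = ann.classify_retrocopy(
                aln, gene, base)[0] is not None
            stricter = ann.Thresholds(
                min_span_bp=base.min_span_bp + int(rng.integers(0, 200)),
                min_identity_pct=base.min_identity_pct
                + float(rng.uniform(0, 30)),
                min_coverage_pct=base.min_coverage_pct
                + float(rng.uniform(0, 30)),
                min_introns_lost=base.min_introns_lost
                + int(rng.integers(0, 3)))
            accepted_strict = ann.classify_retrocopy(
                aln, gene, stricter)[0] is not None
            assert not (accepted_strict and not accepted_base)


class TestCallRetrocopies:
    def test_empty_targets(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        assert ann.call_retrocopies(models, {}) == []

    def test_single_planted_copy_localised(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        gene = models[0]
        _, contig, truth = syn.retropose(gene, divergence=0.08, seed=31,
                                         flank_range=(500, 800))
        calls = ann.call_retrocopies(models, {"c": contig})
        assert len(calls) == 1
        call = calls[0]
        assert call.parent_gene_id == gene.gene_id
        assert abs(call.locus.start - truth.insertion_locus.start) <= 15
        assert abs(call.locus.end - truth.insertion_locus.end) <= 15

    def test_two_parents_two_calls(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        g1, g2 = models[0], models[1]
        _, c1, _ = syn.retropose(g1, divergence=0.05, seed=32)
        _, c2, _ = syn.retropose(g2, divergence=0.05, seed=33)
        calls = ann.call_retrocopies(
            [g1, g2], {"joint": c1 + c2})
        assert len(calls) == 2
        assert {c.parent_gene_id for c in calls} == {g1.gene_id,
                                                     g2.gene_id}
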