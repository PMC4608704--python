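"""Generator determinism, construction guarantees and sampling bounds."""

import numpy as np
import pytest

from retrodup.core import DeletionVariant, GenomicInterval
from retrodup import synthetic_data as syn


class TestGenome:
    def test_seed_determinism(self):
        a = syn.simulate_genome_with_genes(5, (2, 4), 80_000, seed=11)
        b = syn.simulate_genome_with_genes(5, (2, 4), 80_000, seed=11)
        assert a[0] == b[0]
        assert [m.exons for m in a[1]] == [m.exons for m in b[1]]
        assert a[2] == b[2]

    def test_single_exon_gene_has_no_introns(self):
        _, models, _ = syn.simulate_genome_with_genes(3, (1, 1), 50_000,
                                                      seed=1)
        assert all(m.n_introns == 0 for m in models)

    def test_placement_impossible_raises(self):
        with pytest.raises(ValueError, match="too small"):
            syn.simulate_genome_with_genes(50, (3, 6), 10_000, seed=0)

    def test_cds_translates_without_internal_stops(self, small_gene_bundle):
        _, models, proteins = small_gene_bundle
        for m in models:
            assert "*" not in proteins[m.transcript_id]
            assert len(m.mrna) == 3 * len(m.protein)


class TestRetropose:
    def test_clean_copy_equals_mrna(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        gene = models[0]
        cid, contig, truth = syn.retropose(gene, divergence=0.0,
                                           truncate_frac=0.0, seed=5)
        loc = truth.insertion_locus
        assert contig[loc.start:loc.end] == gene.mrna
        assert truth.introns_lost == gene.n_introns

    def test_one_junction_lost_one_intron_retained(self):
        _, models, _ = syn.simulate_genome_with_genes(
            6, (3, 3), 80_000, seed=13)
        gene = models[0]
        assert gene.n_introns == 2
        _, contig, truth = syn.retropose(gene, divergence=0.0,
                                         n_introns_lost=1, seed=2)
        loc = truth.insertion_locus
        retro = contig[loc.start:loc.end]
        # exon junction sequence present for exactly the lost junction,
        # and total length = mRNA + one retained intron
        assert len(retro) > len(gene.mrna)
        exon_lens = [len(e) for e in gene.exons_mrna_order]
        j1 = gene.mrna[:exon_lens[0] + 10]
        j2 = gene.mrna[exon_lens[0]:exon_lens[0] + exon_lens[1] + 10]
        spliced_junctions = sum(
            gene.mrna[cut - 5:cut + 5] in retro
            for cut in (exon_lens[0], exon_lens[0] + exon_lens[1]))
        assert spliced_junctions == 1
        assert truth.introns_lost == 1

    def test_divergence_within_binomial_bound(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        gene = models[1]
        rate = 0.1
        n_out = 0
        for i in range(200):
            _, contig, truth = syn.retropose(gene, divergence=rate, seed=i)
            loc = truth.insertion_locus
            retro = contig[loc.start:loc.end]
            mism = sum(a != b for a, b in zip(retro, gene.mrna))
            n = len(gene.mrna)
            # observed substitutions: a mutated site can coincide with the
            # original base 1/3 of the time is not modelled (mutations always
            # change the base), so the realised rate targets `rate`
            sd = np.sqrt(rate * (1 - rate) / n)
            if abs(mism / n - rate) > 3 * sd:
                n_out += 1
        assert n_out <= 5  # ~0.3% expected outside 3 SD

    def test_truncation_warning(self, small_gene_bundle):
        _, models, _ = small_gene_bundle
        gene = models[2]
        _, _, truth = syn.retropose(gene, truncate_frac=0.95, seed=1)
        assert truth.short_warning


class TestPopulationGenotypes:
    @pytest.mark.parametrize("f,expected", [(0.0, (0, 0)), (1.0, (1, 1))])
    def test_frequency_extremes(self, f, expected):
        panel = syn.make_panel(["CEU", "YRI"], 10)
        dels = [DeletionVariant("d1", GenomicInterval("chr1", 0, 100))]
        freqs = {("d1", p): f for p in panel.populations}
        out, _ = syn.simulate_population_genotypes(dels, panel, freqs,
                                                   seed=1)
        assert all(gt == expected for gt in out[0].genotypes.values())

    def test_unknown_population_raises(self):
        panel = syn.make_panel(["CEU"], 2)
        dels = [DeletionVariant("d1", GenomicInterval("chr1", 0, 100))]
        with pytest.raises(ValueError, match="unknown population"):
            syn.simulate_population_genotypes(
                dels, panel, {("d1", "XXX"): 0.5}, seed=1)

    def test_realized_frequencies_within_3sd(self, rng):
        panel = syn.make_panel(["P1", "P2", "P3", "P4", "P5"], 100)
        n_del = 100  # 500 (deletion, population) cells
        dels = [DeletionVariant(f"d{i}", GenomicInterval("chr1", 0, 100))
                for i in range(n_del)]
        freqs = {(d.id, p): float(rng.uniform(0.05, 0.95))
                 for d in dels for p in panel.populations}
        out, truth = syn.simulate_population_genotypes(dels, panel, freqs,
                                                       seed=8)
        n_ok = n_cells = 0
        for d in out:
            by_pop = {}
            for ind, gt in d.genotypes.items():
                by_pop.setdefault(panel.assignments[ind], []).extend(gt)
            for pop, alleles in by_pop.items():
                f = truth.frequencies[(d.id, pop)]
                n = len(alleles)
                sd = np.sqrt(f * (1 - f) / n)
                n_cells += 1
                if abs(np.mean(alleles) - f) <= 3 * sd:
                    n_ok += 1
        assert n_ok / n_cells >= 0.99


class TestOrthologBlocks:
    def test_no_loss_presence_is_full_clade(self):
        blocks, loci, truths = syn.simulate_ortholog_blocks(
            loss_probability=0.0, n_retrocopies=30, seed=2)
        root = syn._parse_newick(syn.EUTHERIA_NEWICK)

        def leaves_of(name):
            out = []

            def visit(n):
                if n.name == name:
                    out.extend(n.leaves())
                for c in n.children:
                    visit(c)

            visit(root)
            return set(out)

        for t in truths:
            assert set(t.presence) == leaves_of(t.planted_origin)

    def test_terminal_origin_single_species(self):
        blocks, loci, truths = syn.simulate_ortholog_blocks(
            loss_probability=0.0, n_retrocopies=100, seed=3)
        for t in truths:
            if t.planted_origin == "human":
                assert t.presence == frozenset(["human"])
                assert t.inferable_origin is None

    def test_mrca_truth_consistency(self):
        # inferable origin = smallest named clade containing the survivors
        blocks, loci, truths = syn.simulate_ortholog_blocks(
            n_retrocopies=200, seed=4)
        root = syn._parse_newick(syn.EUTHERIA_NEWICK)
        for t in truths:
            if len(t.presence) >= 2:
                assert t.inferable_origin == syn._mrca_name(
                    root, t.presence)


class TestCountsNB:
    def test_poisson_limit_variance(self):
        cm, _ = syn.simulate_counts_nb(2000, {"A": 5, "B": 5},
                                       dispersion=0.0, seed=6)
        ratio = cm.counts.var(axis=1, ddof=1).mean() / cm.counts.mean()
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_no_de_truth_empty(self):
        _, truth = syn.simulate_counts_nb(100, {"A": 3, "B": 3},
                                          de_fraction=0.0, seed=1)
        assert truth.effects == {}

    def test_planted_fold_change_realised(self):
        cm, truth = syn.simulate_counts_nb(
            400, {"A": 10, "B": 10}, dispersion=0.1, de_fraction=0.25,
            log2fc=2.0, seed=9, baseline_mean=500.0)
        idx = {l: i for i, l in enumerate(cm.loci)}
        in_b = np.array([cm.groups[s] == "B" for s in cm.samples])
        ratios = []
        for locus, (lfc, _) in truth.effects.items():
            row = cm.counts[idx[locus]]
            ratios.append((row[in_b].mean() / row[~in_b].mean())
                          / 2.0 ** lfc)
        r = np.array(ratios)
        # sampling noise of a 10-replicate NB mean ratio is ~15% per locus;
        # the planted 4-fold effect must hold in aggregate within 25%
        assert abs(r.mean() - 1.0) < 0.25
        assert np.median(np.abs(r - 1.0)) < 0.25


class TestReads:
    def test_expected_read_count_and_substring(self, rng):
        seq = syn.random_dna(rng, 1000)
        reads = syn.simulate_reads({"s": seq}, 100, 20.0, 0.0, seed=3)
        assert len(reads) == 200
        rc = syn.revcomp(seq)
        assert all(r in seq or r in rc for r in reads.values())

    def test_error_rate_within_3sd(self):
        import edlib

        rng = np.random.default_rng(1)
        seq = syn.random_dna(rng, 2000)
        rate = 0.02
        reads = syn.simulate_reads({"s": seq}, 100, 10.0, rate, seed=4)
        mism = total = 0
        rc = syn.revcomp(seq)
        for r in reads.values():
            mism += min(edlib.align(r, seq, mode="HW")["editDistance"],
                        edlib.align(r, rc, mode="HW")["editDistance"])
            total += 100
            if total >= 10000:
                break
        sd = np.sqrt(rate * (1 - rate) / total)
        assert abs(mism / total - rate) <= 3 * sd


class TestQpcrCurves:
    def test_halved_quantity_shifts_ct_by_one(self):
        _, ct1 = syn.simulate_qpcr_curves(1e-6, 2.0, seed=1)
        _, ct2 = syn.simulate_qpcr_curves(0.5e-6, 2.0, seed=1)
        assert ct2 - ct1 == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_curve_monotone(self):
        df, _ = syn.simulate_qpcr_curves(1e-6, 1.9, noise=0.0, seed=1)
        assert (np.diff(df["fluorescence"].to_numpy()) >= 0).all()

    @pytest.mark.parametrize("eff", [0.9, 2.5])
    def test_efficiency_domain(self, eff):
        with pytest.raises(ValueError):
            syn.simulate_qpcr_curves(1e-6, eff)
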