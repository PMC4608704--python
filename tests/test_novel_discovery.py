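"""Assembly, clustering, consensus, filtering and deletion-site calls."""

import edlib
import numpy as np
import pytest

from retrodup import novel_discovery as nd
from retrodup.synthetic_data import (
    random_dna,
    revcomp,
    mutate_sequence,
    simulate_contig_families,
    simulate_reads,
)


def _identity(a: str, b: str) -> float:
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    d = min(edlib.align(shorter, longer, mode="HW")["editDistance"],
            edlib.align(revcomp(shorter), longer,
                        mode="HW")["editDistance"])
    return 1.0 - d / len(shorter)


class TestAssembleContigs:
    def test_error_free_reads_reassemble_source(self, rng):
        truth = random_dna(rng, 800)
        reads = simulate_reads({"t": truth}, 100, 20.0, 0.0, seed=2)
        contigs = nd.assemble_contigs(reads, "ind1")
        assert len(contigs) == 1
        assert len(contigs[0]) >= 500
        assert _identity(contigs[0].sequence, truth) >= 0.99

    def test_non_overlapping_reads_no_contig(self):
        reads = {"r1": "ACGT" * 25, "r2": "TTGA" * 25}
        assert nd.assemble_contigs(reads, "i") == []

    def test_strand_symmetry(self, rng):
        truth = random_dna(rng, 700)
        reads = simulate_reads({"t": truth}, 100, 20.0, 0.0, seed=3)
        rc_reads = {k: revcomp(v) for k, v in reads.items()}
        c1 = nd.assemble_contigs(reads, "i")
        c2 = nd.assemble_contigs(rc_reads, "i")
        assert len(c1) == len(c2) == 1
        # canonical orientation makes the outputs identical
        assert c1[0].sequence == c2[0].sequence

    def test_deterministic(self, rng):
        truth = random_dna(rng, 900)
        reads = simulate_reads({"t": truth}, 100, 15.0, 0.0, seed=4)
        a = nd.assemble_contigs(reads, "i")
        b = nd.assemble_contigs(dict(reversed(list(reads.items()))), "i")
        assert [c.sequence for c in a] == [c.sequence for c in b]


class TestClusterContigs:
    def test_identical_from_two_individuals(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 700)
        contigs = [nd.Contig("a", seq, "ind1"), nd.Contig("b", seq, "ind2")]
        clusters = nd.cluster_contigs(contigs)
        assert len(clusters) == 1
        assert clusters[0].n_individuals == 2
        assert not clusters[0].is_singleton

    def test_unrelated_singletons(self):
        rng = np.random.default_rng(6)
        contigs = [nd.Contig("a", random_dna(rng, 700), "ind1"),
                   nd.Contig("b", random_dna(rng, 700), "ind1")]
        clusters = nd.cluster_contigs(contigs)
        assert len(clusters) == 2
        assert all(c.is_singleton for c in clusters)

    def test_planted_families_recovered(self):
        seqs, family_of = simulate_contig_families(
            50, members_per_family=3, within_divergence=0.015, seed=7)
        contigs = [nd.Contig(cid, s, f"ind{i % 5}")
                   for i, (cid, s) in enumerate(seqs.items())]
        clusters = nd.cluster_contigs(contigs)
        assert len(clusters) == 50
        for cl in clusters:
            fams = {family_of[m.id] for m in cl.members}
            assert len(fams) == 1
            assert len(cl.members) == 3


class TestConsensus:
    def test_singleton_unchanged(self):
        c = nd.Contig("a", "ACGT" * 200, "i")
        cl = nd.ContigCluster(representative=c, members=[c])
        assert nd.consensus(cl) == c.sequence

    def test_majority_outvotes_lone_snv(self):
        rng = np.random.default_rng(8)
        base = random_dna(rng, 600)
        variant = base[:300] + ("A" if base[300] != "A" else "C") \
            + base[301:]
        members = [nd.Contig("a", base, "i1"), nd.Contig("b", base, "i2"),
                   nd.Contig("c", variant, "i3")]
        cl = nd.ContigCluster(representative=members[0], members=members)
        assert nd.consensus(cl) == base

    def test_consensus_identity_with_noisy_members(self):
        rng = np.random.default_rng(9)
        truth = random_dna(rng, 800)
        members = [nd.Contig(f"m{i}", mutate_sequence(truth, 0.01, rng),
                             f"i{i}") for i in range(5)]
        cl = nd.ContigCluster(representative=members[0], members=members)
        cons = nd.consensus(cl)
        assert _identity(cons, truth) >= 0.995


class TestFilterSequences:
    def test_db_hit_filtered_with_label(self, rng):
        db_seq = random_dna(rng, 900)
        dbs = [("contaminant", {"v": db_seq})]
        retained, filtered = nd.filter_sequences({"c1": db_seq}, dbs)
        assert filtered == {"c1": "contaminant"}
        assert retained == {}

    def test_random_sequence_retained(self, rng):
        dbs = [("contaminant", {"v": random_dna(rng, 900)}),
               ("patch", {"p": random_dna(rng, 900)})]
        seq = random_dna(rng, 800)
        retained, filtered = nd.filter_sequences({"c1": seq}, dbs)
        assert retained == {"c1": seq}

    def test_partition_matches_truth_labels(self, rng):
        contaminants = {f"v{i}": random_dna(rng, 900) for i in range(3)}
        patches = {f"p{i}": random_dna(rng, 900) for i in range(3)}
        dbs = [("contaminant", contaminants), ("patch", patches)]
        consensi = {}
        truth = {}
        for i in range(20):
            kind = i % 3
            if kind == 0:
                base = contaminants[f"v{i % 3}"]
                consensi[f"c{i:02d}"] = mutate_sequence(base, 0.03, rng)
                truth[f"c{i:02d}"] = "contaminant"
            elif kind == 1:
                base = patches[f"p{i % 3}"]
                consensi[f"c{i:02d}"] = mutate_sequence(base, 0.03, rng)
                truth[f"c{i:02d}"] = "patch"
            else:
                consensi[f"c{i:02d}"] = random_dna(rng, 800)
                truth[f"c{i:02d}"] = None
        retained, filtered = nd.filter_sequences(consensi, dbs)
        for cid, label in truth.items():
            if label is None:
                assert cid in retained
            else:
                assert filtered.get(cid) == label
        # bookkeeping conserved
        assert len(retained) + len(filtered) == len(consensi)


class TestLocateDeletionSite:
    def _trio(self, rng, scar_len):
        def repl(c, other):
            return c if c != other else ("A" if other != "A" else "C")

        L, R = random_dna(rng, 600), random_dna(rng, 600)
        retro = random_dna(rng, 500)
        pre, post = random_dna(rng, 60), random_dna(rng, 60)
        # clean breakpoints: no chance microhomology at the edges
        if scar_len > 1:
            scar = random_dna(rng, scar_len)
            scar = repl(scar[0], pre[0]) + scar[1:-1] \
                + repl(scar[-1], post[-1])
        elif scar_len == 1:
            scar = repl(random_dna(rng, 1), pre[0])
        else:
            scar = ""
            R = repl(R[0], pre[0]) + R[1:]
            L = L[:-1] + repl(L[-1], post[-1])
        outgroup = {"og": L + pre + retro + post + R}
        reference = {"chr3": L + scar + R}
        return nd.Contig("c", retro, "i"), outgroup, reference, len(L), \
            scar_len

    def test_planted_site_exact(self, rng):
        contig, outg, ref, lpos, scar_len = self._trio(rng, 110)
        site = nd.locate_deletion_site(contig, outg, ref)
        assert isinstance(site, nd.DeletionSiteCall)
        assert site.reference_interval.start == lpos
        assert site.reference_interval.end == lpos + scar_len

    def test_clean_cut_insertion_point(self, rng):
        contig, outg, ref, lpos, _ = self._trio(rng, 0)
        site = nd.locate_deletion_site(contig, outg, ref)
        assert site.insertion_point
        assert len(site.reference_interval) == 1
        assert site.reference_interval.start == lpos

    def test_duplicated_flank_ambiguous(self, rng):
        contig, outg, ref, _, _ = self._trio(rng, 50)
        ref["chr3"] = ref["chr3"] + ref["chr3"][:650]
        site = nd.locate_deletion_site(contig, outg, ref)
        assert isinstance(site, nd.NoSite)
        assert site.reason == "ambiguous_anchor"

    def test_contig_absent_from_outgroup(self, rng):
        contig = nd.Contig("c", random_dna(rng, 500), "i")
        outg = {"og": random_dna(rng, 2000)}
        ref = {"chr1": random_dna(rng, 2000)}
        site = nd.locate_deletion_site(contig, outg, ref)
        assert isinstance(site, nd.NoSite)
        assert site.reason == "not_in_outgroup"


class TestEndToEnd:
    def test_planted_novel_retrocopies_recovered(self, rng,
                                                 small_gene_bundle):
        """Reads from >= 2 individuals per planted sequence assemble,
        cluster, survive filtering, and classify as retrocopies."""
        from retrodup import retrocopy_annotation as ann
        from retrodup.synthetic_data import retropose

        _, models, _ = small_gene_bundle
        planted = {}
        for i in range(2):
            gene = models[i]
            _, contig, truth = retropose(gene, divergence=0.1,
                                         seed=70 + i, flank_range=(40, 80))
            planted[f"novel{i}"] = contig
        contaminant = {"v": random_dna(rng, 900)}
        contigs = []
        for ind in range(3):
            pool = dict(planted)
            pool["contam"] = contaminant["v"]
            reads = simulate_reads(pool, 100, 20.0, 0.0, seed=80 + ind)
            contigs.extend(nd.assemble_contigs(reads, f"ind{ind}"))
        clusters = nd.cluster_contigs(contigs)
        consensi = {cl.representative.id: nd.consensus(cl)
                    for cl in clusters}
        multi = [cl for cl in clusters if cl.n_individuals >= 2]
        assert len(multi) == len(clusters)  # every source seen 3x
        retained, filtered = nd.filter_sequences(
            consensi, [("contaminant", contaminant)])
        assert sorted(filtered.values()) == ["contaminant"]
        # retained consensi match planted sequences at >= 99%
        assert len(retained) == 2
        matched = 0
        for seq in retained.values():
            for p in planted.values():
                if _identity(seq, p) >= 0.99:
                    matched += 1
                    break
        assert matched == 2
        # and they classify as retrocopies
        calls = ann.call_retrocopies(models[:2], retained)
        assert len(calls) == 2
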