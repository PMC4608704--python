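# Methods

This note records the models, parameter choices and numerical decisions
behind the pipeline, and what the synthetic data does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward strand; VCF
(1-based, anchor-base deletions, `END` honoured) and MAF (strand-relative
starts) are converted at the I/O boundary and nowhere else. Deletion
genotypes are binary presence/absence per allele; multi-allelic records are
split per ALT. Missing genotype calls are excluded from both numerator and
denominator of allele frequencies (how missing calls were handled upstream
of the published frequencies is not documented anywhere we could rely on;
excluding them is the estimator that remains unbiased under missingness at
random). Count matrices are accepted only with an explicit `#prefiltered`
flag line asserting the MAPQ ≥ 50 / uniquely-and-concordantly-mapped
contract — read alignment itself is out of scope.

## Retrocopy calling

The caller aligns each parental protein to the six frame translations of a
target with a local Smith–Waterman (BLOSUM62, gap open 11, extend 1; the
biopython `PairwiseAligner` supplies the DP engine). Identity is matches
over gap-excluded aligned columns; coverage is aligned parent residues over
protein length — the denominators are a package convention, as none is
universal. Acceptance requires span ≥ 150 bp, identity > 50 %,
coverage > 50 % (both strict), and ≥ 2 introns lost; rejection reports the
first failed criterion, and the rule is monotone in all four thresholds.
A shared 5-mer amino-acid word between protein and any frame translation
gates the full alignment; this is purely a speed device and can be
disabled.

**Intron-loss inference.** A junction screen requires the alignment to
cover `min_flank_aa` (default 10) residues on each side of the parental
exon junction; confirmation is at the nucleotide level: the parent mRNA
windows left and right of the junction (up to 60 bp each, truncated at
neighbouring junctions so a window never spans two exons' worth of
junctions) are located in the target by infix edit-distance alignment
(budget 40 % of the window), and the junction counts as lost iff some pair
of tied best placements is adjacent within `max_junction_gap_bp`
(default 30). This confirmation is immune to reading-frame artefacts: a
retained frame-disrupting intron shifts downstream exons out of frame, so
a purely protein-level distance test misjudges such copies, whereas the
exon DNA adjacency does not. The count is deliberately one-sided — a
retained intron is never counted as lost; a spliced junction lying outside
the single best local alignment can be missed. On generator truth the
count is exact for fully spliced and fully retained copies up to ~20 %
nucleotide divergence (600/600 in the development stress run); between 20
and 25 % divergence occasional undercounts appear as local alignments
fray. Partially processed copies (some introns retained) inherit the
one-sided guarantee only.

**ORF conservation** is a separate nucleotide-level test: global alignment
of the retrocopy to the parent CDS (match 2 / mismatch −3 / gap −10 −0.5
per base, free end gaps); conserved iff every internal gap run is a
multiple of 3 and translating the retrocopy in the parent-anchored frame
yields no internal stop over the aligned core.

Competing parent assignments on one locus resolve by alignment score, then
identity, then gene id.

## RDV detection

"Loss of at least 100 bp of the retrocopy sequence" is interpreted as
intersection length ≥ 100 bp (absolute, not a fraction). Population spread
counts populations with any nonzero frequency; the bins are
1 / 2–5 / 6–8 / 9–13 / all, with 9–13 kept as an explicit bin even though
published counts happened to leave it empty. Interval intersection runs on
an interval tree and is tested against a per-base brute-force counter.

## Conservation

Two retrocopies are orthologous when, projected through a shared alignment
block into column space, each covers ≥ 50 % of the other's aligned extent
(reciprocal overlap measured on block-projected extents, not raw genomic
lengths); groups are connected components of this relation. The origin of
a group with ≥ 2 species is the *named* lineage at (or first above) the
MRCA of the presence set: the bundled eutherian tree names exactly the
lineages used for origin counting (Hominidae, Catarrhini, Primates,
Murinae, Glires, Euarchontoglires, Laurasiatheria, Boreoeutheria,
Eutheria), so a human+chimpanzee pair dates to Hominidae and a mouse+rat
pair to the mouse–rat ancestor rather than Glires. Single-species groups
are undatable under the two-species rule and get no origin. A human
retrocopy is ancestral iff an ortholog exists in chimpanzee, gorilla,
orangutan, macaque or marmoset, and deeply conserved iff present outside
Euarchontoglires.

## Novel discovery

Per-individual assembly is a greedy overlap-layout assembler: reads are
deduplicated and sorted, contigs extend by maximal exact suffix–prefix
overlaps ≥ 31 bp on both strands, and contigs < 500 bp are dropped. This
is adequate for error-free to low-error resequencing reads at ≥ 15×
coverage over kilobase-scale inserts; it is not a de Bruijn assembler and
makes no attempt at repeat resolution or scaffolding. Clustering is greedy
incremental in decreasing length order with the 95 % identity / 70 %
coverage rule applied to the shorter sequence (the convention is
configurable because tools differ). Consensus is a star alignment against
the representative with per-column majority vote, ties to the
representative; insertions relative to the representative are ignored.
Filtering thresholds against labelled databases default to 90 % identity
over 50 % of the consensus and are configurable — the right values depend
on the databases used.

**Deletion-site localisation** places the contig in the outgroup genome,
then anchors each outgroup flank in the reference by the innermost unique
exact 40-mer, scanning outward past windows that are absent (deleted
sequence) and aborting on any window that occurs more than once
(`ambiguous_anchor`). Anchors are extended inward base-by-base until the
first reference/outgroup disagreement; the deletion site is the reference
interval strictly between the extended boundaries. A zero-length gap is
reported insertion-point style as a 1 bp interval, and a short boundary
overlap (≤ 20 bp) is collapsed the same way — breakpoint microhomology
makes those bases unattributable in principle, so exact recovery is only
defined for breakpoints without chance edge matches (which is how the
generator plants them).

## Expression

RPM uses per-sample totals over the provided loci unless genome-wide
mapped totals are supplied. The differential test is a per-locus
negative-binomial Wald test: median-of-ratios size factors; per-locus
method-of-moments dispersion from pooled within-group variance of
normalised counts, floored at 1e−8 and shrunk 50/50 in log space toward
the median per-locus estimate (stabilising the plug-in variance at small
n); Wald statistic on the natural-log fold change with variance
`(1/μ_ref + α)/n_ref + (1/μ_test + α)/n_test`; reference distribution
Student t with n₁+n₂−2 degrees of freedom — with a plug-in dispersion the
normal reference is measurably anticonservative (~0.06 empirical type-I at
nominal 0.05 with 10 vs 10 replicates) while the t reference restores
~0.05. BH adjustment runs over tested loci. Fold changes are reported on
the linear scale, tested over reference, both directions (0.43 and 2.10
are both 2-fold hits). The raw (unshrunk) fold change is what the 2-fold
rule tests.

## Validation statistics

The two-sided Fisher p sums hypergeometric point probabilities ≤ the
observed table's (minimum-likelihood convention, tie comparison guarded by
a 1e−7 relative tolerance); it matches an exact rational-arithmetic
enumeration to 1e−10 on random tables. qPCR relative quantity is
`2^−(Ct_target − Ct_reference) × 10⁶`, with targets above Ct 32 reported
not-expressed (Ct exactly 32 is still expressed — the cutoff is "above").
Efficiency estimation subtracts a baseline (mean of the first 3 cycles),
restricts candidate windows to the exponential band — signal between 0.1 %
and 2 % of the curve maximum, clearing both baseline-subtraction error and
plateau suppression — picks the `window_size` (default 4) run maximising
the R² of a line fit to log₁₀ signal (ties to the brighter window), and
widens it while the fit stays straight. Efficiency is 10^slope on the 1–2
per-cycle scale; values above 1.8 (strictly) are acceptable.

## Synthetic data: what it emulates and what it does not

Genes are fully coding (mRNA = CDS, no UTRs, no stop codon), exon
boundaries fall at arbitrary codon phases, introns are 80–400 bp with
GT…AG ends. Retroposition splices a contiguous run of junctions and
retains the remaining introns, applies uniform point mutation (indels only
via an explicit flag, so identity-threshold tests and frameshift/ORF tests
stay separable), truncates from the 5′ end, and embeds the copy between
random flanks. Genotypes are Hardy–Weinberg draws per allele — no
linkage, no inbreeding. Ortholog blocks are ungapped with per-species
offset jitter of ≤ 50 bp over 600 bp loci (reciprocal overlap ≥ ~83 % for
true pairs; decoys are shifted to < 50 %); losses remove whole subtrees,
so there is no homoplasy. Counts are NB with a shared dispersion and
planted two-group fold changes; reads are uniformly placed single-end
substitution-only; qPCR curves are logistic-clipped exponentials with
multiplicative log-normal noise (default 1 % in simulations here — the
exponential window of real SYBR curves is similarly clean, but real
baselines drift, which is not modelled). None of this reproduces human
genome structure, repeat content, alignment artefacts or library effects:
passing tests demonstrate the *logic* of each stage under its stated
assumptions, not performance on real sequencing data.

Problem sizes in the test suite and acceptance script are desk-scale by
design: 100-positive / 100-negative caller sets, 14 populations × 100
diploids, 500 simulated ortholog groups, 2,000-locus expression matrices,
4 planted novel retrocopies × 3 individuals — large enough for the
binomial error bounds asserted, small enough to run the whole suite in
about a minute.

## Known limitations

* Single best local alignment per (protein, target): no chaining across
  retained introns, so intron-loss counts for partially processed copies
  are lower bounds; frameshifted copies are handled by the ORF test, not
  by frameshift-aware alignment.
* The assembler and clusterer are deterministic simplifications sized for
  synthetic data, not replacements for production assemblers.
* Deletion-site breakpoints with microhomology are reported insertion-point
  style rather than resolved.
* The differential test uses raw fold changes and a constant-dispersion
  shrinkage target; no trended dispersion, no LFC shrinkage, two groups
  only.
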