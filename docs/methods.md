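# Methods

`hmcdiff` implements the computational core of a 5-hydroxymethylcytosine
(5-hmC) profiling study: enrichment of pulldown-sequencing peaks over genomic
annotations by a tag-weighted permutation test, gene-level 5-hmC density
quantification, integration with expression, replicate-consensus overlap,
tumor/normal differential calls, and TAB-seq base-resolution quantification.
This note records the model, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish.

## Coordinates and interval arithmetic

All intervals are 0-based, half-open (BED convention) internally; GTF input
(1-based, closed) is converted on read. A single internal convention avoids
off-by-one drift between the BED-consuming and GTF-consuming stages.

Peak shuffling places each peak on a chromosome drawn with probability
proportional to chromosome length among chromosomes long enough to hold it,
then uniformly such that the peak fits entirely. Shuffled peaks may overlap
one another and never straddle chromosomes, mirroring the default behavior
of the standard BED shuffling tool. No exclusion list (assembly gaps) is
applied by default; the synthetic genomes have none. Each shuffle iteration
is seeded from an independent child of the master seed
(`numpy.random.SeedSequence.spawn`), so permutation runs are reproducible
and the iterations independent.

## Permutation enrichment statistic

For a peak *i* with `t_i` tags over length `L_i`, the density is
`d_i = t_i / L_i`. The observed statistic for an annotation *A* is

    Observed(A) = Σ_i |peak_i ∩ A| · d_i ,

the total sequencing-tag mass falling over the annotation. The expected
value is the mean of the same statistic over `n_shuffles` genome-wide
shuffles (default 1,000), enrichment is `Observed / Expected`, and the
empirical p-value uses the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + n_shuffles)`, which is never zero and
floors at 1/1001 for 1,000 shuffles. The depletion tail is computed
analogously and reported alongside; enrichment is reported one-sided by
default. The null standard deviation is also returned as a z-score
diagnostic, though the primary outputs are the ratio and the permutation p.

Annotation intervals are merged before intersection so a base contributes
once per annotation. A per-feature (unmerged) accounting would double-count
bases where features overlap; merged is the only mode offered because the
constructed annotations are merged by construction. When the expected value
is zero the ratio is undefined (NaN) and flagged; the p-value is still
reported.

Replicates are analyzed independently and their enrichment ratios averaged;
the across-replicate spread is the sample standard deviation (ddof=1), which
reduces to 0 for a single replicate by convention.

## Annotations

* **Promoters**: per transcript TSS, the window from 500 bp upstream to
  2 kb downstream (an asymmetric window reaching into the gene body), strand
  aware by default with a strand-ignorant mode, clamped to chromosome
  bounds, merged. One window per distinct transcript TSS, not per gene.
* **CpG shores**: the 2-kb flanks of each CpG island with all island bases
  subtracted, so no base is simultaneously island and shore — this keeps the
  island-vs-shore enrichment contrast interpretable.
* **Extended genes**: gene bodies slopped 2 kb both sides; the unmerged
  per-gene intervals remain queryable for gene-list construction, while the
  merged union serves as an enrichment annotation.

Two deliberately distinct gene/peak rules coexist: hydroxymethylated gene
*lists* use the 2-kb-extended body, whereas gene-level *quantification* and
the consensus-overlap gene calls use the unextended body.

## Gene-level quantification

Only genes whose unextended body overlaps a called peak are quantified. A
tag counts toward a gene when it overlaps the body; a tag overlapping more
than one quantified gene is ambiguous and discarded (union-mode counting).
Density is `tags / gene length`. Genes are binned by density percentile at
0–25, 25–75, 75–98, 98–100; a gene of ascending rank *r* among *n* sits at
percentile `100·r/n` and bins have inclusive upper edges, so 100 distinct
densities split 25/50/23/2 and four records split 1/2/0/1. Ties are broken
by gene id, making the assignment deterministic.

Metagene profiles rescale each feature body to 100 bins with 20 fixed-width
bins per 2-kb flank, average per-bin coverage over features, normalize to
tags per million per base, and reverse minus-strand features so bin 0 is
always the 5′ end. Coverage is evaluated through a piecewise-linear
integrated-coverage table, so fractional bin edges are exact rather than
rounded to bases.

## Expression integration

Differential-expression tables are inputs (the upstream caller is external);
classification defaults to up/down when `q ≤ 0.05` and `|log2FC| ≥ 1`, both
configurable, since the study's own thresholds come from the external
caller's conventions. Bin-vs-class association uses the Pearson chi-squared
test without continuity correction (`scipy.stats.chi2_contingency`);
all-zero rows/columns are dropped with a warning and the degrees of freedom
adjusted. Genes present on only one side of the join are counted and
reported, not silently dropped.

## Consensus overlap and tumor/normal calls

A consensus set is the base-level intersection of the merged coverage of
every replicate (a ≥k-of-n sweep is available for larger groups). Base
overlap between two consensus sets reports shared bases and the fraction of
each set covered — both directions, since containment is asymmetric. A gene
is hydroxymethylated for a set when the set intersects its body by ≥1 base.

Gain/loss calls are presence/absence contrasts: loss = body hit by the
normal consensus and not the tumor consensus, gain mirrored, both-or-neither
uncalled. This binary criterion is this package's design choice; a
density-based alternative would need matched sequencing depths, which the
presence/absence rule does not assume. Expression concordance tests each
called gene with a two-sided Wilcoxon rank-sum test (exact when the pooled
sample is ≤12 and tie-free, otherwise normal approximation with tie and
continuity corrections), Bonferroni-corrected across the set of called genes
actually tested — not the transcriptome — with direction from the median
difference, consistent with a rank test's location interpretation.

## TAB-seq quantification

Standard bisulfite leaves 5-mC and 5-hmC reading as C; TET-assisted
bisulfite (TAB) leaves only 5-hmC reading as C. With C fractions `f_bs` and
`f_tab`,

    %5-hmC = 100·f_tab,  %5-mC = 100·max(0, f_bs − f_tab),  %C = remainder.

When sampling noise makes `f_tab > f_bs`, %5-mC is clamped to 0 and %C
absorbs the remainder — the directly observed 5-hmC fraction is never
re-weighted. Sites need ≥16 clones per treatment (the assay's design floor)
to be quantified. Condition comparisons pool clone counts across a region's
CpGs into a 2×2 C/T table per condition (per-site tables at ~20 clones are
underpowered) and use Pearson chi-squared with df 1; the TAB channel tests
5-hmC, the bisulfite channel total modification. No continuity correction by
default (totals ≥32 under the clone floor); Yates correction is behind a
flag.

## Synthetic data: what it emulates and what it does not

The generator produces a small multi-chromosome genome (default 5 Mb over
two chromosomes), gene bodies and CpG islands packed without overlap
(log-normal lengths: genes median 6 kb, σ=0.6; islands median 1 kb, σ=0.3),
MACS-style peaks (median 500 bp, σ=0.4) with negative-binomial tag counts
(mean 50, dispersion 10 — over-dispersed, as sequencing counts are), and tag
alignments placed inside their peaks. A target fraction *q* of tag mass can
be planted inside a designated annotation: each peak lands fully inside with
probability *q* and fully in the complement otherwise, so the planted
fraction equals *q* in expectation and a planted *q* over an annotation of
genomic fraction *f* yields enrichment ≈ *q/f*. Expression follows
`FPKM ∝ exp(slope · z(density) + noise)` with a logistic induction link;
tumor/normal cohorts plant gain/loss genes as presence/absence of gene-body
peaks, with a configurable subset given a true expression shift — at zero
expression noise the unshifted genes carry identical values in both cohorts,
so recovery of planted counts is exact by construction. TAB-seq clone counts
are binomial draws from the planted three-state truth.

The synthetic genomes have uniform mappability, no sequence content, no GC
structure, no assembly gaps, and non-overlapping features. Passing tests
therefore establish the correctness of the arithmetic and the calibration of
the permutation and chi-squared machinery under the stated sampling models —
not robustness to alignment artifacts, copy-number variation, or
GC-dependent pulldown bias in real data.

## Problem sizes and numerical choices

Simulation-based checks use a 5 Mb genome (1 Mb for the null-calibration
runs) with 100–2,000 peaks and 200–1,000 shuffles; these sizes put the
Monte-Carlo error of each checked quantity well inside its stated tolerance
(e.g., ~2,000 uniform peaks give a per-dataset enrichment standard error of
~0.03 against a ±0.1 acceptance band). The permutation-p floor scenario uses
the full 1,000 shuffles because the floor 1/1001 is the quantity under test.
Degenerate inputs are handled explicitly: empty annotations give observed 0;
an expected value of 0 flags the ratio undefined; constant Wilcoxon samples
give p = 1; zero chi-squared margins give p = 1 with a warning. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; generator functions salt the master seed per
product (genome, peaks, expression, cohort, TAB-seq) so the products are
independent but jointly reproducible.

## Known limitations

* The shuffle null does not match GC content, mappability, or gap structure;
  on real genomes enrichment against such nulls is anti-conservative for
  GC-rich annotations.
* Tag counting treats tags as single unspliced intervals; fragment-level or
  spliced-aware counting is out of scope.
* The gain/loss criterion is binary presence/absence of consensus peaks;
  quantitative 5-hmC changes below the peak-calling threshold are invisible
  to it.
* Percentile binning requires ≥4 quantified genes and its occupancy at very
  small *n* depends on the documented inclusive-edge rule.
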