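# Methods

This note documents the models and procedures `monokaryo` implements, the
parameters that matter, the numerical conventions, and what the synthetic
cohorts do and do not emulate.

## Normalization and the expressed-gene filter

Size factors use the classic median-of-ratios estimator: with counts
k<sub>gj</sub> and the per-gene geometric mean over samples as reference,
s<sub>j</sub> = median over reference genes of k<sub>gj</sub> / geomean.
Reference genes are rows with strictly positive counts in every sample;
geometric means are formed in log space to avoid overflow, while the median
of the ratios themselves is taken in linear space (with an even reference
count, the two central order statistics are averaged). When no all-positive
row exists, an explicit `pseudo_reference=True` fallback computes each row's
geometric mean over its positive entries only ("poscounts" style); the
default is to raise, because silent fallback changes the estimator.

NRC (normalized read count) is count ÷ size factor. The log transform is
log2(NRC + 1): the pipeline's fold-change thresholds are 2-fold, making
base 2 the natural scale, and the +1 pseudocount keeps zero counts finite.
A gene is *expressed* when NRC ≥ 20 in **every** sample of the relevant
scope (a cell/tissue type, or all samples); the boundary value passes. The
threshold is a parameter everywhere it appears.

## e-karyotyping

The chain, in order: normalize → expressed filter → log2 → sort genes by
(chromosome, start, gene id) → subtract each gene's median across the
reference samples (default: all samples; configurable to a control group) →
remove the 10% most variable genes → winsorize → segment per sample and
chromosome → call → smooth.

*Variability filter.* Per gene, SS = Σ<sub>samples</sub> value²; exactly
⌊fraction · n⌋ genes with the largest SS are removed. Ties are broken by
genomic position, removing later-ordered genes first — any deterministic
rule would do; this one is documented and tested. The filter runs after the
expressed-gene restriction; both orderings are defensible and the choice is
explicit in the pipeline code.

*Winsorization.* Per sample, values are clipped to the [q, 1−q] empirical
quantile range with q = 0.001. The thresholds are order statistics (the
nearest rank outside each tail), which makes the operation idempotent —
an interpolated quantile would drift under repetition.

*Segmentation.* Piecewise-constant least squares: minimize
Σ<sub>seg</sub> SSE(seg) + γ·(#segments − 1) exactly, by O(n²) dynamic
programming over breakpoint positions, with an optional hard minimum
segment length. Cost ties break toward fewer segments, then leftmost
breakpoints. The penalty is scale-free: γ = penalty · σ̂² with penalty = 12
by default and σ̂ = 1.4826 · MAD(diff(y)) / √2, the standard
median-absolute-deviation estimator applied to lag-1 differences (which are
noise-dominated for a piecewise-constant signal). σ̂ is estimated per
sample from all within-chromosome differences, giving each sample one noise
level across its genome.

*Calling.* A segment is an aberration when all three hold: |mean| ≥ 0.25
log2 units (roughly the shift a mosaic single-copy gain produces), length ≥
50 genes, and a two-sided z-test of the segment mean against zero
(sd = σ̂/√length) at p ≤ 0.01. The segmentation itself runs **unconstrained**
(minimum segment length 1) and the 50-gene floor is enforced by the caller,
not the optimizer. This split matters: if the optimizer were forbidden to
form segments shorter than 50 genes, a 40-gene aberrant run would be
absorbed into a 50-gene segment whose diluted mean (0.8× the run's) can
still clear the deviation floor — the size floor would then be invisible in
behavior. With the split, a planted run shorter than 50 genes forms its own
segment and is rejected by the length rule, so the configured floor is
exactly the smallest detectable event, which the acceptance scan verifies.
`pcf_segment` still exposes `min_size` as a hard DP constraint for callers
who want it.

*Smoothing.* Centered moving average, 200-gene window by default, truncated
at chromosome boundaries (never wrapped, never crossing chromosomes); with
an even window the extra gene falls on the trailing side (pandas rolling
convention).

*Verdict.* Per sample, the set of chromosomes with ≥ 1 called segment; an
empty set is reported as a stable karyotype.

## Moderated t

Two-group comparison on log2 normalized expression of genes expressed in
either group. Per gene: pooled variance s²<sub>g</sub> with d<sub>g</sub> =
n_A + n_B − 2 df. The prior (d₀, s₀²) is fitted by moment-matching on
log s²<sub>g</sub>, using E[log(χ²<sub>k</sub>/k)] = ψ(k/2) − log(k/2) and
Var[log(χ²<sub>k</sub>/k)] = ψ′(k/2); the trigamma inverse is solved by
Newton iteration. When the observed spread of log s² does not exceed the
sampling spread, d₀ = ∞ and every gene receives the common variance (the
arithmetic mean of the s², the natural estimate under a shared variance).
Exact-zero sample variances are offset to 10⁻⁵ × median before the log;
this matches the canonical empirical-Bayes implementation, against which
the unit tests verify agreement to 1e-5 (and equality with the classical
pooled t when d₀ = 0).

Posterior variance s̃² = (d₀s₀² + d<sub>g</sub>s²)/(d₀ + d<sub>g</sub>);
t = Δmean/(s̃·√(1/n_A + 1/n_B)); two-sided p from t with d₀ + d<sub>g</sub>
df (normal when d₀ = ∞). All-identical rows get t = 0, p = 1 by convention.
Fold change is the difference of group means on the log2(NRC + 1) scale —
a geometric-mean fold change, consistent with the log-domain test; FC-abs =
2^|log2FC|. BH adjustment is the standard step-up q-value; significance
requires q ≤ 0.05 **and** FC-abs ≥ 2, boundaries inclusive, with up/down
partition by the sign of log2FC.

## Structure summaries

- **Concordance**: squared Pearson correlation on log expression over the
  expressed-gene set; a group's summary is the mean r² over its C(m,2)
  distinct pairs with a 95% Student-t interval across those pairs (a
  Fisher-z interval would also be reasonable; the t-interval is the
  default).
- **Clustering**: Euclidean distances between samples on the expressed log
  matrix, average linkage by default (complete/ward available); scipy's
  deterministic agglomeration order is the tie-break. Dendrograms export to
  Newick with branch lengths from merge heights.
- **PCA**: SVD of the gene-centered matrix; variance fractions
  σ²<sub>i</sub>/Σσ², non-negative, descending, summing to 1.
- **Lineage profiling**: per gene, z-scores across samples (zero-variance
  genes excluded); a sample's score for a marker set is the mean z over the
  set's usable genes; assignment is the argmax set, with a tie flag when
  the top two scores are within 1e-12.
- **Upregulated union**: across several pairwise comparisons against
  reference tissues, the union of significantly upregulated genes with a
  per-comparison membership matrix (the Venn structure).

## Synthetic cohorts

Counts are negative binomial with variance μ + φμ². Defaults are the
package's reference study conditions, chosen once to be realistic at desk
scale: 9 chromosomes (8 autosomes + X, echoing the *M. domestica*
karyotype) of 1,200 genes; per-gene baseline means exp(N(5, 1.5²)) (median
mean count ≈ 150, a bulk-RNA-seq-like spread); dispersions
φ = exp(N(ln 0.05, 0.5²)) (biological CV ≈ 22% at the median); library-size
factors uniform on [0.7, 1.4]; 10% DE genes between groups with |log2FC|
uniform on [1, 3] and random sign; dosage events multiply the expected
counts of the targeted genes (1.5 = single-copy gain of a diploid locus);
marker sets add a per-group log2 elevation. One master seed spawns fixed
child streams per stage and per (sample, chromosome) count block, so adding
an aberration to one block leaves every other draw untouched and identical
spec + seed reproduces byte-identical output.

`spike_aneuploidy` also operates on an existing count matrix: deterministic
mode scales and rounds half-to-even (exactly testable); Poisson mode
re-draws each targeted count from Poisson(dosage × count), preserving the
expectation.

What the generator does *not* emulate: GC/length biases, sample batch
effects, correlated gene modules, single-cell dropout, isoform structure,
or mosaicism below the whole-sample level. Tests passing on these cohorts
therefore demonstrate algorithmic correctness and detection power under
clean negative-binomial noise, not robustness to every artefact of real
libraries.

## Problem sizes and test conditions

The packaged validation experiments use cohorts of 6 chromosomes × 500
genes × 6 single-group samples for the karyotyping controls (chromosomes
comfortably above the 50-gene call floor), 2,000-gene tracks for the
aberration-size scan, and 2,000-gene two-group cohorts at n = 3 vs 3 for
the differential-expression power runs — sizes chosen so the full suite
runs in well under a minute of compute per experiment while keeping
segment-level statistics meaningful. Across 50 seeded control cohorts the
spiked sample's called set is exactly {chr2, chr5} with at most one false
chromosome in total, and clean cohorts produce zero calls.

## Degenerate inputs and numerical conventions

- Chromosomes shorter than the minimum segment length return one segment.
- Constant tracks (σ̂ = 0) segment to a single segment via the
  fewest-segments tie-break; calls on σ̂ = 0 use p = 0 for nonzero means.
- Medians with even counts average the two central order statistics
  (linear space for size factors, log2 space for baselines).
- Annotation is held 0-based half-open; GFF3 input (1-based inclusive) is
  converted on read. Chromosome order is order of first appearance in the
  annotation, so "chr2" precedes "chr10" whenever the source lists it so.
- Floats are written with 6 significant digits; all randomness flows from
  explicit integer seeds.

## Known limitations

- e-karyotyping is blind to copy-neutral events and to aberrations in gene
  deserts; sensitivity depends on expressed-gene density along the genome.
- The deviation floor (0.25 log2) is tuned for single-copy gains/losses in
  largely pure samples; heavily mosaic samples dilute below it.
- The moderated t assumes roughly Gaussian log-expression within groups;
  at very low counts the NB skew leaks into the tails.
- The multi-group machinery covers pairwise designs only; no batch
  covariates or GLM-based count models.
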