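# Methods

## Quantification model

DamID signal is quantified per GATC fragment. Fragment boundaries sit at
the first base of each exact GATC occurrence on the forward strand (GATC is
its own reverse complement, so one strand suffices); the 4-bp site belongs
to the fragment it starts, terminal fragments run to the chromosome ends,
and zero-length fragments are suppressed. On i.i.d. uniform sequence the
expected fragment length is 1/0.25⁴ = 256 bp. Reads are extended from
their 5′ end to the mean DamID fragment length (200 bp, configurable) in
their 3′ direction and clamped to the chromosome; a read overlapping k
fragments counts in all k (coverage semantics — the alternative,
fractional assignment, would couple neighbouring fragments' counts in a
way the downstream per-fragment model does not expect).

## Enrichment test

For each fragment we fit a two-group negative-binomial log-linear model
log μ_ij = log s_j + β₀ + β₁·fusion_j by iteratively reweighted least
squares, with fixed per-fragment dispersion α and median-of-ratios size
factors s_j (reference = per-fragment geometric mean over fragments
positive in every sample; factors reported unscaled). The enrichment
p-value is a two-sided Wald test on β₁ (log₂FC = β₁/ln 2); a
likelihood-ratio variant is available and is used as an independent check
in the tests. Fragments with all-zero counts are untested and excluded
from the Benjamini–Hochberg denominator. Binding intervals are maximal
runs of fragments with log₂FC > 0 and adjusted p below the threshold
(0.05 and 0.01 are both first-class outputs) whose inter-fragment gaps
are ≤ 100 bp.

Dispersion estimation is deliberately simple and fully documented rather
than an empirical-Bayes shrinkage scheme: per-fragment method-of-moments
α̂ = max(0, (s² − μ̄)/μ̄²) with the variance pooled within condition, a
mean-dispersion trend α_tr(μ) = a₀ + a₁/μ fitted by least squares over
fragments with α̂ > 0, and a final 50/50 blend floored at 1e-8. The
estimator is validated by calibration (null simulations at α = 0.1 with
3+3 replicates keep the raw p < 0.05 rate near nominal and BH calls near
zero) and by recovery/FDR on planted sites, not by matching any external
package's shrinkage numerically.

## Liftover

The mapped fraction of an interval is the share of its bases inside a
chain's ungapped blocks. A translation is accepted only when exactly one
chain reaches minMatch (default 0.7; 0.5 recommended for distant species
pairs); two or more qualifying chains are rejected as ambiguous, mirroring
the behaviour of region-level liftover with multiple outputs disallowed.
The target is the enclosing span of the mapped pieces. Reverse-strand
chains are normalized to forward-strand target coordinates on read, with
an orientation flag; strand flips on translation. An interval lying
wholly inside a chain's internal gap reports `below_minMatch` (fraction
0), `no_chain` being reserved for intervals no chain span touches.

## Conservation, annotation, turnover

Conservation is single-linkage with ≥ 1 bp overlap and no reciprocal
fraction, per the intersection semantics of the underlying comparisons.
Category distributions use union accounting: intervals from different
species that overlap on the reference are merged into one representative
whose category is the number of species contributing, so percentages are
over all intervals identified across species. Nearest-gene assignment
minimizes the interval-to-gene-span distance with lexicographic
tie-breaks (ties flagged). Feature classes are decided by the interval
midpoint with precedence promoter > exon > intron > intergenic; the
promoter window is [TSS − 2000, TSS + 500) in transcription orientation,
a conventional window chosen here since annotation-tool defaults vary.
Intron ranks count from the 5′ end in transcription order using the
longest transcript (isoform handling is unspecified upstream; longest is
the common fallback). First-intron enrichment compares observed rank-1
hits with an expectation proportional to genomic intron length per rank
(χ², 1 df; exact binomial when expected counts drop below 5).

Turnover is scored per gene: both species have intervals annotated to the
gene, and no interval of one overlaps any translated interval of the
other — any overlap cancels the event (the strictest reading; loci with
mixed overlapping and non-overlapping intervals are counted as
positionally conserved).

## Joint quantitative comparison

Consensus intervals are the merged union of the per-species (translated)
call sets, kept when ≥ 2 sets support them. Extended reads are counted
per consensus interval, all samples are normalized together with
median-of-ratios factors, and affinity = log₂(count/size factor + 0.5);
the +0.5 offset keeps zero counts finite and the base-2 log matches the
fold-change scale used elsewhere. Correlation uses Pearson over
intervals with average-linkage clustering on 1 − r; PCA is an SVD of the
centred sample × interval matrix with the sign convention that the
largest-magnitude loading is positive. Differential binding reuses the
NB Wald machinery on consensus counts at FDR1 = 0.01 / FDR5 = 0.05;
significant intervals are *quantitative* when natively called in both
species and *qualitative* when called in exactly one.

## Motif analysis

Weight scores are log₂ odds w = log₂((p + c·bg)/((1 + c)·bg)) with
pseudocount c = 0.01 (the upstream weight-score scale is tool-internal,
so the ≥ 4 cutoff is adopted on this scale and configurable). The null
score distribution is computed exactly by dynamic programming on a 1e-3
score grid; for width ≤ 8 it matches exhaustive enumeration over 4^w
background-weighted words within grid tolerance. Matches must clear both
the score cutoff (≥ 4) and the match p-value cutoff (< 1e-4); both
strands are scanned, N windows skipped. The background is 0-order,
uniform by default or estimable from the scanned sequences. Positional
conservation requires the identical alignment start column and strand
(no slack); opposite-strand matches at one column are distinct. A
nucleotide column counts as conserved only when every species carries the
identical base with no gap. Wilcoxon rank-sum tests use midranks, exact
enumeration for n ≤ 12 without ties, and otherwise a normal approximation
with tie-corrected variance and ±0.5 continuity correction.

## Synthetic data generator

The generator emulates the comparative study design: an ancestral
uniform-composition sequence with non-overlapping genes (2–4 exons) and
upstream CRMs evolves along a rooted phylogeny (default three species at
branch-length ratios 1:1:4, pairwise distances 0.05/0.2 substitutions per
neutral site; a four-species variant adds a more distant outgroup) under
Jukes–Cantor substitutions plus indels at 10% of the substitution rate
with geometric lengths (mean 3), excluded from exons and planted site
windows. Because every surviving base keeps its ancestral coordinate,
pairwise chains and per-locus multiple alignments are emitted exactly
from the recorded homology map; lineage-specific insertions get private
alignment columns.

Planted sites are 140-bp windows holding 1–5 PWM-sampled motif instances
written into the ancestral sequence near genes (turnover sites occupy two
windows ≥ 2.6 kb apart inside a dedicated gene). The conservation class
is encoded in per-species *binding presence*, which drives the read
simulation; only conserved-class motifs evolve under the constraint
factor (default 0.1, chosen to make the motif-conservation contrast
detectable at a few hundred loci). Planting all classes ancestrally keeps
the truth chains and alignments exact while preserving the evaluated
semantics of every class. Site enrichment folds are drawn from
Uniform(4, 8) and then drift along the tree as Brownian motion of the log
fold (variance 1.0 per unit branch length, floored at fold 1), so
quantitative binding divergence between two species grows with their
phylogenetic distance — the mechanism behind the divergence-follows-
phylogeny pattern the joint comparison measures.

Reads: per fragment, the control intensity is uniform per bp and the
fusion intensity is background × (1 + (fold − 1)·k(d)) with the
triangular kernel k(d) = max(0, 1 − d/spread) on the distance d from the
fragment midpoint to the nearest present site of the factor (common-class
sites feed both factors). The methylation spreading distance is not
quantified upstream, so the kernel half-width is a free parameter; the
default 500 bp spans roughly two GATC fragments and keeps turnover
windows of one gene from merging into one called interval. Per-replicate
fragment counts are negative binomial (default α = 0.1, 3 replicates,
200,000 reads per sample) scaled to depth; reads (50 bp, random strand)
are placed uniformly within their fragment, which is immaterial because
the pipeline consumes fragment overlaps only.

What the generator does *not* emulate: mappability and GC bias, PCR and
sequencing error, realistic indel spectra, chromatin-accessibility
covariates in the Dam-only background, and genome rearrangements
(chains are always collinear). Passing tests therefore demonstrate the
correctness and calibration of the pipeline's inference under its own
model assumptions, not robustness to those artefacts.

## Problem sizes and determinism

The default validation scenario is 3 species × 1 Mb with 300 planted
sites, 3+3 replicates at depth 200,000, and ~110 genes; unit tests use
smaller instances of the same generator (150–400 kb) and the
motif-conservation study uses 600 loci of 260 bp in four species so that
both comparison groups exceed 200 matched motifs. All randomness flows
through explicit integer seeds; rerunning any simulation with the same
seed reproduces its outputs bytewise.

## Known limitations

- The NB Wald test with 3+3 replicates is mildly anti-conservative (null
  raw p < 0.05 rate ≈ 0.06); BH adjustment absorbs this in practice.
- The dispersion trend is fitted only over fragments with positive
  moment estimates, which biases it slightly upward (conservative).
- Conservation classification inherits liftover failures: sites whose
  intervals fail minMatch in one species are counted from the surviving
  species only.
- `common_unique_analysis` compares same-class unions across species;
  with very small classes its χ² can be degenerate and is then skipped.
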