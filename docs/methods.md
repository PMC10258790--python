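# Methods

This note records the models, parameter choices and numerical conventions
behind `chromarch`, and what the synthetic-data suite does and does not
establish about real data.

## Coordinates and containers

All coordinates are 0-based, half-open; bin `b` at bin size `s` covers
`[b*s, (b+1)*s)`. Contact matrices are dense, symmetric, float64, with a
per-bin boolean mappability mask; masked bins carry NaN in every row and
column so they cannot silently leak into downstream statistics. Symmetry is
enforced at construction to a 1e-9 relative tolerance.

## Matrix normalization

**KR balancing.** The scaling vector solves `x * (A x) = 1` (unmasked
submatrix), making the balanced matrix doubly stochastic — unmasked row
sums equal 1 within the convergence tolerance (default 1e-8, measured as
the max per-row residual). The solver is the inner-outer Newton iteration
with conjugate-gradient inner solves and the classic step-length
safeguards; non-convergence within the matrix-vector-product budget raises
`BalancingError` carrying the residual and iteration count. Bins whose raw
marginal falls below 1% of the median positive marginal are masked before
balancing; very sparse rows make the scaling ill-conditioned and such bins
are routinely discarded in practice. The 1% level is this package's choice.

**Cross-sample quantile normalization.** Samples are made comparable by
replacing, at every genomic separation `d`, each sample's diagonal values
with the rank-wise mean of the per-sample sorted values (average rank on
ties). This equalizes the per-distance value distribution across samples
while preserving within-sample rank order, and is idempotent. It is a
deliberately generic stand-in for distance-stratified between-sample
normalization; it does not model band-specific batch covariates. All
samples must share one bin mask — population comparisons are only
meaningful over bins usable in every sample.

**O/E.** `e(d)` is the arithmetic mean of unmasked entries at separation
`d`; entries in strata with `e(d) = 0` become NaN rather than infinities.
By construction the unmasked O/E mean at every distance is 1.

## Compartments

PC1 is computed on the Pearson correlation matrix of the O/E matrix
(columns mean-centered, leading left singular vector scores). The
eigenvector sign is arbitrary, so the profile is oriented to correlate
positively (Spearman) with GC content; when `|r| < 0.1` the GC signal is
considered uninformative and gene density breaks the tie. Chromosomes with
fewer than 10 unmasked bins are skipped with a warning. Undefined O/E
entries inside the unmasked block are replaced by the neutral value 1.0
before correlation.

The A-B index at 20 kb is the bounded contrast
`(S_A - S_B) / (S_A + S_B)` of a bin's summed O/E contact with A- versus
B-labelled 100-kb parent bins, restricted to cis pairs separated by at
least 100 kb so that distance-decay-dominated near-diagonal mass does not
swamp the signal. The index is antisymmetric under a global A/B label swap
and NaN when a bin has no qualifying contact mass.

Population frequency of A status uses only replicates with an assigned
status in the denominator. Class thresholds are strict (`high` iff
frequency > 0.70, `low` iff < 0.30) for compartments, but inclusive at the
top (`high` iff >= 0.70) for TAD boundaries — the two rules are
intentionally different and preserved as such.

Group comparison: a bin is a **switch** when both groups are >= 80%
consistent and their consensus statuses are opposite; a **variable** bin
keeps its status but moves its mean A-B index by more than 0.75 with a
BH-adjusted two-sided Welch t-test q < 0.05 across per-replicate index
values (Welch rather than pooled-variance, since replicate variances need
not match); same-status bins failing that test are **stable**; everything
else (opposite but inconsistent, undetermined status) is **unclassified**.

## Insulation and boundaries

The insulation window is a 260-kb square offset from the diagonal,
mean-aggregated over unmasked cells; scores are log2 ratios to the
chromosome mean of the raw window values, so `2^IS` averages to 1 over
defined bins. Bins within one window of a chromosome end are undefined.
The delta vector subtracts the mean insulation over the 200-kb right span
from the left span; boundaries sit at positive-to-negative zero crossings,
are retained when the flanking delta max-minus-min amplitude reaches 0.1,
and are placed exactly on the minimum-insulation bin of the crossing
(no placement margin). Domains shorter than the window cannot produce
separate minima, so boundary recall is only meaningful for planted
boundaries spaced beyond ~2 windows; the acceptance script plants
boundaries >= 600 kb apart for exactly this reason. On balanced matrices
the end-of-chromosome scaling inflates near-diagonal values and can
produce weak spurious minima near chromosome ends; the planted junction
remains the dominant minimum in all tested settings.

Non-redundant boundary aggregation averages insulation per genomic bin
across the replicates carrying a boundary there, then greedily emits the
remaining candidate with the lowest mean insulation (strongest
insulation minimum; leftmost coordinate on ties) and removes all
candidates within +/- 100 kb, until exhaustion. Emitted centers are
therefore pairwise separated by more than the radius, and the output is
independent of input order for distinct scores. Population frequency
counts the replicates with at least one boundary within +/- 100 kb of a
center.

Partition concordance treats the inter-boundary intervals as the domain
partition. Jaccard matches boundary positions greedily with a +/- 1 bin
tolerance (a package choice; exact matching is recovered with
`bin_size=0`). MoC follows the squared-overlap formula with the single
domain/single domain case defined as 1. VI uses the base-2 joint
bp-overlap distribution; base only rescales the metric.

## Loops and regulation

Loop retention: q < 0.01, both anchors overlapping at least one CTCF
motif, anchor-midpoint span in [30 kb, 2 Mb]. Merging ranks loops by
position, splits odd/even ranks, and joins cross-set loops whose
corresponding anchors overlap or lie within 5 kb (interval gap <= 5 kb)
into union-anchor loops, iterating on the result. Because union anchors
feed back into the next round, merging legitimately chains beyond the
pairwise adjacency of the original calls. The rank alternation is an
efficiency device: a terminal all-pairs sweep guarantees the fixed point
is reached regardless of how ties in the position sort fall. Merged loops
keep the smallest constituent q-value.

RPS sums `log10(l_n)` over a gene's retained enhancers. The logarithm is
undefined for `l_n <= 0` (observed at or below expected); such rows are
excluded and counted in the log, which matches the intent that only
over-represented interactions carry regulatory signal. A gene with no
retained enhancer scores 0, so non-positive scores exist and the
`multi`/`single`/`none` classes partition all genes. Differential RPS
requires both fold change > 1.5 (larger over smaller) and absolute
difference > 2; when either score is non-positive the ratio is
meaningless and the absolute-difference rule alone applies. Covariation
additionally requires a significant expression change (|log2FC| > 1,
FDR < 0.05) with the same sign as the RPS change.

Enhancer activity classes consume two pre-split peak sets (super vs
typical enhancer peaks from upstream ranking); precedence is
high > moderate > low on overlap. Expression detection uses > 0.5 TPM in
at least one sample for protein-coding genes and > 0.1 TPM for
lncRNA/TUCP.

## Conservation and SNP enrichment

The percentile score of a mapped contact is its mean-rank percentile among
all query-genome contacts at the same bin distance; strata with fewer than
20 background pairs are pooled with neighboring distances (trailing
undersized pools merge backwards), and queries at unseen distances use the
nearest stratum. The usage-conservation threshold is strict: PS must
exceed 85. Lifted enhancers with no computable stratum are reported
unclassifiable rather than silently dropped. SNP enrichment is the ratio
of class SNP density to genome-wide density and is invariant to common
scaling of all four counts.

## Synthetic data

The contact-map generator draws Poisson counts around
`lambda(i,j) = depth-scaled |i-j|^-alpha * exp(beta e_i e_j) *
tau^[same domain] * (1 + loop bumps)` with alpha = 1 (the standard Hi-C
scaling regime), beta = 0.6 and tau = 1.5 by default, and a depth of 1e6
expected contacts per 500-bin chromosome — enough that every test runs in
seconds while keeping per-pair counts Poisson-noisy. Loop bumps are 3x3
Gaussian multiplicative kernels. Population replicates flip each bin's
compartment with probability one minus the designed consistency, drop
each boundary with one minus its presence probability, and jitter kept
boundaries uniformly; this makes the frequency estimators exactly
binomial, which the tests exploit via exact 99% binomial intervals.

The regulatory generator plants per-gene enhancer sets with known `l_n`
(so RPS is exactly recoverable in the noise-free limit), expression
coupled log-linearly to planted RPS (so the multi > single > none
expression ordering is planted, not discovered), activity classes realized
as covering peak sets, and conservation classes realized through a
liftover table plus an evenly spaced percentile background in which
usage-conserved enhancers sit at the 95th percentile and
only-sequence-conserved at the 50th.

What passing these tests shows: the estimators and classifiers implement
their definitions correctly and recover designed population parameters at
the stated rates. What they do not show: robustness to real-data features
the generator omits — translocations and copy-number structure, mappability
gradients, distance-dependent batch effects between samples, fragment-level
biases, non-Poisson overdispersion, and cell-composition heterogeneity.

## Problem sizes

Default test and acceptance problem sizes — 500 x 100-kb bins (with the
matching 2500 x 20-kb map) for compartment recovery, 50 replicates for
population statistics, 1000/500 random instances for the
aggregation/merging oracle suites, 10^4 genes for the RPS fidelity check —
were chosen so the whole suite completes in well under a minute while
leaving the binomial coverage checks statistically stable.
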