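# Methods

This note documents the models, parameter choices and numerical decisions
behind hicdelta, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Data model

Contact matrices are symmetric and stored as the upper triangle of a
sparse matrix over a dense genome binning (0-based half-open coordinates;
HiC-Pro's 1-based bin ids are converted at the file boundary). Duplicate
(i, j) entries in a matrix file are treated as corruption and rejected
rather than summed. A per-bin boolean mask carries exclusions (low
coverage, masked translocation blocks) through every downstream operation.

## ICE balancing

Iterative correction assumes technical bias is multiplicative and
separable: W_raw(i,j) = b_i b_j W_true(i,j) with equal true coverage per
bin. Each iteration divides by the outer product of relative marginals.
Parameters: `max_iter` 200; `tol` 1e-5, interpreted as a bound on the
coefficient of variation (CV) of the unmasked marginals — the loop stops
when var(s)/mean(s)² < tol², giving marginals flat to ~1e-5 relative.
Bins with zero marginal, or below the 2% quantile of nonzero marginals
*and* below half the median (the second condition keeps an
already-balanced matrix untouched, making balancing idempotent), are
masked before iterating. Bias recovery is exact (log-correlation > 0.999)
when the data really is b_i b_j × a balanced matrix; on structured data
the recovered bias additionally absorbs genuine coverage structure, which
is the intended behavior of the method, not an error.

## Distance decay and expected values

The expected value E(d) is the mean over unmasked pairs at each bin
distance d, per chromosome; observed/expected divides by E(|i−j|) and is
0 where E is 0. For the decay-exponent (IDE) fits the per-distance means
are pooled across chromosomes with equal weight per distance (so pair
counts do not bias the fit), then grouped into log-spaced bins
(16/decade). Each log bin is summarized by the mean of log10(distance)
and the mean of log10(contact): an exact power law therefore stays
exactly linear after binning, and ordinary least squares per segment
((0.1–1], (1–10], (10–∞) Mb) recovers its exponent to machine precision.
Segments with fewer than three curve points report NaN. Note that under
the full generative model (TAD enrichment on) the short-range segment is
systematically steeper than the underlying decay exponent, because
within-TAD enrichment decays with distance across the segment; the
exponent-recovery benchmark therefore uses the pure-decay configuration.

## Compartments

PC1 is computed per chromosome from the symmetric eigendecomposition of
the Pearson correlation matrix of the O/E cis block over unmasked bins
(largest eigenvalue). The eigenvector sign is arbitrary, so it is
oriented to correlate non-negatively with a caller-supplied reference
activity track — gene density on real data, the generator's truth
activity track (condition-matched) on synthetic data. A condition-matched
reference matters: when switches concentrate on one chromosome, a
reference from the other condition can mis-orient that chromosome
wholesale. Chromosomes with fewer than 10 usable bins are set to NA.
Exact zeros of PC1 are NA. Switch fractions are reported both as
fractions of classified (non-NA) length and of total genome length.

## Insulation and TAD boundaries

The insulation score at bin i is the mean of the w×w square
(i−w…i−1)×(i+1…i+w) over unmasked pairs (w = 10 bins, a 500 kb square at
50 kb), normalized per chromosome as log2(score / chromosome mean).
Before boundary calling the track is smoothed with a 3-bin centered
moving average — the insulation-tool family does the same — because raw
Poisson wiggles otherwise generate spurious weak crossings. Boundaries
are minus-to-plus zero crossings of delta(i) = mean over (i+1…i+d) −
mean over (i−d…i−1) (d = 2), with strength = the delta swing across the
crossing (nearest local max after minus nearest local min before).
The default strength threshold is 0.5: at the benchmark depth
(10⁶ counts/chromosome) noise crossings score ≤ ~0.45 while genuine
boundaries at enrichment ≥ 2 score ≥ ~1.3, so 0.5 separates them
cleanly; all of w, d, smoothing and threshold are configuration options.
Window means skip isolated masked bins instead of propagating NaN, so a
boundary next to a masked bin is still callable.

Boundary sets are matched greedily, nearest first, one-to-one, within
±1 bin by default (one-bin jitter is below the method's localization
accuracy). TADs are the intervals between consecutive boundaries; a TAD
is altered if any condition-specific boundary of either condition touches
it (flank or interior — the interior case is boundary emergence splitting
a domain). Size comparisons use the two-sided rank-sum test with the
normal approximation and tie correction.

## Loops

"Specific" loops are determined by joint anchor matching: a loop is
shared only when a single partner loop matches both anchors, each within
a bin tolerance (default 0 bins at 10 kb — set uniqueness); matching is
one-to-one, greedy by total anchor distance. An `anchorwise` mode (each
anchor individually present somewhere in the other set) is provided for
the more permissive reading. Gene-to-anchor assignment uses ≥1 bp overlap
with half-open intervals.

## Translocation detection and double confirmation

Inter-chromosomal rearrangements appear as rectangular blocks of elevated
trans signal. Per chromosome pair, the background is the median of the
row means over unmasked bins (robust to the hotspot itself, and well
defined on sparse count matrices, where the median *nonzero entry* is
just 1). Candidate regions are connected components of the box-smoothed
block (filter size = `min_span`, default 10 bins) above
max(fold/2 × background, median + 6 robust sigma of the smoothed field);
component edges are refined at half-height on row/column profiles
restricted to the partner span (where the signal is ~fold × background,
so the half-height crossing localizes the edge to ±1 bin), and a
candidate survives only if its raw mean entry reaches the full fold
threshold (default 4×). Masked rows/columns are treated as unknown — they
are filled with background for detection and interpolated in refinement
profiles — so coverage gaps neither split one hotspot into two nor snap
edges to mask boundaries. Earlier profile-only change-point segmentation
was abandoned: a 20-bin block inside an 800-bin profile shifts the
profile mean by only ~20%, far below any sound split criterion.

Double confirmation is literal: an event is confirmed iff at least one of
its four span edges, widened by ±1 bin, contains the corresponding-
chromosome position of a WGS breakpoint whose chromosome pair matches
(either orientation). Confirmed blocks are removed from the matrices
(block-level masking; cis signal untouched) before all downstream stages.
Detection is specific to ICE-normalized input in the pipeline: on raw
matrices, blocks of jointly high-bias bins can mimic fold-4 hotspots.

## SV overlap

A feature (boundary interval or loop anchor) is "affected" by an SV type
if it overlaps any interval of that type by ≥1 bp. Reported fractions
follow the all-features vs altered-features display; the chi-square is
computed on the disjoint altered vs non-altered 2×2 table (Pearson, no
continuity correction, as everywhere in the package), since the nested
all-vs-altered pair is not a valid contingency partition.

## Expression integration

Genes take the switch class of their midpoint bin, TAD status "altered"
iff the midpoint lies in an altered TAD of either condition, and
loop-anchor status by ≥1 bp overlap with a specific-loop anchor (an
"any overlap" compartment mode exists as an option). Up/down ratios are
computed per group (stable = A2A∪B2B, A2B, B2A) with a 2×2 chi-square of
each altered group against stable; DEG/NDEG × altered/stable tables are
built per axis. Zero denominators are flagged (`infinite`/`undefined`)
rather than silently dropped. No multiple-testing correction is applied
across the handful of contingency tests; raw p-values are reported.
DE status defaults to adjusted p < 0.05 and |log2FC| ≥ 1 and is
recomputed from the table columns under the thresholds in effect.

## Synthetic data generator

The generator is the package's instrument for verifying structure
recovery. Expected cis counts are
μ(i,j) = A·max(d,1)^α · plaid(i,j) · tad(i,j) · loop(i,j) · b_i b_j with
d = |i−j| bins (the diagonal reuses the d = 1 value); trans counts are a
flat background times bias, plus planted translocation blocks at a
uniform fold over background (a uniform block, rather than decay from the
breakpoint — the simplification keeps the block's mean at the nominal
fold). All expected values are scaled so the matrix totals a target depth
and sampled as Poisson.

Defaults (the study conditions): three chromosomes of 40/35/25 Mb
(200 bins at 500 kb); α = −1.2; plaid strength k = 1.5 with alternating
A/B blocks of 2–6 Mb; activated switches covering ~16.6% of bins and
deactivated ~8.4% (activation ratio ≈ 2); TAD boundaries at ~600 kb
median spacing with within-TAD enrichment 3, compartment label-change
edges included as boundaries (plaid transitions coincide with domain
borders; otherwise the plaid itself would plant boundaries the truth
record does not know about); 25 loops/chromosome at 10 kb anchors,
3×3-bin Gaussian dots (σ = 1 bin) of fold 4, stamped only at resolutions
within 5× of the anchor width (a 10 kb focal enrichment dilutes away at
500 kb bins; stamping it there would create unphysical diagonal spikes);
per-bin bias log-uniform in [0.5, 2]; depth 3.5×10⁶ (≈10⁶ cis
counts/chromosome); trans background scaled with resolution so the trans
fraction (~8%) is a library property, not a binning artifact; one planted
1.2 Mb × 0.8 Mb translocation at fold 8. Tumor alterations: flipped
compartment blocks, 3 removed / 3 added / 2 moved boundaries, 8 removed /
8 added loops, plus the translocation. Counts are Poisson (no
overdispersion knob); biases are drawn independently per condition and
resolution.

The matched expression table places genes (10 kb, ≥2 kb apart, capped by
each region's capacity) into B2A / A2B / stable / altered-TAD /
specific-loop-anchor regions with log2FC ~ Normal(shift, 0.5); shifts
default to +1.5 / −1.5 / 0 / ±1.5 / ±1.5 (random sign for the
non-directional classes). P-values are a two-sided normal test of log2FC
at scale 0.35, BH-adjusted.

What passing the benchmarks shows: the pipeline recovers exactly the
structures the model plants, at desk scale, under Poisson noise and
multiplicative bias. What it does not show: robustness to overdispersed
counts, copy-number-driven coverage waves, unmappable regions,
centromeres, resolution-dependent loop visibility, or real-genome scale —
the published genome-wide numbers of a real tumor/normal comparison
require the original sequencing data and are structural analogues here,
not targets.

## Numerical conventions

Chi-square tests are Pearson without continuity correction; degenerate
tables (a zero margin) return statistic 0, p 1. Rank-sum tests use the
asymptotic normal approximation with tie correction. Chromosome order is
genome order, never lexicographic. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; equal seeds give
byte-identical outputs, including emitted files and the pipeline report.

## Problem sizes

The shipped configurations run the full pipeline in well under a minute
on one CPU: 100 Mb genome, matrices of 200 / 2000 / 2500 bins at
500 / 50 / 40 kb, ~800 genes, 20-replicate benchmarks for the stochastic
rates. These sizes were chosen so the whole analysis is interactively
reproducible; every threshold above is independent of them.
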