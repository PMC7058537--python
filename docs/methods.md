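# Methods

This note describes the models and procedures implemented in `tadsv`, their
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Contact-matrix model and normalization

A `ContactMatrix` is one chromosome of a symmetric, binned (default 25 kb)
intra-chromosomal contact map with a per-bin boolean mask. Masked bins
(unmappable or zero-coverage) carry NaN in their rows/columns — never a
silent zero — and every statistic averages over unmasked entries only.
Coordinates are 0-based half-open (BED dialect) throughout.

Two normalizations are provided. Knight–Ruiz application divides each entry
by the product of the two bins' precomputed scores; bins with missing or
non-positive scores become masked. Iterative correction (ICE) alternately
rescales rows/columns until the coefficient of variation of unmasked row
sums falls below `tol` (default 1e-5, max 200 iterations; non-convergence
warns rather than fails). The returned bias vector is normalized to mean 1
so the count scale is preserved, and satisfies
`balanced[i,j] = raw[i,j] / (b_i * b_j)` exactly.

## Insulation score and boundary calling

The TAD signal is a banded row sum: S(i) sums contacts from bin i to all
unmasked bins within 2 Mb (diagonal excluded, truncated at chromosome
ends), reported as log2(S(i) / local 2-Mb mean of S). The sentence-level
definition admits more than one reading; the banded-row-sum reading is
fixed here as normative (an alternative per-entry log-ratio is not
implemented). Both the TAD signal and the insulation score are invariant
under global rescaling of the matrix, by construction.

The insulation score I(i) is the mean contact in the square
`(i-s..i-1) x (i+1..i+s)` with `s` = 1 Mb / bin size = 40 bins, using only
unmasked entries; a square with fewer than 25% valid entries yields a
missing value, as do bins within `s` of a chromosome end. Scores are
log2-normalized to the chromosome mean of I (per-chromosome, not
genome-wide, normalization is adopted). The delta track is the mean
normalized score over the next `d` = 200 kb / bin = 8 bins minus the mean
over the previous 8; at an insulation minimum it crosses zero upward.

Boundary calling places a candidate at each upward zero crossing, on the
lower-insulation side of the crossing. Strength is the delta swing across
the crossing — the nearest *following* local maximum of delta minus the
nearest *preceding* local minimum. (With this delta sign convention the
preceding extremum is the minimum; the published caller's description pairs
the extrema the other way because its delta is the mirror image. The swing
magnitude is identical.) Candidates below the noise threshold `nt` = 0.1
are dropped; candidates within `bmoe` = 1 bin are merged keeping the
stronger, ties to the smaller coordinate. Each boundary is emitted as the
central bin ± 1 bin, i.e. a 75-kb interval, bin-aligned.

## Consensus boundaries

Boundary centers from all input sets are pooled per chromosome and grouped
greedily left-to-right, a new member joining the open group while its
center is within 50 kb of the previous member (chained adjacency — this
reproduces the intended grouping for jittered boundary stacks, which a
strict max-minus-min rule does not). A group with at least one member from
every set emits one consensus boundary: a 3-bin interval at the bin of the
median member center, strength the mean of member strengths.

## Shuffle nulls

All permutation tests share one scheme: a shuffled boundary set keeps the
per-chromosome count and widths and re-places boundaries uniformly on the
bin grid without overlap. Placement uses the exact bijection between
non-overlapping configurations and sorted distinct integers (sample
t_1 < … < t_n, set start_i = t_i + (i-1)(w-1)), so the null is uniform over
all valid configurations at any density. Each result records the observed
statistic, null mean and SD, z, a two-sided normal-approximation p from z,
and a one-sided upper-tail empirical p with add-one correction (minimum
1/(n_shuffles+1)). Both p values are reported because the published
procedure applies a t-test to a bootstrap distribution, whose intent is
ambiguous; the empirical p is the primary quantity.

A property of this null worth knowing: when the observed boundaries tile
the genome quasi-regularly (as real TADs do) and events are long enough to
host several boundaries, the uniform null allows boundary clustering that
the observed configuration forbids, making per-event spanning slightly
*more* likely under the observed configuration than under the null
(anti-conservative fold ≈ 1.3 at 2-Mb spacing with log-uniform 50 kb–2 Mb
events in the synthetic genome). Calibration experiments therefore draw the
"observed" boundary configuration from the shuffle distribution itself,
which makes the test exchangeable; applications to regularly spaced
boundary sets inherit the bias of the published scheme.

## BA-SVs, enrichment, recurrence

SVs are intra-chromosomal typed break-end pairs (DEL/DUP/INV/COMPLEX);
inter-chromosomal records are dropped at read time with a logged count, and
identical (sample, chrom, start, end, type) records are counted once.
Short-range means length strictly below 2 Mb. An SV is boundary-affecting
(BA) when `sv.start <= b.start and sv.end >= b.end` — containment inclusive
at both ends (the boundary's whole 75-kb length is inside the footprint).
Enrichment per type compares the observed BA count with counts under
shuffled boundaries; the fold is observed / null mean. The
germline-vs-somatic comparison filters both deletion sets to lengths in
[75 kb, 250 kb] (closed interval) before computing BA rates. Recurrence
builds a binary sample × boundary matrix per cohort; a boundary is
recurrent when affected in strictly more than 10% of samples.
Loop-disrupting SVs overlap exactly one of the two CTCF anchors of an
insulated neighborhood.

## Domain classes

Domains are the gaps between adjacent consensus boundaries (boundary
intervals and chromosome-terminal segments excluded), so domains plus
boundaries tile each chromosome's interior. Each domain's 15-state coverage
vector (state bp / domain length) is clustered with k-means (k = 5, 50
restarts, fixed seed). Clusters are named by ranking centroids on
active-state mass minus quiescent/heterochromatin mass into
heterochromatin < low < repressed < low-active < active; which states count
as active or quiescent comes from a configurable state dictionary, not
hard-coded (default: the seven promoter/transcription/enhancer states of a
Roadmap-style 15-state model are active; the heterochromatin and quiescent
states are quiescent). Hierarchical clustering of state rows in the
original presentation is display-only and omitted.

For flanking-domain pairs, each break-end is assigned the domain containing
it, else the nearest domain by center (ties to the left — relevant for
break-ends inside boundary intervals). The same-class diagonal count is
tested against shuffled boundaries with the domain partition re-derived;
since the shuffle carries no chromatin-state information, each null domain
inherits the class of the original domain nearest its center. Gene-level
summaries assign each gene to the domain containing its start (a TSS-based
alternative would differ only for genes straddling a boundary).

## Expression fold changes

fc = expression of the flank gene in the SV carrier / mean over the other
samples of the same cohort. Flank genes are the nearest genes wholly
outside the footprint on each side; genes overlapping a break-end are
excluded; equidistant ties go to the smaller coordinate. Filters: cohort
*mean* expression < 0.1 FPKM (cohort-level rather than per-sample, so the
denominator is stable; RPKM/FPKM are treated as interchangeable units),
carrier copy number > 4 (missing CN entries default to 2 with a warning),
distance > 1 Mb. All three cut-offs retain the boundary value. The filters
are independent predicates, so application order cannot change the retained
set. Group comparisons use a one-tailed Mann–Whitney U (exact null for
groups up to 20 without ties, otherwise the tie-corrected normal
approximation). The more-than-twofold fraction counts records with fc > 2
or fc < 0.5, strict on both sides, per flank-gene record.

## Fusion statistics

The expected contact at separation d is the empirical mean over unmasked
pairs at that distance (no spline smoothing); separations supported by
fewer than 10 pairs are pooled with neighboring distances. The per-SV
scaling factor is the mean observed contact over all unmasked pairs in the
SV's window divided by the distance-matched expected mean; the window is
the SV footprint extended symmetrically to a 2-Mb total span, truncated per
side at the nearest break-end of another SV and at chromosome ends. Windows
below 4 bins, and scaling factors below 0.1 (likely false-positive SV
calls), are excluded. The scaling of the expected model against itself is
exactly 1 on any window.

Cross-SV bin pairs (one bin on each side of the footprint) are intra-TAD/SV
when both bins lie between a break-end and the nearest boundary beyond it,
inter-TAD/SV when they reach past either boundary; distances are measured
in reference coordinates. If no boundary lies within the window on a side,
that side contributes only inter labels. The fusion statistic is the mean
observed/expected ratio of intra pairs over that of inter pairs.
Observed/expected normalization is applied to both classes. On an
*unrearranged* map with periodic TADs this null ratio sits slightly below 1
(≈ 0.85 in the synthetic genome) rather than exactly at 1: intra pairs
occupy shorter distances, where the genome-mean expectation carries more
within-TAD enrichment. The fused-deletion signal (ratio ≥ 1.5) is well
separated from this null. Break-end aggregate analysis averages the
(2h+1)² observed/expected fold submatrix centered on each SV's
(start-bin, end-bin) pixel; SVs with masked or out-of-range center pixels
are skipped and counted.

## Synthetic data

Contact maps follow `expected(i,j) = depth · max(d,1)^(−alpha) ·
(1 + tau·[same TAD])` with independent Poisson counts (alpha = 1, tau = 1,
depth = 60 by default — depth 60 gives ≳ 100 mean first-off-diagonal counts,
comfortably above the 50 needed for reliable boundary recovery).
Overdispersion is not modeled; Poisson noise is adequate for recovery and
calibration tests but understates the variance of real Hi-C. The default
genome is 2 × 20 Mb at 25-kb bins with boundaries every 2 Mb; cell-type
sets share these and add private boundaries kept ≥ 600 kb from any other so
that adjacent insulation minima remain resolvable by a 1-Mb square.
Rearranged maps are simulated on the derived chromosome (deletion removes
bins, tandem duplication repeats the segment, inversion reverses it; nested
or overlapping SVs are rejected), with TADs re-derived from surviving
boundary bins, then projected back to reference bins summing over
duplicated copies; fully deleted bins are masked. Chromothripsis-scale maps
are emulated as many disjoint SVs on one chromosome.

SV catalogs draw per-sample event counts from a Poisson, types from a
configurable mixture, lengths log-uniform in [50 kb, 2 Mb), placement
uniform; an enrichment knob forces a per-type fraction of events to span
(or, if negative, avoid) a boundary, with ground-truth BA flags recorded.
State tracks draw each domain's composition from a Dirichlet around its
class archetype (concentration 60); heterochromatin/low domains become
constitutive LADs. Expression is log-normal around ordered per-class means
(0.5 / 1 / 2 / 8 / 32 RPKM-like) with CV 0.3; planted effects multiply
target genes in affected samples; copy number is 2 except a 5% aberrant
fraction. All generators are pure functions of (spec, seed): reruns are
bit-identical.

What passing tests on these synthetics do *not* show: robustness to
overdispersed counts, mappability artifacts, copy-number-driven coverage
waves, non-uniform SV background rates along the genome, or TAD-size
heterogeneity beyond the planted layouts.

## Problem sizes and numerical choices

Tests and the acceptance script run single 20-Mb chromosomes (800 bins),
cohorts of 12–150 samples and 200-replicate calibrations with 300–1,000
shuffles per test; these sizes give Monte-Carlo error comfortably inside
every asserted band while keeping the whole suite around ten seconds. The
fused-TAD scenario uses 0.8-Mb boundary spacing so that flanking boundaries
fall inside the 2-Mb fusion window (with 2-Mb TADs the nearest boundary
lies outside the window and every cross-SV pair is inter by the stated
rule); the duplication-scaling scenario uses a 2-Mb duplication so the
window coincides with the duplicated footprint, where the scaling factor
estimates the copy ratio directly. K-means uses 50 restarts with a fixed
seed stream; all pipeline randomness flows from one root seed through named
SHA-256-derived substreams per stage, making full runs byte-identical.

## Known limitations

- Only intra-chromosomal maps and SVs; translocations are out of scope.
- The rearranged-map generator forbids nested/overlapping SVs.
- COMPLEX events are consumed as pre-typed single footprints; junction
  clustering is upstream.
- The shuffle null ignores mappability unless a mask is supplied, and is
  anti-conservative for regularly tiled boundary sets (see above).
- The insulation caller assumes boundaries at least ~600 kb apart are the
  norm; closer minima may merge or shadow each other at the default 1-Mb
  square.
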