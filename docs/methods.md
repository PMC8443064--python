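# Methods

This note documents the models, conventions and numerical choices behind
`epm`, and what the synthetic-data experiments do and do not demonstrate.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open (BED convention); any
1-based dialect must be converted at the reader boundary. Overlap means
sharing at least 1 bp under half-open semantics. Distance is the gap in bp
between nearest ends, 0 for overlapping *or touching* intervals, and
undefined across chromosomes — note that touching intervals (end == start)
have distance 0 without overlapping, which is exactly the "contiguity"
notion the merging and ambiguity rules rely on. Genome bins tile each
chromosome left to right; the terminal bin of a chromosome whose length is
not a multiple of the bin width is kept as a shorter partial bin
(identifiable by its length), which is harmless downstream because all
signal is averaged per bp.

## Chromatin-state post-processing

A segmentation track must be sorted and non-overlapping per chromosome.
Transition counts are taken between consecutive segments within a
chromosome, left to right; chromosome boundaries contribute nothing. By
default the track is coalesced first (touching same-state segments merged),
so transitions are between distinct states; a flag exposes the raw-track
variant because published figures do not always state which was used.
Expected counts use the standard contingency expectation
`E(x,y) = out(x)·in(y)/N` — the natural formalization of "expected by
chance" — and enrichment is O/E with undefined cells reported as missing.

Group merging maps each state to one of {active, intermediate, poised,
repressed_only, unmarked}; the default scheme is 1–4 → active,
5 → intermediate (H3K4me1-only), 6–7 → poised (H3K27me3 together with
H3K4me1/H3K4me3), 8 → repressed_only (H3K27me3 tail-ends), 9 → unmarked.
Maximal runs of *touching* same-group segments become one candidate region.
"Contiguous" means a 0-bp gap; any gap or any non-active/non-poised segment
breaks a run. The minimum length (default 600 bp) is applied after merging
and before the ambiguity rule, which then discards both members of any
surviving active/poised touching pair. This ordering matters: a 500-bp
active run touching a poised region is removed by the length filter first
and does not doom its neighbour.

## Classification and association

The promoter window around a TSS at position t is `[t − w, t + w + 1)`
(2w + 1 bp, default w = 500). The ±w phrasing in the field does not fix
whether both boundary bases are included; the symmetric 1001-bp window is
the default and w is a parameter. Promoter precedence over enhancer status
is absolute, and enhancers are *not* filtered on histone content (an
enhancer carrying H3K4me3 stays an enhancer). Distal enhancers are those
strictly more than 5 kb from every TSS.

Contact-based association requires the enhancer and promoter classes to
match (AE–AP, PE–BP) and each region to overlap one anchor of the same
significant contact; both anchor orderings are tried and rows are
deduplicated on (enhancer, promoter, gene). Anchors are used exactly as
given (typically 5-kb caller bins) with no extension or merging. The
distance variant links same-class pairs with gap strictly below 1 Mb (the
approximate size of a topologically associating domain).

The enrichment test is a one-sided (greater) exact binomial on
deduplicated (contact, enhancer, promoter) triples: n counts triples where
an enhancer of the tested class touches one anchor and any promoter the
other, k counts those whose promoter is the state-matched target. The null
probability p0 is, by default, the marginal frequency of the target
promoter class among promoter-side anchor instances pooled over *both*
enhancer classes — a natural chance level when no external estimate exists
— but it is an explicit argument everywhere so alternative nulls can be
supplied. The tail probability is computed with the regularized incomplete
beta function (`scipy.stats.binom.sf`), which agrees with exact integer
tail sums to well below 1e-10 over the n ≤ 1000 range used here.

## Signal quantification

The signal of a sample at a region is
`1e6 · reads_overlapping / library_size / region_length` — reads per
million, averaged per bp. A read counts toward every region it overlaps by
≥ 1 bp (a read straddling two regions counts in both); a midpoint
assignment mode is available (`count_mode="midpoint"`) because counting
tools differ on this rule and it is rarely documented. Precomputed
per-bin/per-region values can be supplied directly, bypassing counting.

## Cyclic MA-LOESS normalization

For a sample pair, M = log₂x₁ − log₂x₂ and A is the average log₂ intensity.
A is the mean of logs by default, matching the microarray implementation
this scheme generalizes; the "log of the mean" reading is available behind
`a_mode="log_mean"`. Rows containing a zero in any sample are discarded
before fitting, because a zero cannot be distinguished between dropout and
true absence and the log transform is undefined there.

Each round, for every unordered sample pair, a robust degree-1 local
regression of M on A (span 2/3, three robustness iterations — the
conventional defaults for this smoother) is fitted on a seeded subset of at
most 5000 rows and evaluated on a fixed 256-point A-grid. Half the fitted
trend is charged against each sample of the pair; a sample's round
correction is the average over the J − 1 pairs it joins. Dividing by J − 1
makes a constant two-sample bias correct exactly in one round and keeps
the corrections balanced (Σ_s c_s(A) = 0 at every grid point), so each
row's average log intensity — and hence its A — is invariant across rounds.
That invariance is what lets the cumulative per-sample curves, stored as
piecewise-linear interpolants with constant extrapolation, reproduce the
iterative fit when re-applied and transfer to new tables (fit on
genome-wide bins, apply to regulatory regions or expression tables).
Iteration stops when the largest per-sample mean absolute applied
correction drops below 0.01 log₂ units or after 3 rounds; for J > 2
samples a constant bias shrinks by a factor ≥ 4 per round, so 3 rounds
leave residuals well under the tolerance.

The method assumes most rows are unchanged between samples. It removes
global and smooth intensity-dependent biases; it cannot distinguish a
genuine global abundance shift from a technical one (that requires
spike-ins), and a planted minority trend is shrunk slightly but its sign
survives — which is what the housekeeping/bivalent validation checks.

## Expression models

The response is y = log₂(FPKM + 0.1) and predictors are
x_j = log₂(signal_j + 0.1); the 0.1 pseudocount keeps zero FPKM/signal
finite at y = log₂0.1 ≈ −3.32. Fits are ordinary least squares with
intercept; rank-deficient designs raise an error naming the collinear
predictors, and exactly interpolating fits report t as an infinite flag
rather than a number (importance shares are then computed over finite
entries). Importance is |t_j| and the share normalizes over predictors.
Mark-exclusion models (e.g. dropping H3K27me3) are configuration, not
separate code paths.

For enhancer models a gene enters once per associated enhancer, so its
measured expression is duplicated; duplicating a row k times is exactly
weighted least squares with weight k (asserted against a WLS oracle in the
tests). Train/test splits and cross-validation folds operate at the gene
level by default so duplicated rows never straddle a split — row-level
splitting would leak identical y values — with a row-level mode retained
for fidelity experiments. Performance is the Pearson correlation between
predicted and measured y over rows (duplicated genes contribute one term
per row); a gene-aggregated mode is deliberately not the default.
Randomized controls shuffle expression values over all genes before
dataset assembly. Cross-context evaluation fits on all of one context's
rows and scores on every other context's full dataset; paired t-tests
compare model and random-model performance paired by evaluation set, with
the conventional star thresholds (< 0.0001, 0.001, 0.01, 0.05).

## Synthetic data: what it emulates

The generators are pure functions of their parameters and seed.

* **Segmentation**: a Markov chain over 9 states with zero-diagonal
  transition probabilities enriched within the active (1–4) and poised
  (6–7) blocks and the unmarked state as the common spacer; segment
  lengths are geometric multiples of 200 bp (mean 400 bp). A second
  constructor builds a tiling segmentation from a list of candidate
  regions so the merge step recovers them exactly — used for end-to-end
  recovery tests.
* **Regions and contacts**: AP/BP/AE/PE regions (defaults 40/25/45/30 per
  small genome, 1 kb each) on a 20-kb slot grid so every 5-kb anchor
  covers exactly one region; TSSs sit inside promoters, p300 peaks inside
  enhancers, decoy candidates carry neither. Each contact picks a poised
  enhancer with probability 0.44 and its promoter side hits the
  state-matched class with probability q = 0.29 for PEs and 0.80 for AEs,
  making the pooled bivalent-promoter marginal ≈ 0.24 — the observed and
  chance contact probabilities reported for this system. Only matched
  draws enter the ground-truth association table.
* **Signal and expression**: per gene a latent 10-mark profile is drawn
  from a multivariate normal (mean 2, unit variances, optional
  anticorrelated pairs such as H3K27ac/H3K27me3 at ρ = −0.9, reflecting
  their chemical exclusivity); housekeeping genes (30%) reuse it across
  contexts, background genes add an independent per-context deviation, and
  bivalent-like genes (17%, matching the bivalent fraction of
  protein-coding genes in this system) carry, for the half of them that
  activate, a planted monotone trend along the context order in the
  activation direction (gaining H3K27ac/H3K4me3/H3K36me3, losing
  H3K27me3). Expression follows y = β₀ + xᵀβ + N(0, σ) with FPKM =
  max(2^y − 0.1, 0); the default β makes H3K27me3 the dominant (negative)
  coefficient. When σ is unset it is calibrated per context so the
  theoretical evaluation correlation √(Var(xβ)/(Var(xβ)+σ²)) equals
  r\* = 0.8, the scale at which promoter models operate in this field.
* **Biases and trajectories**: multi-sample tables multiply a base
  intensity by 2^{g_s(A)} for smooth bounded g (sinusoidal in rescaled A,
  amplitude ≤ 1) plus log-normal noise; expression trajectories combine
  stable housekeeping/background genes (per-gene log-normal baselines,
  noise sd 0.2), activated bivalent genes (slopes 0.5–1.5 log₂ per step
  from a repressed baseline), and a global per-sample bias spanning ±0.5
  log₂ units.
* **Reads**: an optional Poisson read-level mode inverts the
  quantification formula (expected count = value·length·library/1e6) and
  places reads uniformly within regions, to exercise the counting path.

What passing tests show: the implementation recovers planted structure —
region classes and associations exactly, coefficients within OLS
confidence bounds, contact preferences at the exact test's nominal error
rates, bias curves to the stated tolerances. What they do not show:
robustness to features of real data the generators omit — mappability and
GC artefacts, peak-shape diversity, copy-number variation, fragment-length
effects, TAD structure in contacts, or count overdispersion beyond
Poisson. Conclusions about real datasets require the real inputs.

## Problem sizes

Default experiment sizes were chosen so the whole suite exercises every
claim at statistically meaningful scale while remaining a desk-scale
computation: 2000 genes × 10 marks for model experiments (sampling sd of r
≈ 0.01 at that n), 500 contacts for enrichment power, 1000–3000 rows for
normalization, and a 3 × 1 Mb genome for region planting. Where an
assertion is a per-seed bound (e.g. |r| of a null control), the evaluated
sample size is chosen so the bound sits several sampling standard
deviations from the expected value; the test docstrings state the
reasoning.
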