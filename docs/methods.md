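# Methods

## Model

Reads at a CpG are conditionally binomial: `k ~ Binomial(n, p)` with `p` the
true methylation ratio.  A conjugate `Beta(α₀, β₀)` prior gives the
posterior `Beta(k + α₀, n − k + β₀)`.  The prior is shared genome-wide and
estimated per condition by maximizing the marginal Beta-Binomial
log-likelihood Σ log BB(k | n, α, β); since the marginal pmf depends only on
(n, k), identical observations are aggregated first, which makes the
estimation cost independent of genome size.  Optimization is L-BFGS-B on
(log α, log β) with box bounds [1e−3, 1e4], gradient tolerance 1e−8 and
multi-starts at (0.5, 0.5), (1, 1) and a method-of-moments point; it is
deterministic.  Degenerate inputs (zero biological variance) drive the fit
to a box bound; the estimate is returned with a warning.  Fewer than 100
informative sites triggers a fallback to `Beta(0.5, 0.5)` (weakly bimodal,
matching the empirical all-or-nothing shape of genomic methylation) with a
warning.  Zero-read sites are excluded from estimation and logged.

With N ≥ 2 biological replicates, the condition's ratio distribution
`Beta(α_i, β_i)` is fit by maximizing

    Σ_j log BB(k_ij | n_ij, α, β)  −  (w/2)·[(log α − log α₀)² + (log β − log β₀)²],

a Beta-Binomial likelihood with an independent log-normal penalty (unit
log-variance) centred at the genome-wide prior.  The penalty regularizes the
weakly identified N = 2 problem: without it, perfectly concordant replicates
drive α + β to the box bound (a near-delta density), and the fit is
undefined in direction.  The default weight is w = 0.25.  The weight was set
from the canonical qualitative behaviors the fit must show: discordant
replicates (0/14 and 14/14) must yield α, β < 1 (bimodal), concordant
replicates α, β > 1 with a third concordant replicate tightening the fit —
all of which hold for any w in [0.02, 1] — while two concordant replicates
should concentrate to roughly (not beyond) the precision of the pooled
conjugate posterior.  At w = 1 the penalty dominates an N = 2 likelihood
(counts 3/30 and 4/30 fit to Beta(0.8, 2.6), erasing a clear low-vs-high
contrast); at w ≤ 0.02 concordant fits become implausibly confident.

## Difference densities and CDIF

Beta densities are tabulated on [0, 1] as exact per-cell masses (differences
of the regularized incomplete beta function at the cell edges; G = 512 cells
by default), so endpoint singularities for shapes < 1 carry their exact
mass.  The density of `t = p₁ − p₂` is the discrete cross-correlation of the
two mass vectors (2G − 1 cells on [−1, 1]); a second cross-correlation gives
`x = t − t′` on [−2, 2] for differential 5hmC.  Direct summation is used
(O(G²), ~0.2 ms at G = 512); grids of unequal resolution are re-binned to
the coarser one by CDF interpolation.

Credible intervals use the equal-tail ("proportional area") condition by
default — quantiles at (1 ± level)/2 with linear interpolation inside cells
— because it is unique and stable even for the occasionally bimodal
replicate-fitted densities.  A minimal-length criterion is available; for
multimodal densities it returns the shortest single interval and logs a
warning; ties across flat stretches resolve to the leftmost minimal
interval.  CDIF is the signed distance from 0 to the interval.  The
similarity p-value is the two-sided tail-mass statistic
`p = 2·min(P(t ≤ 0), P(t ≥ 0))`, clipped to (0, 1]; its exact form is a
package choice.  CDIF at G = 512 differs from G = 2048 by well under 2/512
on random inputs.  Per-table results are memoized on
(n₁, k₁, n₂, k₂, priors, level, grid); at fixed depth d a genome run
touches at most (d+1)² distinct tables, which is the dominant cost saver.
Replicate fits are likewise memoized on the order-independent count tuple.

## Calling, FDR, regions

Per site, `call_dmcs` reports the pooled nominal difference, CDIF (replicate
aware when N ≥ 2), the similarity p-value and a two-sided Fisher exact p on
pooled counts.  The Fisher p sums hypergeometric probabilities of all tables
(fixed margins) whose probability is at most the observed one, with relative
tolerance 1e−7; zero-read sites get p = 1.  Sites below `min_depth`
(default 1: report everything) are emitted flagged, never dropped.

Permutation FDR shuffles replicate column labels across conditions,
recomputes |CDIF| for each relabeling, and estimates
FDR(θ) = mean null count ≥ θ / observed count ≥ θ, clipped to [0, 1] and
monotonized (non-increasing in θ).  The identity assignment and — when group
sizes are equal — its complement are excluded from the null: a full condition
swap reproduces the observed |CDIF| distribution exactly (the statistic is
symmetric) and would floor the FDR at 1/n_permutations even for perfect
signal.  With one replicate per condition no genuine relabeling exists and
the function directs the caller to Benjamini–Hochberg on the similarity
p-values.

DMC→DMR merging is distance-based by default: consecutive significant DMCs
(CDIF ≠ 0, same sign, optional FDR mask) merge while the inter-CpG gap is
≤ `max_gap` bp; regions with fewer than `min_cpgs` members are dropped;
regions never span chromosomes; coordinates are 0-based half-open with the
end at the last C + 1.  The alternative HMM merge decodes a fixed 3-state
(hypo/background/hyper) Gaussian HMM over the signed CDIF track per
chromosome — self-transition 0.9, method-of-moments emission means, common
emission scale clamped to [0.02, 0.2] — with Viterbi (via hmmlearn), then
applies the same filters.  The HMM is deliberately untrained: a fixed,
reproducible topology was preferred over fitting choices that cannot be
validated; the distance merge is the default for the same reason.

## Synthetic data

`simulate_two_sample` generates the two-sample benchmark: true negatives
share a ratio drawn from the bimodal mixture
`0.55·Beta(0.5, 8) + 0.45·Beta(8, 0.5)` (configurable; the mixture mimics
the all-or-nothing shape of real methylomes but its exact parameters are a
free choice), true positives draw uniform ratios from [0, 0.25] and
[0.75, 1] with the side randomized per site, every ratio is perturbed by an
independent uniform ±0.05 per sample (bisulfite-conversion error) and
clipped to [0, 1], and counts are binomial at integer depths uniform on
[depth_lo, depth_hi], independent per sample and replicate.  Defaults:
10% true positives, depths 5–50.  All randomness flows through one
`numpy` Generator seeded explicitly; runs are bit-reproducible.

What the generator does *not* emulate: spatial correlation of methylation
along the chromosome, per-read error structure and mapping bias, copy-number
depth distortion, and condition-specific prior shapes.  Passing benchmarks
here therefore demonstrate the statistical engine under idealized sampling,
not end-to-end performance on real libraries.

`evaluate_at_fdr` ranks sites by score, restricts to thresholds at distinct
score boundaries, picks the largest discovery set whose empirical FDR
(against ground truth) stays at or below the target, and returns
true-positive recall.  `downsample_depth` thins totals binomially and
methylated counts hypergeometrically, preserving the expected ratio.

`min_coverage_to_detect` computes, by exact enumeration over the joint
(RRBS, oxBS) count distribution (binomial pmfs pruned below 1e−12), the
power of detecting a 5hmC fraction, and returns the smallest coverage n
reaching the power target (default 0.95 at credible level 0.95).  Detection
means the 95% credible interval of the RRBS−oxBS difference excludes zero
(CDIF route; thresholds in k are located by bisection, valid because
detection is monotone in the RRBS count at fixed oxBS count) or two-sided
Fisher p < 0.05 (FETP route; hypergeometric enumeration windowed to ±12 sd,
with the excluded < 1e−12 tail mass folded in conservatively).  The n-search
brackets geometrically, bisects, then walks down across discreteness
plateaus; power is assumed non-decreasing in n, which held at every probed
configuration.  The "detect" criterion itself (power 0.95 at level 0.95) is
a package inference — the published coverage curves never state one — and
both the level and the power target are parameters.

## Problem sizes and defaults

Benchmark runs use 50,000 CpGs (the published experiment simulated
1,000,000); the measured quantities are proportions, so the smaller size
changes only Monte-Carlo error (±1–2% at these sizes).  Grid size 512,
credible level 0.95, equal-tail intervals, replicate penalty weight 0.25,
coverage search cap 2000 (4000 in the acceptance script, so the 50%-5mC
requirements resolve to actual minima rather than a censored bound).

## Known limitations

- The CDIF→Fisher significance guarantee ("a CDIF above min(1/n₁, 1/n₂)
  implies Fisher p < 0.05") is approximate: with uniform priors about 0.4%
  of random count quadruples violate it, all with highly unbalanced depths
  and p just above 0.05.  Empirically the guarantee holds with the coarser
  resolution max(1/n₁, 1/n₂).
- With a strongly bimodal empirical-Bayes prior, all-or-nothing count
  tables (e.g. 4/10 vs 0/10) rank above some mixed tables of equal nominal
  difference; depending on the true-negative ratio distribution this can
  cost sensitivity at intermediate depths relative to a flat prior.  The
  prior mode is selectable per run (`eb`, `jeffreys`, `uniform`).
- The minimal-coverage numbers are exact for their stated criterion but
  sensitive to it; a different power target or one-sided level shifts them
  substantially (see parameters above).
- Sites are treated independently throughout; no smoothing or spatial prior.
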