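"""Synthetic BS-seq data and power/benchmark harnesses.

The two-sample generator emulates the standard DMC benchmark: true-negative
CpGs share methylation ratios drawn from a bimodal genome-like mixture (most
CpGs fully methylated or fully unmethylated); true-positive CpGs get a low
ratio in [0, 0.25] in one sample and a high ratio in [0.75, 1] in the other
(side randomized per site); every ratio is then perturbed by a uniform
+/-0.05 fluctuation emulating bisulfite-conversion error, and read counts are
drawn binomially at per-site depths uniform over a configurable fold range.

The evaluation harnesses measure sensitivity at a fixed realized FDR against
ground truth, and compute the minimum sequencing coverage at which a small
5hmC fraction is detectable from paired RRBS/oxBS assays, by exact
enumeration of the joint count distribution (no sampling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binom, hypergeom

from .core_posterior import BetaParams, MethCount, ReplicateSet
from .diff_inference import DEFAULT_GRID, DEFAULT_LEVEL, difference_summary
from .dm_calling import CpGSite

__all__ = [
    "SimulatedSite",
    "TN_MIXTURE",
    "simulate_two_sample",
    "evaluate_at_fdr",
    "min_coverage_to_detect",
    "downsample_depth",
]

#: True-negative ratio mixture: (weight of unmethylated component,
#: Beta(a, b) of the unmethylated mode); the methylated mode mirrors it.
TN_MIXTURE = (0.55, 0.5, 8.0)


@dataclass(frozen=True)
class SimulatedSite:
    """Ground truth and sampled observation for one simulated CpG."""

    true_ratio_1: float
    true_ratio_2: float
    is_true_positive: bool
    observed: CpGSite


def _sample_tn_ratios(rng: np.random.Generator, n: int, mixture=TN_MIXTURE) -> np.ndarray:
    w, a, b = mixture
    low = rng.random(n) < w
    r = np.empty(n)
    r[low] = rng.beta(a, b, size=int(low.sum()))
    r[~low] = rng.beta(b, a, size=int((~low).sum()))
    return r


def simulate_two_sample(
    n_sites: int,
    tp_fraction: float = 0.1,
    depth_lo: int = 5,
    depth_hi: int = 50,
    fluctuation: float = 0.05,
    seed: int = 0,
    n_replicates: int = 1,
    mixture=TN_MIXTURE,
) -> list[SimulatedSite]:
    """Simulate a two-sample DMC benchmark with known ground truth.

    Exactly ``round(n_sites * tp_fraction)`` sites are true positives.  True
    negatives share a ratio (drawn from the bimodal mixture) between samples
    before the per-sample fluctuation, so their nominal differences stay
    within +/- 2 * ``fluctuation`` of zero.  Depths are integers uniform on
    [depth_lo, depth_hi], independent per sample and replicate.
    Deterministic (bit-reproducible) for a fixed seed.
    """
    if not 0.0 <= tp_fraction <= 1.0:
        raise ValueError("tp_fraction must be in [0, 1]")
    if not 1 <= depth_lo <= depth_hi:
        raise ValueError("need 1 <= depth_lo <= depth_hi")
    rng = np.random.default_rng(seed)
    n_tp = int(round(n_sites * tp_fraction))
    is_tp = np.zeros(n_sites, dtype=bool)
    is_tp[rng.permutation(n_sites)[:n_tp]] = True

    r1 = np.empty(n_sites)
    r2 = np.empty(n_sites)
    tn = _sample_tn_ratios(rng, n_sites - n_tp, mixture)
    r1[~is_tp] = tn
    r2[~is_tp] = tn
    low = rng.uniform(0.0, 0.25, size=n_tp)
    high = rng.uniform(0.75, 1.0, size=n_tp)
    side = rng.random(n_tp) < 0.5
    r1[is_tp] = np.where(side, low, high)
    r2[is_tp] = np.where(side, high, low)

    r1 = np.clip(r1 + rng.uniform(-fluctuation, fluctuation, n_sites), 0.0, 1.0)
    r2 = np.clip(r2 + rng.uniform(-fluctuation, fluctuation, n_sites), 0.0, 1.0)

    sites: list[SimulatedSite] = []
    for i in range(n_sites):
        reps = []
        for r in (r1[i], r2[i]):
            counts = []
            for _ in range(n_replicates):
                d = int(rng.integers(depth_lo, depth_hi + 1))
                counts.append(MethCount(d, int(rng.binomial(d, r))))
            reps.append(ReplicateSet(tuple(counts)))
        obs = CpGSite(chrom="sim", pos=2 * i, cond1=reps[0], cond2=reps[1])
        sites.append(SimulatedSite(float(r1[i]), float(r2[i]), bool(is_tp[i]), obs))
    return sites


def evaluate_at_fdr(
    sim: Sequence[SimulatedSite],
    scores: Sequence[float],
    fdr_target: float = 0.05,
) -> float:
    """Sensitivity (true-positive recall) at a realized FDR against ground truth.

    Sites are ranked by score (higher = more significant); among thresholds
    at distinct score boundaries, the largest discovery set with empirical
    FDR <= ``fdr_target`` is selected and the fraction of true positives it
    recovers is returned.  Returns 0 when no threshold qualifies.
    """
    truth = np.array([s.is_true_positive for s in sim], dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != truth.shape:
        raise ValueError("need exactly one score per site")
    n_tp_total = int(truth.sum())
    if n_tp_total == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    tp_cum = np.cumsum(truth[order])
    k = np.arange(1, scores.size + 1)
    # only thresholds at distinct score boundaries are admissible
    boundary = np.ones(scores.size, dtype=bool)
    boundary[:-1] = s_sorted[:-1] != s_sorted[1:]
    fdr = (k - tp_cum) / k
    ok = boundary & (fdr <= fdr_target)
    if not ok.any():
        return 0.0
    k_star = int(np.nonzero(ok)[0].max())
    return float(tp_cum[k_star] / n_tp_total)


def _binom_support(n: int, p: float, prune: float) -> tuple[np.ndarray, np.ndarray]:
    ks = np.arange(n + 1)
    pmf = binom.pmf(ks, n, p)
    keep = pmf > prune
    return ks[keep], pmf[keep]


def _cdif_detects(n: int, k1: int, k2: int, prior: BetaParams,
                  level: float, grid_points: int) -> float:
    c = difference_summary(
        MethCount(n, k1), MethCount(n, k2), prior, level, grid_points
    ).cdif
    return c


def _cdif_power(n: int, p1: float, p2: float, prior: BetaParams,
                level: float, grid_points: int, prune: float) -> float:
    """Exact P(credible interval of the difference excludes 0).

    For fixed oxBS count k2, detection is monotone in the RRBS count k1 on
    each side (larger k1 shifts the difference posterior up), so the
    positive and negative detection thresholds are found by bisection and
    tail probabilities come from the exact Binomial CDF.
    """
    k2s, pmf2 = _binom_support(n, p2, prune)
    k1s, _ = _binom_support(n, p1, prune)
    k1_lo, k1_hi = int(k1s[0]), int(k1s[-1])
    power = 0.0
    for k2, w2 in zip(k2s, pmf2):
        k2 = int(k2)
        # smallest k1 with CDIF > 0
        if _cdif_detects(n, k1_hi, k2, prior, level, grid_points) > 0:
            lo, hi = k1_lo, k1_hi
            if _cdif_detects(n, lo, k2, prior, level, grid_points) > 0:
                c_hi = lo
            else:
                while hi - lo > 1:
                    mid = (lo + hi) // 2
                    if _cdif_detects(n, mid, k2, prior, level, grid_points) > 0:
                        hi = mid
                    else:
                        lo = mid
                c_hi = hi
            power += w2 * float(binom.sf(c_hi - 1, n, p1))
        # largest k1 with CDIF < 0
        if _cdif_detects(n, k1_lo, k2, prior, level, grid_points) < 0:
            lo, hi = k1_lo, k1_hi
            if _cdif_detects(n, hi, k2, prior, level, grid_points) < 0:
                c_lo = hi
            else:
                while hi - lo > 1:
                    mid = (lo + hi) // 2
                    if _cdif_detects(n, mid, k2, prior, level, grid_points) < 0:
                        lo = mid
                    else:
                        hi = mid
                c_lo = lo
            power += w2 * float(binom.cdf(c_lo, n, p1))
    return power


def _fisher_pvalues_windowed(K: int, n: int, k1_query: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p for queried k1 under margins (K, n, n).

    Enumerates the hypergeometric pmf only inside a +/-12 sd window around
    its mean; the excluded tail mass (< 1e-12) is added to every p-value,
    which is exact for any table whose own probability exceeds the window
    edge (always true near the alpha = 0.05 detection boundary).
    """
    jmin, jmax = max(0, K - n), min(K, n)
    mean = K / 2.0
    sd = np.sqrt(max(K * 0.25 * (2 * n - K) / max(2 * n - 1, 1), 1.0))
    lo = max(jmin, int(mean - 12 * sd))
    hi = min(jmax, int(mean + 12 * sd) + 1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, 2 * n, K, n)
    tail = max(0.0, 1.0 - float(pmf.sum()))
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    out = np.ones_like(k1_query, dtype=float)
    inside = (k1_query >= lo) & (k1_query <= hi)
    q = k1_query[inside] - lo
    idx = np.searchsorted(sorted_pmf, pmf[q] * (1.0 + 1e-7), side="right")
    out[inside] = np.minimum(csum[np.maximum(idx, 1) - 1] + tail, 1.0)
    # queries outside the window are extreme tables: p <= tail mass
    out[~inside] = tail
    return out


def _fetp_power(n: int, p1: float, p2: float, alpha: float, prune: float) -> float:
    """Exact P(two-sided Fisher p < alpha) over the joint count distribution."""
    k1s, pmf1 = _binom_support(n, p1, prune)
    k2s, pmf2 = _binom_support(n, p2, prune)
    pmf1_full = np.zeros(n + 1)
    pmf1_full[k1s] = pmf1
    pmf2_full = np.zeros(n + 1)
    pmf2_full[k2s] = pmf2
    power = 0.0
    for K in range(int(k1s[0] + k2s[0]), int(k1s[-1] + k2s[-1]) + 1):
        # k1 must be in its pruned support and k2 = K - k1 in its own
        k1_range = np.arange(max(max(0, K - n), k1s[0], K - k2s[-1]),
                             min(min(K, n), k1s[-1], K - k2s[0]) + 1)
        if k1_range.size == 0:
            continue
        pvals = _fisher_pvalues_windowed(K, n, k1_range)
        detected = pvals < alpha
        if detected.any():
            k2_of = K - k1_range
            power += float(
                np.sum(pmf1_full[k1_range[detected]] * pmf2_full[k2_of[detected]])
            )
    return power


def min_coverage_to_detect(
    hmc_level: float,
    mc_level: float,
    method: str = "cdif",
    level: float = DEFAULT_LEVEL,
    power_target: float = 0.95,
    n_max: int = 2000,
    prior: BetaParams = BetaParams(1.0, 1.0),
    grid_points: int = DEFAULT_GRID,
    prune: float = 1e-12,
) -> int | None:
    """Smallest per-assay coverage detecting a 5hmC fraction with given power.

    RRBS counts are Binomial(n, mc + hmc) and oxBS counts Binomial(n, mc).
    Detection means, for ``cdif``, that the ``level`` credible interval of
    the RRBS - oxBS difference excludes zero; for ``fetp``, a two-sided
    Fisher exact p below 1 - ``level``.  Power is computed by exact
    enumeration over count pairs (Binomial pmfs pruned below ``prune``).
    The search brackets geometrically then bisects, assuming power is
    non-decreasing in n, and finally walks downward across any discreteness
    plateau.  Returns None when the target power is unreachable by
    ``n_max``.
    """
    if hmc_level < 0 or mc_level < 0 or hmc_level + mc_level > 1.0:
        raise ValueError("need hmc_level, mc_level >= 0 with sum <= 1")
    if method not in ("cdif", "fetp"):
        raise ValueError(f"unknown method: {method!r}")
    p1, p2 = mc_level + hmc_level, mc_level

    def power(n: int) -> float:
        if method == "cdif":
            return _cdif_power(n, p1, p2, prior, level, grid_points, prune)
        return _fetp_power(n, p1, p2, 1.0 - level, prune)

    n = 1
    while n < n_max and power(n) < power_target:
        n *= 2
    if n >= n_max:
        n = n_max
        if power(n) < power_target:
            return None
    lo = n // 2 if n > 1 else 0
    hi = n
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power(mid) >= power_target:
            hi = mid
        else:
            lo = mid
    while hi > 1 and power(hi - 1) >= power_target:
        hi -= 1
    return hi


def _thin_count(c: MethCount, q: float, rng: np.random.Generator) -> MethCount:
    n_new = int(rng.binomial(c.n_total, q)) if c.n_total else 0
    if n_new == 0:
        return MethCount(0, 0)
    k_new = int(rng.hypergeometric(c.k_meth, c.n_total - c.k_meth, n_new))
    return MethCount(n_new, k_new)


def downsample_depth(
    sites: Sequence[CpGSite], target_mean_depth: float, seed: int = 0
) -> list[CpGSite]:
    """Binomially thin read counts to a target mean depth.

    Each read is kept independently with probability target/current mean
    depth; the methylated count is then drawn hypergeometrically given the
    surviving total, which leaves the expected methylation ratio unchanged.
    """
    depths = [c.n_total for s in sites for rs in (s.cond1, s.cond2) for c in rs]
    current = float(np.mean(depths)) if depths else 0.0
    if target_mean_depth > current:
        raise ValueError(
            f"target depth {target_mean_depth} exceeds current mean {current:.2f}"
        )
    q = target_mean_depth / current if current > 0 else 0.0
    rng = np.random.default_rng(seed)
    out = []
    for s in sites:
        new_reps = tuple(
            ReplicateSet(tuple(_thin_count(c, q, rng) for c in rs))
            for rs in (s.cond1, s.cond2)
        )
        out.append(
            CpGSite(s.chrom, s.pos, new_reps[0], new_reps[1], s.strand)
        )
    return out
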