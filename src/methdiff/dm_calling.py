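"""Genome-scale differential-methylation calling.

Per-site calling combines two routes: the CDIF credible difference (replicate
aware, depth aware) and the classical two-sided Fisher exact test on pooled
counts, the standard comparator for DMC detection.  Site scores feed a
permutation false-discovery-rate estimate built by shuffling replicate sample
labels across conditions, and significant sites are merged into differentially
methylated regions either by a simple distance rule or by Viterbi decoding of
a three-state Gaussian HMM over the signed CDIF track.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .core_posterior import BetaParams, CredibleInterval, MethCount, ReplicateSet
from .diff_inference import DEFAULT_GRID, DEFAULT_LEVEL, difference_summary

__all__ = [
    "CpGSite",
    "DMCRecord",
    "DMRegion",
    "PermutationFdr",
    "fisher_exact_2x2",
    "call_dmcs",
    "permutation_fdr",
    "merge_dmrs",
    "cnv_keep_probability",
]

logger = logging.getLogger("methdiff")

# Relative tolerance when comparing table probabilities in the two-sided
# Fisher test, guarding against floating-point ties.
_FISHER_RTOL = 1e-7


@dataclass(frozen=True)
class CpGSite:
    """One CpG with replicate observations in two conditions."""

    chrom: str
    pos: int
    cond1: ReplicateSet
    cond2: ReplicateSet
    strand: str = "combined"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"position must be >= 0: {self.pos}")
        if self.strand not in ("+", "-", "combined"):
            raise ValueError(f"invalid strand: {self.strand!r}")


@dataclass(frozen=True)
class DMCRecord:
    """Per-site differential-methylation result."""

    site: CpGSite
    nominal_diff: float
    cdif: float
    fet_p: float
    sim_p: float
    ci: CredibleInterval
    skipped: bool = False


@dataclass(frozen=True)
class DMRegion:
    """Differentially methylated region (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_cdif: float
    direction: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("DMRegion requires end > start")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"invalid direction: {self.direction!r}")


def _fisher_pvalues_for_margin(K: int, n1: int, n2: int) -> np.ndarray:
    """Two-sided Fisher p for every table with margins (K, n1, n2).

    Returns p indexed by k1 - jmin over the hypergeometric support.  The
    p-value of an observed table is the sum of probabilities of all tables
    (fixed margins) whose probability does not exceed the observed one,
    within relative tolerance.
    """
    jmin, jmax = max(0, K - n2), min(K, n1)
    support = np.arange(jmin, jmax + 1)
    pmf = hypergeom.pmf(support, n1 + n2, K, n1)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + _FISHER_RTOL), side="right")
    p = csum[np.maximum(idx, 1) - 1]
    return np.minimum(p, 1.0)


def fisher_exact_2x2(c1: MethCount, c2: MethCount) -> float:
    """Two-sided Fisher exact test on the table [[k1, n1-k1], [k2, n2-k2]].

    Replicates are expected to be pooled by the caller.  A zero-read site in
    either condition returns p = 1 (logged), matching the convention that an
    unobserved site carries no evidence.
    """
    n1, k1 = c1.n_total, c1.k_meth
    n2, k2 = c2.n_total, c2.k_meth
    if n1 == 0 or n2 == 0:
        logger.debug("zero-read site in Fisher test (n1=%d, n2=%d); p=1", n1, n2)
        return 1.0
    K = k1 + k2
    jmin = max(0, K - n2)
    p = _fisher_pvalues_for_margin(K, n1, n2)[k1 - jmin]
    return float(p)


def _pool(reps: ReplicateSet | Sequence[MethCount]) -> MethCount:
    if isinstance(reps, ReplicateSet):
        return reps.pooled()
    return MethCount(sum(c.n_total for c in reps), sum(c.k_meth for c in reps))


def call_dmcs(
    sites: Iterable[CpGSite],
    priors=BetaParams(1.0, 1.0),
    level: float = DEFAULT_LEVEL,
    min_depth: int = 1,
    grid_points: int = DEFAULT_GRID,
    replicate_weight: float = 0.25,
) -> list[DMCRecord]:
    """Score every site with CDIF, Fisher p and the similarity p-value.

    Sites whose pooled depth falls below ``min_depth`` in either condition
    are emitted with ``skipped=True`` (CDIF 0, p-values 1) rather than
    dropped, so output order and site identity always match the input.
    The CDIF route uses the replicate-aware Beta fit when a condition has
    two or more replicates; the Fisher route always pools replicate counts.
    """
    out: list[DMCRecord] = []
    for site in sites:
        p1, p2 = _pool(site.cond1), _pool(site.cond2)
        nominal = (p1.ratio - p2.ratio) if (p1.n_total and p2.n_total) else float("nan")
        if p1.n_total < min_depth or p2.n_total < min_depth:
            out.append(
                DMCRecord(
                    site, nominal, 0.0, 1.0, 1.0,
                    CredibleInterval(-1.0, 1.0, level), skipped=True,
                )
            )
            continue
        res = difference_summary(
            site.cond1, site.cond2, priors, level, grid_points,
            replicate_weight=replicate_weight,
        )
        fet = fisher_exact_2x2(p1, p2)
        out.append(DMCRecord(site, nominal, res.cdif, fet, res.sim_p, res.ci))
    return out


@dataclass(frozen=True)
class PermutationFdr:
    """FDR as a non-increasing step function of the |score| threshold."""

    thresholds: np.ndarray
    fdr: np.ndarray
    n_perm: int

    def at(self, threshold: float) -> float:
        """FDR estimate at a given |score| cutoff."""
        i = np.searchsorted(self.thresholds, threshold, side="right") - 1
        if i < 0:
            return 1.0
        return float(self.fdr[i])


def _site_matrix(sites: Sequence[CpGSite]) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack replicate counts into (n_sites, n_samples) arrays (cond1 first)."""
    n1 = len(tuple(sites[0].cond1))
    n2 = len(tuple(sites[0].cond2))
    N = np.empty((len(sites), n1 + n2), dtype=np.int64)
    K = np.empty_like(N)
    for i, s in enumerate(sites):
        cs = tuple(s.cond1) + tuple(s.cond2)
        if len(cs) != n1 + n2:
            raise ValueError("all sites must have the same replicate layout")
        N[i] = [c.n_total for c in cs]
        K[i] = [c.k_meth for c in cs]
    return N, K, n1


def _scores_for_assignment(
    N: np.ndarray, K: np.ndarray, idx1: Sequence[int],
    priors, level: float, grid_points: int, replicate_weight: float,
) -> np.ndarray:
    idx1 = list(idx1)
    idx2 = [j for j in range(N.shape[1]) if j not in idx1]
    scores = np.empty(N.shape[0])
    for i in range(N.shape[0]):
        c1 = tuple(MethCount(int(N[i, j]), int(K[i, j])) for j in idx1)
        c2 = tuple(MethCount(int(N[i, j]), int(K[i, j])) for j in idx2)
        scores[i] = abs(
            difference_summary(
                c1, c2, priors, level, grid_points,
                replicate_weight=replicate_weight,
            ).cdif
        )
    return scores


def permutation_fdr(
    sites: Sequence[CpGSite],
    n_perm: int = 20,
    seed: int = 0,
    priors=BetaParams(1.0, 1.0),
    level: float = DEFAULT_LEVEL,
    grid_points: int = DEFAULT_GRID,
    replicate_weight: float = 0.25,
) -> PermutationFdr:
    """Permutation FDR from shuffling replicate sample labels across conditions.

    For each permutation the replicate columns are re-assigned to the two
    conditions and |CDIF| scores recomputed, giving a null score distribution.
    FDR(theta) = (mean null count of |score| >= theta) / (observed count of
    |score| >= theta), clipped to [0, 1] and monotonized so it is
    non-increasing in theta.  Deterministic given ``seed``.
    """
    sites = list(sites)
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    N, K, n1 = _site_matrix(sites)
    S = N.shape[1]
    all_assign = [c for c in combinations(range(S), n1)]
    identity = tuple(range(n1))
    # the complement of the identity reproduces the observed |score|
    # distribution exactly (the statistic is symmetric), so it is not a
    # null relabeling; drop it when group sizes are equal
    mirror = tuple(range(n1, S)) if S == 2 * n1 else None
    null_assign = [a for a in all_assign if a not in (identity, mirror)]
    if len(null_assign) < 2:
        raise ValueError(
            "only one distinct label permutation exists; use Benjamini-Hochberg "
            "on the similarity p-values instead"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(null_assign), size=n_perm, replace=n_perm > len(null_assign))
    obs = _scores_for_assignment(
        N, K, identity, priors, level, grid_points, replicate_weight
    )
    null_scores = [
        _scores_for_assignment(
            N, K, null_assign[p], priors, level, grid_points, replicate_weight
        )
        for p in picks
    ]
    null_all = np.sort(np.concatenate(null_scores))
    thresholds = np.unique(obs)
    n_obs = obs.size - np.searchsorted(np.sort(obs), thresholds, side="left")
    n_null = (null_all.size - np.searchsorted(null_all, thresholds, side="left")) / n_perm
    fdr = np.clip(np.divide(n_null, np.maximum(n_obs, 1)), 0.0, 1.0)
    # conservative monotonization: non-increasing in the threshold
    fdr = np.maximum.accumulate(fdr[::-1])[::-1]
    return PermutationFdr(thresholds, fdr, n_perm)


def _mom_emissions(cdifs: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments Gaussian emission parameters for the 3-state HMM."""
    pos = cdifs[cdifs > 0]
    neg = cdifs[cdifs < 0]
    mu_hyper = float(pos.mean()) if pos.size else 0.3
    mu_hypo = float(neg.mean()) if neg.size else -0.3
    sigma = float(cdifs.std()) if cdifs.size else 0.05
    sigma = max(min(sigma, 0.2), 0.02)
    return mu_hypo, mu_hyper, sigma


def _viterbi_states(cdifs: np.ndarray, self_prob: float) -> np.ndarray:
    """Viterbi path of a fixed 3-state (hypo / same / hyper) Gaussian HMM."""
    from hmmlearn.hmm import GaussianHMM

    mu_hypo, mu_hyper, sigma = _mom_emissions(cdifs)
    model = GaussianHMM(n_components=3, covariance_type="diag", init_params="", params="")
    model.startprob_ = np.array([0.1, 0.8, 0.1])
    off = (1.0 - self_prob) / 2.0
    model.transmat_ = np.array(
        [
            [self_prob, off, off],
            [off, self_prob, off],
            [off, off, self_prob],
        ]
    )
    model.means_ = np.array([[mu_hypo], [0.0], [mu_hyper]])
    model.covars_ = np.full((3, 1), sigma**2)
    return model.predict(cdifs.reshape(-1, 1))


def merge_dmrs(
    dmcs: Sequence[DMCRecord],
    max_gap: int = 300,
    min_cpgs: int = 3,
    method: str = "distance",
    fdr_mask: Sequence[bool] | None = None,
    self_prob: float = 0.9,
) -> list[DMRegion]:
    """Group significant DMCs into differentially methylated regions.

    ``distance``: consecutive significant DMCs (CDIF != 0, same sign,
    optional FDR mask) merge while the inter-CpG gap is <= ``max_gap`` bp;
    regions with fewer than ``min_cpgs`` members are dropped.  ``hmm``:
    Viterbi decoding of a 3-state Gaussian HMM over the signed CDIF track per
    chromosome (fixed transitions with self-probability ``self_prob``,
    method-of-moments emissions); state runs become candidate regions, then
    the same sign/significance and ``min_cpgs`` filters apply.  Regions never
    span chromosomes; input must be sorted by (chrom, pos).
    """
    dmcs = list(dmcs)
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    keys = [(r.site.chrom, r.site.pos) for r in dmcs]
    if keys != sorted(keys):
        bad = next(i for i in range(1, len(keys)) if keys[i] < keys[i - 1])
        raise ValueError(
            f"DMC records must be sorted by (chrom, pos); record {bad} "
            f"({keys[bad]}) precedes {keys[bad - 1]}"
        )
    if fdr_mask is None:
        sig = [(not r.skipped) and r.cdif != 0.0 for r in dmcs]
    else:
        if len(fdr_mask) != len(dmcs):
            raise ValueError("fdr_mask length must match dmcs")
        sig = [
            (not r.skipped) and r.cdif != 0.0 and bool(m)
            for r, m in zip(dmcs, fdr_mask)
        ]

    def _emit(members: list[DMCRecord]) -> DMRegion | None:
        if len(members) < min_cpgs:
            return None
        cd = np.array([m.cdif for m in members])
        return DMRegion(
            chrom=members[0].site.chrom,
            start=members[0].site.pos,
            end=members[-1].site.pos + 1,
            n_cpgs=len(members),
            mean_cdif=float(cd.mean()),
            direction="hyper" if cd[0] > 0 else "hypo",
        )

    regions: list[DMRegion] = []
    if method == "distance":
        run: list[DMCRecord] = []
        for r, s in zip(dmcs, sig):
            if not s:
                if run and (reg := _emit(run)):
                    regions.append(reg)
                run = []
                continue
            if run and (
                r.site.chrom != run[-1].site.chrom
                or r.site.pos - run[-1].site.pos > max_gap
                or math.copysign(1, r.cdif) != math.copysign(1, run[-1].cdif)
            ):
                if reg := _emit(run):
                    regions.append(reg)
                run = []
            run.append(r)
        if run and (reg := _emit(run)):
            regions.append(reg)
        return regions

    if method != "hmm":
        raise ValueError(f"unknown merge method: {method!r}")

    # HMM route: decode per chromosome, keep runs of the hypo/hyper states.
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(dmcs):
        by_chrom.setdefault(r.site.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        cd = np.array([dmcs[i].cdif for i in idxs])
        states = _viterbi_states(cd, self_prob)
        start = 0
        for stop in range(1, len(idxs) + 1):
            if stop == len(idxs) or states[stop] != states[start]:
                if states[start] != 1:
                    want = 1.0 if states[start] == 2 else -1.0
                    members = [
                        dmcs[idxs[j]]
                        for j in range(start, stop)
                        if sig[idxs[j]] and math.copysign(1, dmcs[idxs[j]].cdif) == want
                    ]
                    if members and (reg := _emit(members)):
                        regions.append(reg)
                start = stop
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def cnv_keep_probability(copy_number: float) -> float:
    """Read-retention probability 2/X correcting copy-number depth bias.

    In a region of copy number X in a diploid genome, keeping each read with
    probability 2/X restores the diploid expected depth; for deletions
    (X < 2) the probability is capped at 1, since reads cannot be up-sampled.
    """
    if not copy_number > 0:
        raise ValueError(f"copy number must be positive: {copy_number}")
    return min(1.0, 2.0 / copy_number)
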