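"""Beta posteriors of methylation ratios and empirical-Bayes prior estimation.

Bisulfite sequencing reports, per cytosine, the number of total reads ``n``
and methylated reads ``k``.  Given the true methylation ratio ``p``, reads are
``k ~ Binomial(n, p)``; with a conjugate ``Beta(alpha0, beta0)`` prior the
posterior of ``p`` is ``Beta(k + alpha0, n - k + beta0)``.  The prior is
estimated genome-wide by maximizing the Beta-Binomial marginal likelihood,
which lets sites with few reads borrow the strongly bimodal shape of genomic
methylation (most CpGs are fully methylated or fully unmethylated).

With biological replicates, a per-condition ``Beta(alpha_i, beta_i)`` is fit
to the replicate counts by maximum penalized Beta-Binomial likelihood, so the
inferred methylation-ratio distribution widens (even turns bimodal) for
discordant replicates and tightens as concordant replicates accumulate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "MethCount",
    "BetaParams",
    "ReplicateSet",
    "DensityGrid",
    "CredibleInterval",
    "PriorEstimationError",
    "DEFAULT_PRIOR",
    "UNIFORM_PRIOR",
    "posterior_from_counts",
    "beta_density_grid",
    "betabinom_logpmf",
    "estimate_genome_prior",
    "fit_replicate_beta",
    "single_proportion_ci",
]

logger = logging.getLogger("methdiff")

# Box bounds for shape parameters during likelihood optimization (log space).
_LOG_BOUND_LO = np.log(1e-3)
_LOG_BOUND_HI = np.log(1e4)
_GTOL = 1e-8
_MIN_SITES_FOR_PRIOR = 100


@dataclass(frozen=True)
class MethCount:
    """Read observation at one cytosine in one replicate: ``k`` of ``n`` methylated."""

    n_total: int
    k_meth: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.k_meth < 0 or self.k_meth > self.n_total:
            raise ValueError(
                f"invalid methylation counts: k={self.k_meth}, n={self.n_total}"
            )

    @property
    def ratio(self) -> float:
        """Nominal methylation ratio k/n (nan when n = 0)."""
        return self.k_meth / self.n_total if self.n_total > 0 else float("nan")


@dataclass(frozen=True)
class BetaParams:
    """Shape pair (alpha, beta) of a Beta distribution on [0, 1]."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0) or not (
            np.isfinite(self.alpha) and np.isfinite(self.beta)
        ):
            raise ValueError(f"Beta shapes must be positive finite, got {self}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


#: Weakly bimodal default prior; genomic methylation is strongly bimodal.
DEFAULT_PRIOR = BetaParams(0.5, 0.5)
#: Flat prior, selectable when no shrinkage toward bimodality is wanted.
UNIFORM_PRIOR = BetaParams(1.0, 1.0)


@dataclass(frozen=True)
class ReplicateSet:
    """Ordered biological replicates of one condition at one cytosine."""

    counts: tuple[MethCount, ...]

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ValueError("ReplicateSet requires at least one replicate")

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self) -> Iterator[MethCount]:
        return iter(self.counts)

    def pooled(self) -> MethCount:
        """Sum counts across replicates (the pooling used by Fisher-test calling)."""
        return MethCount(
            sum(c.n_total for c in self.counts),
            sum(c.k_meth for c in self.counts),
        )


@dataclass
class DensityGrid:
    """Probability density tabulated as exact per-cell masses on [lo, hi].

    The support is divided into ``G`` equal cells; ``cell_mass[i]`` is the
    integrated probability of cell ``i``.  Working with masses rather than
    midpoint density values keeps endpoint singularities (Beta shapes < 1)
    exact and makes convolution of distributions a discrete convolution.
    """

    lo: float
    hi: float
    cell_mass: np.ndarray

    def __post_init__(self) -> None:
        self.cell_mass = np.asarray(self.cell_mass, dtype=float)
        if not self.hi > self.lo:
            raise ValueError("DensityGrid requires hi > lo")
        if self.cell_mass.ndim != 1 or self.cell_mass.size < 1:
            raise ValueError("cell_mass must be a 1-D array")
        if np.any(self.cell_mass < -1e-12):
            raise ValueError("cell masses must be non-negative")
        total = float(self.cell_mass.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"cell masses must sum to 1 (got {total})")

    @property
    def n_cells(self) -> int:
        return self.cell_mass.size

    @property
    def cell_width(self) -> float:
        return (self.hi - self.lo) / self.n_cells

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_cells + 1)

    @property
    def midpoints(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def values(self) -> np.ndarray:
        """Density values (mass / cell width) at cell midpoints."""
        return self.cell_mass / self.cell_width

    def mean(self) -> float:
        return float(np.dot(self.cell_mass, self.midpoints))

    def _cumulative(self) -> np.ndarray:
        cum = np.empty(self.n_cells + 1)
        cum[0] = 0.0
        np.cumsum(self.cell_mass, out=cum[1:])
        cum[-1] = 1.0
        return cum

    def cdf(self, x) -> np.ndarray | float:
        """P(X <= x), linear within cells."""
        out = np.interp(x, self.edges, self._cumulative())
        return out

    def quantile(self, q) -> np.ndarray | float:
        """Smallest x with CDF(x) >= q, linear within cells."""
        cum = self._cumulative()
        edges = self.edges
        qs = np.atleast_1d(np.asarray(q, dtype=float))
        idx = np.searchsorted(cum, qs, side="left")
        idx = np.clip(idx, 1, self.n_cells)
        lo_c, hi_c = cum[idx - 1], cum[idx]
        frac = np.where(hi_c > lo_c, (qs - lo_c) / np.maximum(hi_c - lo_c, 1e-300), 0.0)
        x = edges[idx - 1] + np.clip(frac, 0.0, 1.0) * (edges[idx] - edges[idx - 1])
        return x if np.ndim(q) else float(x[0])


@dataclass(frozen=True)
class CredibleInterval:
    """Credible interval (a, b) containing ``level`` posterior mass."""

    a: float
    b: float
    level: float

    def __post_init__(self) -> None:
        if self.a > self.b:
            raise ValueError(f"interval bounds out of order: {self}")
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0,1): {self.level}")


class PriorEstimationError(RuntimeError):
    """Marginal-likelihood optimization failed; carries the best iterate found."""

    def __init__(self, message: str, best: BetaParams):
        super().__init__(message)
        self.best = best


def posterior_from_counts(counts: MethCount, prior: BetaParams) -> BetaParams:
    """Conjugate Beta posterior of the methylation ratio at one site.

    alpha = k + alpha0, beta = n - k + beta0.  With n = 0 the prior is
    returned unchanged.
    """
    return BetaParams(
        prior.alpha + counts.k_meth,
        prior.beta + counts.n_total - counts.k_meth,
    )


def beta_density_grid(params: BetaParams, grid_points: int = 512) -> DensityGrid:
    """Tabulate a Beta density on [0, 1] as exact per-cell probabilities.

    Cell masses are differences of the regularized incomplete beta function at
    the cell edges, so the result is exact (up to normalization round-off)
    even when alpha < 1 or beta < 1 and the density diverges at an endpoint.
    """
    if grid_points < 64:
        raise ValueError("grid_points must be >= 64")
    edges = np.linspace(0.0, 1.0, grid_points + 1)
    cdf = special.betainc(params.alpha, params.beta, edges)
    mass = np.diff(cdf)
    mass = np.clip(mass, 0.0, None)
    mass /= mass.sum()
    return DensityGrid(0.0, 1.0, mass)


def _bb_logpmf(n, k, alpha: float, beta: float):
    """Vectorized Beta-Binomial log pmf via log-gamma."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return (
        special.gammaln(n + 1.0)
        - special.gammaln(k + 1.0)
        - special.gammaln(n - k + 1.0)
        + special.betaln(alpha + k, beta + n - k)
        - special.betaln(alpha, beta)
    )


def betabinom_logpmf(counts: MethCount, params: BetaParams) -> float:
    """log P(k | n, alpha, beta) under the Beta-Binomial marginal.

    This is the log of ``C(n,k) B(alpha+k, beta+n-k) / B(alpha, beta)``,
    i.e. the Binomial likelihood integrated over a Beta-distributed ratio.
    """
    return float(_bb_logpmf(counts.n_total, counts.k_meth, params.alpha, params.beta))


def _aggregate_counts(all_counts) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse a site collection to unique (n, k) pairs with multiplicities."""
    n = np.fromiter((c.n_total for c in all_counts), dtype=np.int64)
    k = np.fromiter((c.k_meth for c in all_counts), dtype=np.int64)
    keep = n >= 1
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluding %d zero-read sites from prior estimation", n_excluded)
    n, k = n[keep], k[keep]
    pairs = np.stack([n, k], axis=1)
    uniq, w = np.unique(pairs, axis=0, return_counts=True)
    return uniq[:, 0].astype(float), uniq[:, 1].astype(float), w.astype(float)


def _moment_start(n: np.ndarray, k: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Beta fit of the nominal ratios, as an optimizer start."""
    r = k / n
    m = float(np.average(r, weights=w))
    v = float(np.average((r - m) ** 2, weights=w))
    m = min(max(m, 1e-3), 1.0 - 1e-3)
    if v <= 1e-6 or v >= m * (1.0 - m):
        return 1.0, 1.0
    s = m * (1.0 - m) / v - 1.0
    return float(np.clip(m * s, 1e-3, 1e4)), float(np.clip((1.0 - m) * s, 1e-3, 1e4))


def _maximize_bb_loglik(
    n: np.ndarray,
    k: np.ndarray,
    w: np.ndarray,
    starts: Sequence[tuple[float, float]],
    penalty_center: BetaParams | None = None,
    penalty_weight: float = 0.0,
) -> tuple[BetaParams, float, bool]:
    """L-BFGS-B maximization of the (penalized) Beta-Binomial log likelihood.

    Works in (log alpha, log beta) with box bounds; the optional penalty is an
    independent log-normal on each shape centred at ``penalty_center`` with
    unit log-variance.  Returns (argmax, value, converged).
    """
    if penalty_center is not None and penalty_weight > 0.0:
        c = (np.log(penalty_center.alpha), np.log(penalty_center.beta))
    else:
        c = None

    def neg(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        ll = float(np.dot(w, _bb_logpmf(n, k, a, b)))
        if c is not None:
            ll -= 0.5 * penalty_weight * ((theta[0] - c[0]) ** 2 + (theta[1] - c[1]) ** 2)
        return -ll

    bounds = [(_LOG_BOUND_LO, _LOG_BOUND_HI)] * 2
    best_x, best_f, any_ok = None, np.inf, False
    for a0, b0 in starts:
        x0 = np.log(np.clip([a0, b0], np.exp(_LOG_BOUND_LO), np.exp(_LOG_BOUND_HI)))
        res = optimize.minimize(
            neg, x0, method="L-BFGS-B", bounds=bounds, options={"gtol": _GTOL, "maxiter": 500}
        )
        any_ok = any_ok or bool(res.success)
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    a, b = np.exp(best_x)
    at_boundary = (
        min(best_x[0] - _LOG_BOUND_LO, _LOG_BOUND_HI - best_x[0]) < 1e-6
        or min(best_x[1] - _LOG_BOUND_LO, _LOG_BOUND_HI - best_x[1]) < 1e-6
    )
    if at_boundary:
        warnings.warn(
            f"Beta shape estimate at optimization bound: alpha={a:.4g}, beta={b:.4g}",
            RuntimeWarning,
            stacklevel=3,
        )
    if not any_ok:
        raise PriorEstimationError(
            "Beta-Binomial likelihood maximization did not converge", BetaParams(a, b)
        )
    return BetaParams(float(a), float(b)), -best_f, bool(any_ok)


def estimate_genome_prior(
    all_counts, init: BetaParams = UNIFORM_PRIOR
) -> BetaParams:
    """Empirical-Bayes Beta prior from all cytosines of one condition.

    Maximizes the marginal Beta-Binomial log likelihood summed over sites by
    quasi-Newton optimization in log-parameter space; identical (n, k)
    observations are aggregated first, which makes genome-scale estimation
    cheap.  Zero-read sites are excluded (logged, never an error).  With
    fewer than 100 informative sites a warning is issued and the weakly
    bimodal fallback ``Beta(0.5, 0.5)`` is returned.
    """
    n, k, w = _aggregate_counts(all_counts)
    if int(w.sum()) < _MIN_SITES_FOR_PRIOR:
        warnings.warn(
            f"only {int(w.sum())} informative sites; falling back to "
            f"Beta({DEFAULT_PRIOR.alpha}, {DEFAULT_PRIOR.beta}) prior",
            RuntimeWarning,
            stacklevel=2,
        )
        return DEFAULT_PRIOR
    starts = [(0.5, 0.5), (1.0, 1.0), _moment_start(n, k, w), (init.alpha, init.beta)]
    est, ll, _ = _maximize_bb_loglik(n, k, w, starts)
    ll_init = float(np.dot(w, _bb_logpmf(n, k, init.alpha, init.beta)))
    if ll < ll_init - 1e-6:
        raise PriorEstimationError(
            "optimizer ended below the initial log-likelihood", est
        )
    return est


def fit_replicate_beta(
    reps: ReplicateSet | Sequence[MethCount],
    hyperprior: BetaParams,
    weight: float = 0.25,
) -> BetaParams:
    """Fit a condition's methylation-ratio Beta from >= 2 biological replicates.

    Maximizes the sum of per-replicate Beta-Binomial log pmfs plus a weak
    log-normal penalty on (alpha, beta) centred at ``hyperprior`` (unit
    log-variance, weight configurable).  Discordant replicates drive both
    shapes below 1 (bimodal inferred density); concordant replicates drive
    both above 1, and adding concordant replicates shrinks its variance.
    """
    counts = tuple(reps)
    if len(counts) < 2:
        raise ValueError(
            "fit_replicate_beta requires >= 2 replicates; "
            "use posterior_from_counts for a single sample"
        )
    n = np.array([c.n_total for c in counts], dtype=float)
    k = np.array([c.k_meth for c in counts], dtype=float)
    w = np.ones_like(n)
    starts = [
        (0.5, 0.5),
        (1.0, 1.0),
        _moment_start(n, k, w),
        (hyperprior.alpha, hyperprior.beta),
    ]
    est, _, _ = _maximize_bb_loglik(
        n, k, w, starts, penalty_center=hyperprior, penalty_weight=weight
    )
    return est


def single_proportion_ci(
    counts: MethCount, prior: BetaParams, level: float = 0.95
) -> CredibleInterval:
    """Equal-tail credible interval of a single methylation ratio.

    Taken directly from the Beta posterior quantiles at (1-level)/2 and
    1-(1-level)/2.
    """
    if not 0.5 < level < 1.0:
        raise ValueError(f"level must be in (0.5, 1): {level}")
    post = posterior_from_counts(counts, prior)
    from scipy.stats import beta as beta_dist

    tail = (1.0 - level) / 2.0
    a = float(beta_dist.ppf(tail, post.alpha, post.beta))
    b = float(beta_dist.ppf(1.0 - tail, post.alpha, post.beta))
    return CredibleInterval(a, b, level)
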