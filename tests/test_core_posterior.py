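"""Beta posterior updates, density grids, Beta-Binomial likelihood and fits."""

import numpy as np
import pytest
import warnings
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import beta as beta_dist

from methdiff import (
    BetaParams,
    MethCount,
    beta_density_grid,
    betabinom_logpmf,
    estimate_genome_prior,
    fit_replicate_beta,
    posterior_from_counts,
    single_proportion_ci,
)
from methdiff.core_posterior import _bb_logpmf


class TestPosteriorUpdate:
    @pytest.mark.parametrize(
        "n,k,prior,expected",
        [
            (0, 0, (1, 1), (1, 1)),          # no data returns the prior
            (10, 9, (1, 1), (10, 2)),
            (80, 12, (1, 1), (13, 69)),
            (14, 7, (0.5, 0.5), (7.5, 7.5)),
        ],
    )
    def test_conjugate_update(self, n, k, prior, expected):
        post = posterior_from_counts(MethCount(n, k), BetaParams(*prior))
        assert (post.alpha, post.beta) == expected

    def test_low_depth_posterior_has_higher_variance(self):
        shallow = posterior_from_counts(MethCount(10, 9), BetaParams(1, 1))
        deep = posterior_from_counts(MethCount(80, 12), BetaParams(1, 1))
        assert shallow.variance > deep.variance

    def test_symmetric_counts_give_mean_half(self):
        post = posterior_from_counts(MethCount(14, 7), BetaParams(0.5, 0.5))
        assert post.mean == 0.5

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            MethCount(5, 6)
        with pytest.raises(ValueError):
            MethCount(-1, 0)

    @given(
        n=st.integers(1, 200),
        k_frac=st.floats(0.01, 0.99),
        a=st.floats(0.1, 20),
        b=st.floats(0.1, 20),
    )
    @settings(max_examples=50, derandomize=True)
    def test_shrinkage_between_prior_mean_and_mle(self, n, k_frac, a, b):
        k = max(1, min(n - 1, int(round(k_frac * n))))
        if k <= 0 or k >= n:
            return
        prior = BetaParams(a, b)
        post = posterior_from_counts(MethCount(n, k), prior)
        lo, hi = sorted((prior.mean, k / n))
        assert lo - 1e-12 <= post.mean <= hi + 1e-12


class TestBetaDensityGrid:
    def test_uniform_masses(self):
        g = beta_density_grid(BetaParams(1, 1), 100)
        assert np.allclose(g.cell_mass, 0.01, atol=1e-12)

    def test_cell_masses_match_quadrature(self):
        g = beta_density_grid(BetaParams(10, 2), 512)
        edges = g.edges
        for i in range(0, 512, 37):
            q, _ = integrate.quad(
                lambda p: beta_dist.pdf(p, 10, 2), edges[i], edges[i + 1]
            )
            assert g.cell_mass[i] == pytest.approx(q, abs=1e-8)

    def test_endpoint_singularities_normalized(self):
        g = beta_density_grid(BetaParams(0.5, 0.5), 512)
        assert abs(g.cell_mass.sum() - 1.0) < 1e-12

    @given(a=st.floats(0.05, 50), b=st.floats(0.05, 50))
    @settings(max_examples=40, derandomize=True)
    def test_masses_always_sum_to_one(self, a, b):
        g = beta_density_grid(BetaParams(a, b), 512)
        assert abs(g.cell_mass.sum() - 1.0) < 1e-6

    def test_rejects_too_coarse_grid(self):
        with pytest.raises(ValueError):
            beta_density_grid(BetaParams(1, 1), 32)


class TestBetaBinomialPmf:
    def test_single_uniform_draw(self):
        assert betabinom_logpmf(MethCount(1, 1), BetaParams(1, 1)) == pytest.approx(
            np.log(0.5)
        )

    def test_matches_quadrature_of_marginal(self):
        from scipy.special import comb

        target, _ = integrate.quad(
            lambda p: comb(10, 3) * p**3 * (1 - p) ** 7 * beta_dist.pdf(p, 2, 5),
            0, 1,
        )
        got = np.exp(betabinom_logpmf(MethCount(10, 3), BetaParams(2, 5)))
        assert got == pytest.approx(target, abs=1e-10)

    def test_matches_scipy_distribution(self):
        from scipy.stats import betabinom as sp_bb

        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 100))
            k = int(rng.integers(0, n + 1))
            a, b = rng.uniform(0.05, 30, 2)
            assert betabinom_logpmf(MethCount(n, k), BetaParams(a, b)) == pytest.approx(
                sp_bb.logpmf(k, n, a, b), rel=1e-10
            )

    @given(
        n=st.integers(0, 60), a=st.floats(0.05, 40), b=st.floats(0.05, 40)
    )
    @settings(max_examples=40, derandomize=True)
    def test_pmf_normalizes_over_k(self, n, a, b):
        total = np.exp(_bb_logpmf(np.full(n + 1, n), np.arange(n + 1), a, b)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)


class TestGenomePriorEstimation:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(42)
        p = rng.beta(0.4, 0.4, 50_000)
        counts = [MethCount(30, int(k)) for k in rng.binomial(30, p)]
        est = estimate_genome_prior(counts)
        assert est.alpha == pytest.approx(0.4, rel=0.10)
        assert est.beta == pytest.approx(0.4, rel=0.10)

    def test_fully_methylated_terminates_at_boundary(self):
        counts = [MethCount(20, 20)] * 500
        with pytest.warns(RuntimeWarning, match="optimization bound"):
            est = estimate_genome_prior(counts)
        assert est.beta <= 1.01e-3

    def test_duplicating_data_leaves_argmax_unchanged(self):
        rng = np.random.default_rng(3)
        p = rng.beta(2.0, 5.0, 2_000)
        counts = [MethCount(25, int(k)) for k in rng.binomial(25, p)]
        e1 = estimate_genome_prior(counts)
        e2 = estimate_genome_prior(counts + counts)
        assert e2.alpha == pytest.approx(e1.alpha, rel=1e-4)
        assert e2.beta == pytest.approx(e1.beta, rel=1e-4)

    def test_too_few_sites_falls_back_with_warning(self):
        with pytest.warns(RuntimeWarning, match="falling back"):
            est = estimate_genome_prior([MethCount(10, 5)] * 50)
        assert (est.alpha, est.beta) == (0.5, 0.5)

    def test_zero_read_sites_excluded_not_fatal(self):
        rng = np.random.default_rng(8)
        p = rng.beta(1.5, 3.0, 500)
        counts = [MethCount(20, int(k)) for k in rng.binomial(20, p)]
        counts += [MethCount(0, 0)] * 100
        est = estimate_genome_prior(counts)
        assert est.alpha > 0 and est.beta > 0


class TestReplicateBetaFit:
    def test_discordant_replicates_give_bimodal_shape(self):
        f = fit_replicate_beta(
            [MethCount(14, 0), MethCount(14, 14)], BetaParams(1, 1)
        )
        assert f.alpha < 1 and f.beta < 1

    def test_concordant_replicates_give_unimodal_shape(self):
        f = fit_replicate_beta([MethCount(14, 7)] * 2, BetaParams(1, 1))
        assert f.alpha > 1 and f.beta > 1
        assert f.mean == pytest.approx(0.5, abs=1e-6)

    def test_third_concordant_replicate_shrinks_variance(self):
        f2 = fit_replicate_beta([MethCount(14, 7)] * 2, BetaParams(1, 1))
        f3 = fit_replicate_beta([MethCount(14, 7)] * 3, BetaParams(1, 1))
        assert f3.variance < f2.variance

    def test_single_replicate_is_contract_violation(self):
        with pytest.raises(ValueError, match="2 replicates"):
            fit_replicate_beta([MethCount(14, 7)], BetaParams(1, 1))

    @pytest.mark.parametrize(
        "reps",
        [
            (MethCount(14, 0), MethCount(14, 14)),
            (MethCount(14, 7), MethCount(14, 7)),
            (MethCount(30, 3), MethCount(30, 4)),
            (MethCount(20, 5), MethCount(25, 18)),
        ],
    )
    def test_dominates_grid_search_oracle(self, reps):
        hyper = BetaParams(1, 1)
        fitted = fit_replicate_beta(reps, hyper)

        n = np.array([c.n_total for c in reps], float)
        k = np.array([c.k_meth for c in reps], float)

        def objective(a, b):
            ll = _bb_logpmf(n, k, a, b).sum()
            pen = 0.5 * 0.25 * (np.log(a) ** 2 + np.log(b) ** 2)
            return ll - pen

        grid = np.exp(np.linspace(np.log(0.05), np.log(50), 200))
        best = max(objective(a, b) for a in grid for b in grid)
        assert objective(fitted.alpha, fitted.beta) >= best - 1e-6


class TestSingleProportionCi:
    def test_uniform_posterior_quantiles(self):
        ci = single_proportion_ci(MethCount(0, 0), BetaParams(1, 1), 0.95)
        assert ci.a == pytest.approx(0.025, abs=1e-9)
        assert ci.b == pytest.approx(0.975, abs=1e-9)

    def test_matches_bisection_on_cdf_oracle(self):
        ci = single_proportion_ci(MethCount(10, 9), BetaParams(1, 1), 0.95)

        def bisect_quantile(q):
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = (lo + hi) / 2
                if beta_dist.cdf(mid, 10, 2) < q:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        assert ci.a == pytest.approx(bisect_quantile(0.025), abs=1e-8)
        assert ci.b == pytest.approx(bisect_quantile(0.975), abs=1e-8)

    def test_width_non_increasing_in_depth(self):
        widths = []
        for n in (10, 20, 40, 80, 160, 320, 640):
            k = int(0.7 * n)
            ci = single_proportion_ci(MethCount(n, k), BetaParams(1, 1), 0.95)
            widths.append(ci.b - ci.a)
        assert all(w2 <= w1 + 1e-12 for w1, w2 in zip(widths, widths[1:]))
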