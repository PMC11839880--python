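import numpy as np
import pytest

from distfree import (
    GRID,
    BetaParams,
    DiscretePosterior,
    MannWhitneyStats,
    WilcoxonStats,
    mann_whitney,
    mann_whitney_small_posterior,
    rank_large_posterior,
    wilcoxon,
    wilcoxon_exact_posterior,
    wilcoxon_small_posterior,
)

from _oracles import wilcoxon_enumeration_posterior


def tv_distance(p, q):
    return 0.5 * np.abs(np.asarray(p) - np.asarray(q)).sum()


class TestGrid:
    def test_grid_values_exact(self):
        assert GRID.size == 200
        np.testing.assert_array_equal(GRID, 0.0025 + 0.005 * np.arange(200))
        assert not np.any(GRID == 0.5)

    def test_probs_must_normalize(self):
        with pytest.raises(ValueError):
            DiscretePosterior(GRID, np.full(200, 0.004))


class TestWilcoxonSmall:
    @pytest.mark.parametrize("n,t_obs", [(3, 6), (9, 32), (9, 13)])
    def test_monte_carlo_matches_enumeration(self, n, t_obs):
        """The sampled grid posterior converges to the exhaustive 2^n
        enumeration posterior in total variation."""
        stats = WilcoxonStats(t_plus=t_obs, t_minus=n * (n + 1) / 2 - t_obs, n_blocks=n)
        post = wilcoxon_small_posterior(stats, samples=100_000, seed=42, quiet=True)
        exact = wilcoxon_enumeration_posterior(n, t_obs, GRID)
        assert tv_distance(post.discrete.probs, exact) < 0.01

    def test_exact_dp_equals_enumeration(self):
        """The dynamic-programming likelihood reproduces the 2^n enumeration
        posterior to machine precision."""
        for n, t_obs in [(3, 6), (8, 20), (12, 50)]:
            stats = WilcoxonStats(t_obs, n * (n + 1) / 2 - t_obs, n)
            post = wilcoxon_exact_posterior(stats)
            exact = wilcoxon_enumeration_posterior(n, t_obs, GRID)
            np.testing.assert_allclose(post.discrete.probs, exact, atol=1e-12)

    def test_symmetric_statistic_balances(self):
        stats = WilcoxonStats(22.5, 22.5, 9)  # T+ = n(n+1)/4
        post = wilcoxon_exact_posterior(stats)
        # rounding T+ to 22 tips the balance by less than one grid step of mass
        assert post.post_prob_gt_half == pytest.approx(0.5, abs=0.05)

    def test_mirror_antisymmetry(self):
        a = wilcoxon_exact_posterior(WilcoxonStats(32, 13, 9))
        b = wilcoxon_exact_posterior(WilcoxonStats(13, 32, 9))
        np.testing.assert_allclose(a.discrete.probs, b.discrete.probs[::-1], atol=1e-12)

    def test_unreachable_statistic_raises(self):
        with pytest.raises(ValueError, match="large"):
            wilcoxon_exact_posterior(WilcoxonStats(100, 0, 3))


class TestMannWhitneySmall:
    def test_single_pair_closed_form(self):
        """With one observation per group and U_E = 1 the likelihood is
        exactly Omega, so the uniform-prior posterior is linear in Omega."""
        stats = MannWhitneyStats(1, 0, 1, 1)
        post = mann_whitney_small_posterior(stats, samples=100_000, seed=9, quiet=True)
        exact = GRID / GRID.sum()
        assert tv_distance(post.discrete.probs, exact) < 0.01

    def test_balanced_u_is_symmetric(self):
        stats = MannWhitneyStats(8, 8, 4, 4)
        post = mann_whitney_small_posterior(stats, samples=30_000, seed=3, quiet=True)
        assert post.post_prob_gt_half == pytest.approx(0.5, abs=0.02)

    def test_group_swap_mirrors_posterior(self):
        a = mann_whitney_small_posterior(
            MannWhitneyStats(16, 4, 5, 4), samples=40_000, seed=17, quiet=True
        )
        b = mann_whitney_small_posterior(
            MannWhitneyStats(4, 16, 4, 5), samples=40_000, seed=18, quiet=True
        )
        assert a.post_prob_gt_half == pytest.approx(1.0 - b.post_prob_gt_half, abs=0.02)
        assert tv_distance(a.discrete.probs, b.discrete.probs[::-1]) < 0.03

    def test_dominant_experimental_group(self):
        post = mann_whitney_small_posterior(
            MannWhitneyStats(16, 4, 5, 4), samples=40_000, seed=17, quiet=True
        )
        assert post.posterior_mean > 0.5
        assert post.bf10 > 1.0


class TestLargeSample:
    def test_wilcoxon_large_close_to_exact_small(self):
        rng = np.random.default_rng(8)
        y1 = rng.normal(0.5, 1, 20)
        y2 = rng.normal(0.0, 1, 20)
        small = wilcoxon(y1, y2, method="small", samples=100_000, seed=1, quiet=True)
        large = wilcoxon(y1, y2, method="large")
        qs = [0.025, 0.5, 0.975]
        small_q = small.discrete.quantile(qs)
        large_q = large.beta_approx.ppf(qs)
        np.testing.assert_allclose(small_q, large_q, atol=0.02)
        assert abs(small.post_prob_gt_half - large.post_prob_gt_half) < 0.02

    def test_symmetric_statistic_centers_fit(self):
        stats = WilcoxonStats(60, 60, 15)  # T+ = n(n+1)/4 for n = 15
        post = rank_large_posterior(stats)
        assert post.beta_approx.mean == pytest.approx(0.5, abs=0.01)

    def test_mw_parameter_recovery(self):
        """Data simulated at known Omega recover it within 3 posterior SDs in
        nearly all replications."""
        omega_true = 0.7
        rng = np.random.default_rng(123)
        hits = 0
        reps = 200
        for _ in range(reps):
            e = rng.exponential(1 / (1 - omega_true), 30)
            c = rng.exponential(1 / omega_true, 30)
            post = mann_whitney(e, c)  # harmonic mean 30 -> large method
            fit = post.beta_approx
            sd = np.sqrt(fit.variance)
            hits += abs(fit.mean - omega_true) <= 3 * sd
        assert hits >= 0.99 * reps

    def test_method_autoselection(self, paired_ten_blocks):
        y1, y2 = paired_ten_blocks
        assert wilcoxon(y1, y2, samples=2000, seed=0, quiet=True).method_used == "small"
        rng = np.random.default_rng(0)
        big1, big2 = rng.normal(size=30), rng.normal(size=30)
        assert wilcoxon(big1, big2 + 0.1).method_used == "large"
        assert mann_whitney(big1, big2).method_used == "large"
        assert (
            mann_whitney(big1[:10], big2, samples=1000, seed=0, quiet=True).method_used
            == "small"
        )  # harmonic mean 15 < 19

    def test_seed_reproducibility(self):
        stats = MannWhitneyStats(16, 4, 5, 4)
        a = mann_whitney_small_posterior(stats, samples=5000, seed=7, quiet=True)
        b = mann_whitney_small_posterior(stats, samples=5000, seed=7, quiet=True)
        np.testing.assert_array_equal(a.discrete.probs, b.discrete.probs)


class TestPriorUse:
    def test_informative_prior_shifts_posterior(self):
        stats = WilcoxonStats(32, 13, 9)
        flat = wilcoxon_exact_posterior(stats)
        skeptical = wilcoxon_exact_posterior(stats, prior=BetaParams(1, 9))
        assert skeptical.posterior_mean < flat.posterior_mean
        assert skeptical.prior_prob_gt_half < 0.01
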