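"""Empirical-Bayes prior fitting, conjugate updating, and credible intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from assocnet import (
    BetaPrior,
    DyadCounts,
    counts_from_periods,
    credible_interval,
    draw_posterior_networks,
    fit_empirical_prior,
    posterior_point,
    posterior_update,
)
from assocnet.bayes_edges import split_periods
from assocnet.simnet import SamplingPeriods
from assocnet.util import dyads_from_square, square_from_dyads

from _oracles import beta_quantile_bisect, log_marginal_grid_max


def counts_from_vectors(d, s):
    """Build DyadCounts for the smallest network holding len(d) dyads."""
    d = np.asarray(d)
    n = int(np.ceil((1 + np.sqrt(1 + 8 * d.size)) / 2))
    n_dyads = n * (n - 1) // 2
    d_full = np.zeros(n_dyads, dtype=np.int64)
    s_full = np.zeros(n_dyads, dtype=np.int64)
    d_full[: d.size] = d
    s_full[: d.size] = s
    return DyadCounts(d=square_from_dyads(d_full, n), s=square_from_dyads(s_full, n))


class TestFitEmpiricalPrior:
    def test_recovers_beta_binomial_parameters(self, rng):
        a0, b0 = 2.0, 5.0
        theta = rng.beta(a0, b0, size=500)
        d = rng.binomial(50, theta)
        counts = counts_from_vectors(d, np.full(500, 50))
        prior = fit_empirical_prior(counts)
        assert abs(prior.a - a0) / a0 < 0.3
        assert abs(prior.b - b0) / b0 < 0.3
        assert prior.n_dyads_used == 500

        # grid-search oracle of the same marginal objective
        mask = dyads_from_square(counts.s) > 0
        dv = dyads_from_square(counts.d)[mask]
        sv = dyads_from_square(counts.s)[mask]
        grid_best, _, _ = log_marginal_grid_max(
            dv, sv, np.geomspace(0.5, 8, 100), np.geomspace(1, 20, 100)
        )
        assert prior.fit_log_marginal >= grid_best - 1e-6

    def test_two_dyads_match_grid_search(self):
        # two identical half-and-half dyads: no overdispersion, so the fit is
        # boundary-attracted; the optimizer must still beat a fine grid search
        counts = counts_from_vectors([1, 1], [2, 2])
        with pytest.warns(RuntimeWarning, match="bound"):
            prior = fit_empirical_prior(counts)
        mask = dyads_from_square(counts.s) > 0
        dv = dyads_from_square(counts.d)[mask]
        sv = dyads_from_square(counts.s)[mask]
        grid_best, _, _ = log_marginal_grid_max(
            dv, sv, np.geomspace(1e-3, 1e3, 200), np.geomspace(1e-3, 1e3, 200)
        )
        assert prior.fit_log_marginal >= grid_best - 1e-6

    def test_single_dyad_rejected(self):
        counts = counts_from_vectors([1], [2])
        with pytest.raises(ValueError, match="at least 2"):
            fit_empirical_prior(counts)

    def test_deterministic(self, counts20):
        p1 = fit_empirical_prior(counts20)
        p2 = fit_empirical_prior(counts20)
        assert (p1.a, p1.b) == (p2.a, p2.b)


class TestPosteriorUpdate:
    def test_uniform_prior_three_observations(self):
        obs = SamplingPeriods(n_nodes=2, together=np.array([[1], [0], [1]]))
        post = posterior_update(counts_from_periods(obs), BetaPrior(1.0, 1.0))
        assert post.alpha[0, 1] == pytest.approx(3.0)
        assert post.beta[0, 1] == pytest.approx(2.0)
        assert posterior_point(post)[0, 1] == pytest.approx(2 / 3)

    def test_unsampled_dyad_keeps_prior(self):
        counts = counts_from_vectors([2, 0], [5, 0])
        post = posterior_update(counts, BetaPrior(1.5, 2.5))
        iu, ju = np.triu_indices(counts.n_nodes, k=1)
        i, j = iu[1], ju[1]
        assert post.alpha[i, j] == 1.5 and post.beta[i, j] == 2.5
        assert post.unsampled[i, j]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            counts_from_vectors([3], [2])

    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30)).map(
                lambda t: (min(t), max(t))
            ),
            min_size=1,
            max_size=6,
        ),
        st.integers(1, 10**6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conjugacy_batch_equals_sequential(self, ds_pairs, split_seed):
        # updating with concatenated data equals composing the updates
        d = np.array([p[0] for p in ds_pairs])
        s = np.array([p[1] for p in ds_pairs])
        rng = np.random.default_rng(split_seed)
        d1 = rng.integers(0, d + 1)
        s1 = np.minimum(s, d1 + rng.integers(0, s - d + 1))
        prior = BetaPrior(0.7, 1.3)
        batch = posterior_update(counts_from_vectors(d, s), prior)
        first = posterior_update(counts_from_vectors(d1, s1), prior)
        rest = counts_from_vectors(d - d1, s - s1)
        # the first posterior is (elementwise) the prior of the second update
        alpha2 = first.alpha + rest.d
        beta2 = first.beta + (rest.s - rest.d)
        np.fill_diagonal(alpha2, 0)
        np.fill_diagonal(beta2, 0)
        assert np.array_equal(alpha2, batch.alpha)
        assert np.array_equal(beta2, batch.beta)


class TestPosteriorPoint:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(3, 2, 2 / 3), (1, 5, 0.0), (5, 1, 1.0), (2, 2, 0.5)],
    )
    def test_mode(self, a, b, expected):
        post = posterior_update(
            counts_from_vectors([0], [0]), BetaPrior(float(a), float(b))
        )
        assert posterior_point(post)[0, 1] == pytest.approx(expected)

    def test_bathtub_falls_back_to_mean(self):
        post = posterior_update(counts_from_vectors([0], [0]), BetaPrior(0.5, 0.5))
        with pytest.warns(RuntimeWarning, match="no interior mode"):
            assert posterior_point(post)[0, 1] == pytest.approx(0.5)


class TestCredibleInterval:
    def test_uniform_prior_interval(self):
        post = posterior_update(counts_from_vectors([0], [0]), BetaPrior(1.0, 1.0))
        est = credible_interval(post, level=0.95)
        assert est.lower[0, 1] == pytest.approx(0.025)
        assert est.upper[0, 1] == pytest.approx(0.975)
        assert est.method == "bayes"

    def test_matches_bisection_oracle(self):
        post = posterior_update(counts_from_vectors([2], [3]), BetaPrior(1.0, 1.0))
        est = credible_interval(post)  # Beta(3, 2)
        assert est.lower[0, 1] == pytest.approx(
            beta_quantile_bisect(0.025, 3, 2), abs=1e-9
        )
        assert est.upper[0, 1] == pytest.approx(
            beta_quantile_bisect(0.975, 3, 2), abs=1e-9
        )

    def test_interval_mass_equals_level(self, rng):
        # posterior mass inside the equal-tailed interval equals the level
        a = rng.uniform(0.2, 50, size=200)
        b = rng.uniform(0.2, 50, size=200)
        for level in (0.5, 0.9, 0.95, 0.99):
            lo = beta_dist.ppf((1 - level) / 2, a, b)
            hi = beta_dist.ppf((1 + level) / 2, a, b)
            mass = beta_dist.cdf(hi, a, b) - beta_dist.cdf(lo, a, b)
            assert np.all(np.abs(mass - level) <= 1e-8)

    def test_level_approaching_one_spans_unit_interval(self):
        post = posterior_update(counts_from_vectors([2], [3]), BetaPrior(1.0, 1.0))
        est = credible_interval(post, level=1 - 1e-9)
        assert est.lower[0, 1] == pytest.approx(0.0, abs=1e-2)
        assert est.upper[0, 1] == pytest.approx(1.0, abs=1e-2)

    def test_width_decreases_with_sampling(self, rng):
        import warnings as _warnings

        theta = 0.3
        widths = []
        for s in (5, 20, 80):
            d = rng.binomial(s, theta, size=210)
            counts = counts_from_vectors(d, np.full(210, s))
            with _warnings.catch_warnings():
                # homogeneous dyads have no overdispersion: the prior fit is
                # legitimately boundary-attracted and warns
                _warnings.simplefilter("ignore", RuntimeWarning)
                est = credible_interval(
                    posterior_update(counts, fit_empirical_prior(counts))
                )
            widths.append(dyads_from_square(est.width)[:210].mean())
        assert widths[0] > widths[1] > widths[2]

    def test_prior_matched_coverage(self):
        # truth drawn from the same beta family the prior fit recovers:
        # equal-tailed 95% intervals must cover ~95% of true edge weights
        rng = np.random.default_rng(123)
        n_dyads, s = 10_585, 20
        theta = rng.beta(2.0, 5.0, size=n_dyads)
        d = rng.binomial(s, theta)
        counts = counts_from_vectors(d, np.full(n_dyads, s))
        est = credible_interval(posterior_update(counts, fit_empirical_prior(counts)))
        lo = dyads_from_square(est.lower)[:n_dyads]
        hi = dyads_from_square(est.upper)[:n_dyads]
        coverage = np.mean((theta >= lo) & (theta <= hi))
        tol = 3 * np.sqrt(0.95 * 0.05 / n_dyads)
        assert abs(coverage - 0.95) <= tol


class TestPosteriorDraws:
    def test_concentrated_posterior(self):
        post = posterior_update(counts_from_vectors([0, 0, 0], [0, 0, 0]),
                                BetaPrior(1e6, 1.0))
        draws = draw_posterior_networks(post, 10, seed=0)
        vals = np.concatenate([dyads_from_square(m) for m in draws])
        assert np.all(vals > 0.99)

    def test_draw_mean_matches_beta_mean(self):
        post = posterior_update(counts_from_vectors([2], [3]), BetaPrior(1.0, 1.0))
        draws = draw_posterior_networks(post, 100, seed=1)
        vals = np.array([m[0, 1] for m in draws])
        se = np.sqrt(3 * 2 / (25 * 6)) / 10  # Beta(3,2) sd over sqrt(100)
        assert abs(vals.mean() - 0.6) <= 3 * se

    def test_reproducible_given_seed(self, counts20):
        post = posterior_update(counts20, BetaPrior(1.0, 1.0))
        a = draw_posterior_networks(post, 5, seed=2)
        b = draw_posterior_networks(post, 5, seed=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, draw_posterior_networks(post, 5, seed=3))

    def test_draws_symmetric(self, counts20):
        post = posterior_update(counts20, BetaPrior(1.0, 1.0))
        draws = draw_posterior_networks(post, 3, seed=4)
        assert np.allclose(draws, draws.transpose(0, 2, 1))
        assert np.all(draws.diagonal(axis1=1, axis2=2) == 0)


class TestHoldoutSplit:
    def test_split_halves(self, obs20):
        fit_part, rest = split_periods(obs20, 0.5)
        assert fit_part.n_periods == 10 and rest.n_periods == 10
        stacked = np.vstack([fit_part.together, rest.together])
        assert np.array_equal(stacked, obs20.together)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2])
    def test_invalid_fraction(self, obs20, fraction):
        with pytest.raises(ValueError):
            split_periods(obs20, fraction)
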