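"""Prior sampling, importance weighting, resampling and marginal likelihoods."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

import humpback as hb
from humpback import sir
from humpback.catches import LossRateDraw


class TestSamplePrior:
    def test_uniform_rmax_moments(self, priors):
        spec = hb.load_scenario("RC")
        draws = sir.sample_prior(spec, 100_000, np.random.default_rng(0), priors)
        se = (sir.RMAX_UPPER / np.sqrt(12)) / np.sqrt(100_000)
        assert draws["r_max"].mean() == pytest.approx(0.059, abs=3 * se)
        assert draws["r_max"].between(0, sir.RMAX_UPPER).all()
        assert draws["theta"].between(0, 1).all()
        assert draws["n_recent"].between(500, 40_000).all()

    def test_informative_rmax_prior_interval(self, priors):
        # life-history prior: ~95% of mass in [0.05, 0.114], hard cap 0.118
        spec = hb.load_scenario("D-7")
        draws = sir.sample_prior(spec, 100_000, np.random.default_rng(1), priors)
        inside = draws["r_max"].between(0.05, 0.114).mean()
        assert inside == pytest.approx(0.95, abs=0.02)
        assert draws["r_max"].max() <= sir.RMAX_UPPER

    def test_recent_year_anchoring(self):
        assert hb.load_scenario("D-1").recent_year == 2012
        assert hb.load_scenario("RC").recent_year == 2008

    def test_slr_columns_follow_mode(self, priors):
        rng = np.random.default_rng(2)
        none = sir.sample_prior(hb.load_scenario("C-3"), 100, rng, priors)
        assert (none["slr_premodern"] == 1.0).all()
        assert (none["slr_modern"] == 1.0).all()
        split = sir.sample_prior(hb.load_scenario("C-4"), 100, rng, priors)
        assert (split["slr_early_modern"] != split["slr_modern"]).all()


class TestResampling:
    def test_equal_weights_resample_uniformly(self):
        rng = np.random.default_rng(0)
        idx = sir.sir_resample(np.ones(10), 100_000, rng)
        counts = np.bincount(idx, minlength=10)
        assert stats.chisquare(counts).pvalue > 0.001

    def test_single_positive_weight_degenerates(self):
        rng = np.random.default_rng(0)
        w = np.zeros(5)
        w[3] = 2.0
        assert (sir.sir_resample(w, 1_000, rng) == 3).all()

    def test_one_three_weights_split_25_75(self):
        rng = np.random.default_rng(1)
        idx = sir.sir_resample([1.0, 3.0], 100_000, rng)
        share = np.mean(idx == 1)
        se = np.sqrt(0.75 * 0.25 / 100_000)
        assert share == pytest.approx(0.75, abs=3 * se)

    def test_all_zero_weights_raise(self):
        with pytest.raises(ValueError, match="no feasible draws"):
            sir.sir_resample(np.zeros(4), 10, np.random.default_rng(0))


class TestDiagnostics:
    def test_equal_weights_give_full_ess(self):
        d = sir.diagnostics(np.ones(250))
        assert d["ess"] == pytest.approx(250.0)

    def test_single_weight_gives_unit_ess(self):
        d = sir.diagnostics([0.0, 5.0, 0.0])
        assert d["ess"] == pytest.approx(1.0)
        assert d["max_weight_share"] == pytest.approx(1.0)

    def test_hand_computed_case(self):
        d = sir.diagnostics([1.0, 1.0, 2.0])
        assert d["ess"] == pytest.approx(16.0 / 6.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sir.diagnostics([])


class TestLogMarginal:
    def test_equal_weights_recover_log_weight(self):
        lw = np.full(100, np.log(0.37))
        assert sir.estimate_log_marginal(lw) == pytest.approx(np.log(0.37))

    def test_identical_draws_give_identical_marginals(self):
        rng = np.random.default_rng(0)
        lw = rng.normal(-3, 1, 1_000)
        assert sir.estimate_log_marginal(lw) == sir.estimate_log_marginal(lw.copy())

    def test_monte_carlo_matches_quadrature_on_toy_model(self):
        # y ~ N(mu, 1), mu ~ U[0, 1]: marginal = Phi(y) - Phi(y - 1)
        rng = np.random.default_rng(42)
        y = 0.3
        mu = rng.uniform(0, 1, 200_000)
        lw = stats.norm.logpdf(y, mu, 1.0)
        estimate = np.exp(sir.estimate_log_marginal(lw))
        exact = stats.norm.cdf(y) - stats.norm.cdf(y - 1.0)
        assert estimate == pytest.approx(exact, rel=0.01)

    def test_all_zero_weights_are_minus_infinity(self):
        assert sir.estimate_log_marginal(np.full(5, -np.inf)) == -np.inf


class TestEvaluateDraw:
    def _zero_catch_tables(self):
        pre = pd.DataFrame(
            {"start_year": [1830], "end_year": [1830], "brazil_min": [0],
             "brazil_max": [0], "pelagic": [0]}
        )
        mod = pd.DataFrame(
            {"year": [1904], "core": [0.0], "falkland": [0.0], "fringe": [0.0],
             "overlap": [0.0]}
        )
        return hb.CatchTables(pre, mod)

    def test_zero_catch_exact_estimate_gives_single_term(self):
        tables = self._zero_catch_tables()
        spec = hb.load_scenario("RC")
        obs = hb.ObservationSet(
            absolute=pd.DataFrame(
                {"series_id": "ABS", "year": [2008], "estimate": [12_000.0],
                 "cv": [0.1]}
            )
        )
        draw = sir.ParameterDraw(0.08, 0.5, 12_000.0, LossRateDraw())
        done = sir.evaluate_draw(draw, spec, obs, tables)
        assert done.feasible
        assert done.K == pytest.approx(12_000.0, rel=1e-6)
        sigma = hb.lognormal_sigma(0.1)
        expected = -0.5 * np.log(2 * np.pi) - np.log(sigma)
        assert done.loglik == pytest.approx(expected, abs=1e-6)

    def test_infeasible_target_zero_weight(self, obs_rc):
        spec = hb.load_scenario("RC")
        draw = sir.ParameterDraw(0.0, 0.5, 7.0e8, LossRateDraw(1.71, 1.0185, 1.0185))
        done = sir.evaluate_draw(draw, spec, obs_rc)
        assert not done.feasible and done.loglik == -np.inf

    def test_posterior_median_like_draw_solves_plausible_K(self, obs_rc, tables):
        spec = hb.load_scenario("RC")
        draw = sir.ParameterDraw(
            0.088, 0.5, 14_264.0, LossRateDraw(1.71, 1.0185, 1.0185)
        )
        done = sir.evaluate_draw(draw, spec, obs_rc, tables)
        assert done.feasible
        assert 22_821 <= done.K <= 33_578


class TestZeroDataPosterior:
    def test_sir_with_no_data_returns_the_prior(self, tables):
        spec = hb.load_scenario("RC")
        empty = hb.ObservationSet(
            absolute=pd.DataFrame(
                {"series_id": [], "year": [], "estimate": [], "cv": []}
            )
        )
        rng = np.random.default_rng(9)
        post = sir.run_sir(
            spec, rng, n_prior=40_000, n_out=10_000, data=empty, tables=tables
        )
        fresh = np.random.default_rng(10).uniform(0, sir.RMAX_UPPER, 10_000)
        ks = stats.ks_2samp(post.draws["r_max"].to_numpy(), fresh)
        assert ks.pvalue > 0.001

    def test_no_feasible_draws_is_an_error(self, tables, obs_rc):
        import dataclasses

        # a floor above the whole prior support kills every trajectory
        spec = dataclasses.replace(hb.load_scenario("G-1"), n_floor=1.0e9)
        rng = np.random.default_rng(0)
        with pytest.raises(RuntimeError, match="no feasible draws"):
            sir.run_sir(spec, rng, n_prior=200, n_out=50, data=obs_rc, tables=tables)


class TestSeedStability:
    def test_rc_posterior_median_K_stable_across_seeds(self):
        medians = []
        for seed in (101, 202):
            res = hb.run_scenario("RC", np.random.default_rng(seed))
            medians.append(res.posterior.draws["K"].median())
        assert abs(medians[0] - medians[1]) / medians[0] < 0.02
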