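"""Lognormal likelihood terms, the marginalized-catchability index likelihood
and the genetic floor."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

import humpback as hb
from humpback import likelihoods


class TestLognormalSigma:
    def test_closed_form_values(self):
        assert hb.lognormal_sigma(0.084) == pytest.approx(0.08385, abs=5e-5)
        assert hb.lognormal_sigma(1.0) == pytest.approx(math.sqrt(math.log(2.0)))

    def test_vanishes_with_cv(self):
        assert hb.lognormal_sigma(1e-9) < 2e-9

    def test_nonpositive_cv_rejected(self):
        with pytest.raises(ValueError):
            hb.lognormal_sigma(0.0)


class TestAbsoluteAbundance:
    def test_exact_fit_attains_the_maximum(self, flat_trajectory, series_frame):
        est = series_frame([2008, 2012], [15_000.0, 15_000.0], [0.084, 0.071])
        exact = hb.abs_abundance_loglik(flat_trajectory(15_000.0), est)
        for off in (0.9, 1.1):
            assert hb.abs_abundance_loglik(flat_trajectory(off * 15_000.0), est) < exact

    def test_doubling_a_residual_quadruples_its_penalty(
        self, flat_trajectory, series_frame
    ):
        est = series_frame([2008], [10_000.0], [0.1])
        base = hb.abs_abundance_loglik(flat_trajectory(10_000.0), est)
        one = hb.abs_abundance_loglik(flat_trajectory(10_000.0 * math.e**0.05), est)
        two = hb.abs_abundance_loglik(flat_trajectory(10_000.0 * math.e**0.10), est)
        assert (two - base) == pytest.approx(4 * (one - base), rel=1e-9)

    def test_matches_direct_density_evaluation(self, flat_trajectory, series_frame):
        # 2008 estimate 14264 against a model abundance of 14913
        est = series_frame([2008], [14_264.0], [0.084])
        value = hb.abs_abundance_loglik(flat_trajectory(14_913.0), est)
        sigma = math.sqrt(math.log(1 + 0.084**2))
        oracle = norm.logpdf(math.log(14_264.0), math.log(14_913.0), sigma)
        assert value == pytest.approx(float(oracle), rel=1e-12)

    def test_nonpositive_model_abundance_gives_zero_weight(self, series_frame):
        traj = hb.Trajectory(1830, np.zeros(201), valid=True)
        est = series_frame([2008], [14_264.0], [0.084])
        assert hb.abs_abundance_loglik(traj, est) == -np.inf


def quadrature_marginal(series, log_model):
    """Independent oracle: integrate the index likelihood over log-catchability
    on a fine grid."""
    sigma = np.sqrt(np.log1p(series["cv"].to_numpy() ** 2))
    e = np.log(series["estimate"].to_numpy()) - log_model
    grid = np.linspace(e.min() - 12, e.max() + 12, 40_001)
    log_int = norm.logpdf(e[:, None], grid[None, :], sigma[:, None]).sum(axis=0)
    from scipy.special import logsumexp

    return float(logsumexp(log_int) + np.log(grid[1] - grid[0]))


class TestIndexMarginal:
    def test_single_observation_is_trajectory_independent(
        self, flat_trajectory, series_frame
    ):
        series = series_frame([2008], [5_000.0], [0.1])
        a = hb.index_marginal_loglik(flat_trajectory(4_000.0), series)
        b = hb.index_marginal_loglik(flat_trajectory(30_000.0), series)
        assert a == pytest.approx(b, abs=1e-12)

    def test_two_equal_sigma_points_depend_only_on_residual_difference(
        self, series_frame
    ):
        # same e1 - e2 under two different trajectories -> same likelihood
        series = series_frame([2000, 2010], [1_000.0, 2_000.0], [0.2, 0.2])
        vals = np.full(201, 8_000.0)
        t1 = hb.Trajectory(1830, vals, True)
        t2 = hb.Trajectory(1830, vals * 3.7, True)
        a = hb.index_marginal_loglik(t1, series)
        b = hb.index_marginal_loglik(t2, series)
        assert a == pytest.approx(b, abs=1e-10)

    def test_matches_quadrature_oracle_on_randomized_cases(self, series_frame):
        rng = np.random.default_rng(11)
        for _ in range(6):
            n = int(rng.integers(2, 7))
            years = np.arange(2000, 2000 + n)
            cvs = rng.uniform(0.05, 0.9, n)
            model = rng.uniform(2_000, 30_000, n)
            idx = rng.uniform(0.1, 3.0) * model * np.exp(rng.normal(0, 0.3, n))
            series = series_frame(years, idx, cvs)
            vals = np.full(201, 1.0)
            vals[years - 1830] = model
            traj = hb.Trajectory(1830, vals, True)
            value = hb.index_marginal_loglik(traj, series)
            oracle = quadrature_marginal(series, np.log(model))
            assert value == pytest.approx(oracle, rel=1e-6, abs=1e-6)

    @given(st.floats(0.01, 100.0))
    def test_invariant_to_rescaling_the_whole_series(self, scale):
        import pandas as pd

        series = pd.DataFrame(
            {"year": [2000, 2005, 2010], "estimate": [500.0, 900.0, 1_500.0],
             "cv": [0.3, 0.2, 0.25]}
        )
        scaled = series.assign(estimate=series["estimate"] * scale)
        vals = np.full(201, 10_000.0)
        vals[[170, 175, 180]] = [9_000.0, 11_000.0, 14_000.0]
        traj = hb.Trajectory(1830, vals, True)
        a = hb.index_marginal_loglik(traj, series)
        b = hb.index_marginal_loglik(traj, scaled)
        assert a == pytest.approx(b, abs=1e-9)

    def test_empty_series_rejected(self, flat_trajectory, series_frame):
        with pytest.raises(ValueError):
            hb.index_marginal_loglik(
                flat_trajectory(1_000.0), series_frame([], [], [])
            )


class TestGeneticFloor:
    @pytest.mark.parametrize(
        "n_min, n_floor, expected",
        [(440, 162, True), (100, 162, False), (5, 0, True), (162, 162, True)],
    )
    def test_indicator(self, n_min, n_floor, expected):
        assert hb.genetic_floor_indicator(n_min, n_floor) is expected

    @pytest.mark.parametrize("h, floor", [(54, 162), (5, 15), (0, 0)])
    def test_haplotype_floor(self, h, floor):
        assert hb.n_floor_from_haplotypes(h) == floor

    def test_negative_haplotypes_rejected(self):
        with pytest.raises(ValueError):
            hb.n_floor_from_haplotypes(-1)


class TestTotalLoglik:
    def test_floor_violation_is_exactly_minus_infinity(
        self, flat_trajectory, series_frame
    ):
        obs = hb.ObservationSet(
            absolute=series_frame([2008], [14_264.0], [0.084], "ABS")
        )
        vals = np.full(201, 14_264.0)
        vals[120] = 100.0  # dip below a 162-whale floor
        traj = hb.Trajectory(1830, vals, True)
        ll = hb.total_loglik(traj, obs, n_floor=162)
        assert ll.total == -np.inf and not ll.floor_ok
        ll_free = hb.total_loglik(traj, obs, n_floor=0)
        assert np.isfinite(ll_free.total)

    def test_components_sum_to_total(self, flat_trajectory):
        obs = hb.load_observation_set(("FG", "BG1"))
        traj = flat_trajectory(14_000.0)
        ll = hb.total_loglik(traj, obs)
        assert ll.total == pytest.approx(sum(ll.components.values()))
        assert set(ll.components) == {"ABS", "FG", "BG1"}

    def test_invalid_trajectory_gets_zero_weight(self, series_frame):
        obs = hb.ObservationSet(
            absolute=series_frame([2008], [14_264.0], [0.084], "ABS")
        )
        traj = hb.Trajectory(1830, np.full(201, 5_000.0), valid=False)
        assert hb.total_loglik(traj, obs).total == -np.inf


class TestBatchForms:
    def test_batch_matches_scalar_paths(self, series_frame):
        rng = np.random.default_rng(3)
        obs = hb.load_observation_set(("FG", "BG1"))
        years = sorted(
            set(obs.absolute["year"]).union(*[set(s["year"]) for s in obs.indices.values()])
        )
        for _ in range(5):
            vals = np.full(201, 0.0) + rng.uniform(3_000, 30_000)
            traj = hb.Trajectory(1830, vals, True)
            log_model = {int(y): np.array([math.log(traj.at(y))]) for y in years}
            batch = likelihoods.abs_loglik_batch(log_model, obs.absolute)
            for sid in obs.indices:
                batch = batch + likelihoods.index_marginal_loglik_batch(
                    log_model, obs.indices[sid]
                )
            assert batch[0] == pytest.approx(hb.total_loglik(traj, obs).total, rel=1e-12)
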