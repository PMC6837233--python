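import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import humpback as hb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables():
    return hb.load_catch_tables()


@pytest.fixture(scope="session")
def priors():
    return hb.load_loss_rate_priors()


@pytest.fixture(scope="session")
def obs_rc():
    return hb.load_observation_set(("FG", "BG1"))


@pytest.fixture(scope="session")
def rc_removals(tables):
    """Reference-case removal series at theta = 0.5 and prior-mean loss factors."""
    spec = hb.load_scenario("RC")
    slr = hb.LossRateDraw(premodern_factor=1.71, modern_factor=1.0185)
    return hb.assemble_removals(spec, 0.5, slr, tables)


@pytest.fixture(scope="session")
def assessment():
    """Full model-averaged assessment: the nine averaging scenarios at
    2e5 prior draws each, combined by Bayes factors."""
    results, averaged = hb.run_assessment(seed=1)
    return results, averaged


@pytest.fixture(scope="session")
def floor_comparison_runs():
    """RC, G-1 and G-2 run from identical seeds so the only difference is the
    genetic floor on minimum abundance."""
    runs = {}
    for name in ("RC", "G-1", "G-2"):
        runs[name] = hb.run_scenario(name, np.random.default_rng(7))
    return runs


@pytest.fixture(scope="session")
def catch_sensitivity_runs():
    """C-1 and C-2 (pre-modern catches excluded) for direction checks."""
    return {
        name: hb.run_scenario(name, np.random.default_rng(3))
        for name in ("C-1", "C-2")
    }


@pytest.fixture
def flat_trajectory():
    """A constant synthetic trajectory, handy for likelihood unit tests."""

    def make(level: float, start_year: int = 1830, end_year: int = 2030):
        n = end_year - start_year + 1
        return hb.Trajectory(
            start_year=start_year, values=np.full(n, float(level)), valid=True
        )

    return make


@pytest.fixture
def series_frame():
    """Build an abundance-series frame from parallel lists."""

    def make(years, estimates, cvs, series_id="X"):
        return pd.DataFrame(
            {
                "series_id": series_id,
                "year": list(years),
                "estimate": list(estimates),
                "cv": list(cvs),
            }
        )

    return make
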