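"""Annual removal series for the assessment.

Landed-catch records become total removals in three steps: period totals are
annualized (uniform spread over the period's years, with the fixed pelagic
component added), the pre-modern series is interpolated between its minimum
and maximum reconstructions by a single parameter theta in [0, 1], and
era-specific struck-and-lost rate (SLR) factors scale landings up to total
kills.  Everything here is deterministic given (scenario, theta, SLR draw);
the factors themselves are sampled once per parameter draw from the priors in
the loss-rate table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import (
    CatchTables,
    LossRatePrior,
    ScenarioSpec,
    load_catch_tables,
    load_loss_rate_priors,
)

__all__ = [
    "FIRST_YEAR",
    "LAST_CATCH_YEAR",
    "EARLY_MODERN_WINDOW",
    "AnnualCatchSeries",
    "LossRateDraw",
    "RemovalSeries",
    "annualize_periods",
    "interpolate_premodern",
    "sample_loss_rates",
    "assemble_removals",
    "modern_allocation_series",
]

FIRST_YEAR = 1830
LAST_CATCH_YEAR = 1972
#: Early-modern whaling years receiving the separate C-4 loss-rate factor.
EARLY_MODERN_WINDOW = (1904, 1918)

_N_CATCH_YEARS = LAST_CATCH_YEAR - FIRST_YEAR + 1


@dataclass(frozen=True)
class AnnualCatchSeries:
    """Catches per year 1830-1972, before loss-rate correction.

    ``premodern_min``/``premodern_max`` bracket the pre-modern reconstruction
    (coastal Brazil plus the fixed pelagic component); ``modern`` is the
    landed catch under one allocation hypothesis.
    """

    years: np.ndarray
    premodern_min: np.ndarray
    premodern_max: np.ndarray
    modern: np.ndarray

    def __post_init__(self) -> None:
        if (self.premodern_min > self.premodern_max + 1e-12).any():
            raise ValueError("premodern_min exceeds premodern_max")
        for arr in (self.premodern_min, self.premodern_max, self.modern):
            if (np.asarray(arr) < 0).any():
                raise ValueError("negative annual catch")


@dataclass(frozen=True)
class LossRateDraw:
    """One draw of the era-specific struck-and-lost factors (>= 1)."""

    premodern_factor: float = 1.0
    modern_factor: float = 1.0
    early_modern_factor: float = 1.0


@dataclass(frozen=True)
class RemovalSeries:
    """Total corrected removals per year; zero after 1972."""

    years: np.ndarray
    removals: np.ndarray

    def at(self, year: int) -> float:
        if year < FIRST_YEAR or year > LAST_CATCH_YEAR:
            return 0.0
        return float(self.removals[year - FIRST_YEAR])


def annualize_periods(premodern, modern=None) -> AnnualCatchSeries:
    """Spread each period's totals uniformly over its years.

    The pre-modern table reports totals per multi-year period; lacking any
    within-period information, each total is divided evenly across the
    period's years (fractional annual catches are fine - the modern table
    already contains fractions).  The pelagic column is annualized the same
    way and added to both the min and max series.
    """
    years = np.arange(FIRST_YEAR, LAST_CATCH_YEAR + 1)
    pre_min = np.zeros(_N_CATCH_YEARS)
    pre_max = np.zeros(_N_CATCH_YEARS)
    spans = sorted(zip(premodern["start_year"], premodern["end_year"]))
    for (_, e0), (s1, _) in zip(spans, spans[1:]):
        if s1 <= e0:
            raise ValueError("overlapping pre-modern periods")
    for row in premodern.itertuples(index=False):
        n_years = int(row.end_year) - int(row.start_year) + 1
        sl = slice(int(row.start_year) - FIRST_YEAR, int(row.end_year) - FIRST_YEAR + 1)
        pre_min[sl] += (row.brazil_min + row.pelagic) / n_years
        pre_max[sl] += (row.brazil_max + row.pelagic) / n_years
    mod = np.zeros(_N_CATCH_YEARS)
    if modern is not None:
        mod[np.asarray(modern["year"]) - FIRST_YEAR] = np.asarray(
            modern.iloc[:, 1], dtype=float
        )
    return AnnualCatchSeries(years, pre_min, pre_max, mod)


def modern_allocation_series(tables: CatchTables, allocation: str) -> np.ndarray:
    """Annual modern landings (1830-1972 grid) for one allocation hypothesis."""
    mod = tables.modern
    if allocation == "core":
        values = mod["core"].to_numpy(float)
    elif allocation == "core+falkland":
        values = (mod["core"] + mod["falkland"]).to_numpy(float)
    elif allocation in ("fringe", "overlap"):
        values = mod[allocation].to_numpy(float)
    else:
        raise ValueError(f"unknown allocation {allocation!r}")
    out = np.zeros(_N_CATCH_YEARS)
    out[mod["year"].to_numpy() - FIRST_YEAR] = values
    return out


def interpolate_premodern(theta: float, series: AnnualCatchSeries) -> np.ndarray:
    """Pre-modern catch in each year: C_t = C_t,min + theta * (C_t,max - C_t,min)."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    return series.premodern_min + theta * (series.premodern_max - series.premodern_min)


def _sample_factor(prior: LossRatePrior, rng: np.random.Generator, size):
    """Draw factor(s) from a truncated prior family."""
    if prior.family == "normal":
        a = (prior.lower_trunc - prior.location) / prior.scale
        b = (prior.upper_trunc - prior.location) / prior.scale
        return stats.truncnorm.rvs(
            a, b, loc=prior.location, scale=prior.scale, size=size, random_state=rng
        )
    if prior.family == "offset_halfnormal":
        # factor = location + lambda, lambda ~ half-normal(scale) truncated so
        # the factor stays below upper_trunc.
        upper = (prior.upper_trunc - prior.location) / prior.scale
        u = rng.uniform(0.0, stats.halfnorm.cdf(upper), size=size)
        return prior.location + prior.scale * stats.halfnorm.ppf(u)
    raise ValueError(f"unknown loss-rate prior family {prior.family!r}")


def sample_loss_rates(
    priors: dict[str, LossRatePrior],
    mode: str,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Sample struck-and-lost factors for one scenario mode.

    Modes: ``both_eras`` (pre-modern and modern factors from their priors),
    ``none`` (all factors 1), ``modern_only`` (pre-modern factor 1),
    ``C4_split`` (as both_eras plus a separate early-modern factor applied to
    1904-1918 modern catches).  With ``size`` given, vectorized arrays are
    returned for use by the importance sampler.
    """
    n = 1 if size is None else size
    ones = np.ones(n)
    if mode == "none":
        pre = mod = early = ones
    elif mode == "modern_only":
        pre = ones
        mod = _sample_factor(priors["modern"], rng, n)
        early = mod
    elif mode == "both_eras":
        pre = _sample_factor(priors["premodern"], rng, n)
        mod = _sample_factor(priors["modern"], rng, n)
        early = mod
    elif mode == "C4_split":
        pre = _sample_factor(priors["premodern"], rng, n)
        mod = _sample_factor(priors["modern"], rng, n)
        early = _sample_factor(priors["early_modern_C4"], rng, n)
    else:
        raise ValueError(f"unknown slr_mode {mode!r}")
    if size is None:
        return LossRateDraw(float(pre[0]), float(mod[0]), float(early[0]))
    return LossRateDraw(pre, mod, early)


def assemble_removals(
    spec: ScenarioSpec,
    theta: float,
    slr: LossRateDraw,
    tables: CatchTables | None = None,
) -> RemovalSeries:
    """Total removal series for one scenario and parameter draw.

    removal_t = SLR_pre * C_t^premodern(theta) + SLR_era(t) * C_t^modern,
    where the early-modern factor replaces the modern factor in 1904-1918
    under the C-4 split and the pre-modern component is zeroed when the
    scenario excludes it.
    """
    if tables is None:
        tables = load_catch_tables()
    series = annualize_periods(tables.premodern)
    years = series.years
    removals = np.zeros_like(series.premodern_min)
    if spec.include_premodern:
        removals += slr.premodern_factor * interpolate_premodern(theta, series)
    modern = modern_allocation_series(tables, spec.allocation)
    early = (years >= EARLY_MODERN_WINDOW[0]) & (years <= EARLY_MODERN_WINDOW[1])
    factor = np.where(early, slr.early_modern_factor, slr.modern_factor)
    removals += factor * modern
    return RemovalSeries(years=years, removals=removals)
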