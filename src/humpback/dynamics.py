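"""Deterministic generalized logistic (Pella-Tomlinson) population dynamics.

The model is

    N_{t+1} = N_t + N_t * r_max * [1 - (N_t / K)^z] - R_t,

with the population at carrying capacity K in 1830, annual removals R_t
through 1972 and zero afterwards, and projection to 2030.  The shape
parameter z places maximum production at a fraction (1+z)^(-1/z) of K
(z = 2.39 gives the conventional 60% level).

Carrying capacity is never assigned a prior.  Instead a prior is placed on a
recent abundance and K is found by the "backwards" approach: bisection on K
until the forward projection passes through the sampled recent abundance.
Abundance at the recent year is strictly increasing in K for fixed
(r_max, z, removals), which is what makes bisection valid; the test suite
checks this monotonicity on grids.

A trajectory that falls below the extinction floor (1 whale) is invalid: the
population is treated as extinct (abundance pinned at zero) and the draw
receives zero weight downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catches import FIRST_YEAR, LAST_CATCH_YEAR, RemovalSeries

__all__ = [
    "EXTINCTION_FLOOR",
    "END_YEAR",
    "STATUS_YEARS",
    "PopulationParams",
    "Trajectory",
    "TrajectoryStats",
    "step",
    "project",
    "solve_K",
    "msyl_fraction",
    "trajectory_stats",
    "project_batch",
    "solve_K_batch",
]

EXTINCTION_FLOOR = 1.0
END_YEAR = 2030
#: Years at which depletion relative to K is reported.
STATUS_YEARS = (2006, 2008, 2012, 2019, 2030)

_K_UPPER_BOUND = 5.0e5  # an order of magnitude above any plausible K
_BISECTION_ITERS = 64


@dataclass(frozen=True)
class PopulationParams:
    K: float
    r_max: float
    z: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.r_max < 0:
            raise ValueError("r_max must be non-negative")
        if self.z <= 0:
            raise ValueError("z must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Annual abundance from ``start_year`` through 2030.

    ``valid`` is False when the trajectory crossed the extinction floor;
    abundances are pinned at zero from that point on.
    """

    start_year: int
    values: np.ndarray
    valid: bool

    def at(self, year: int) -> float:
        return float(self.values[year - self.start_year])

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + len(self.values))


@dataclass(frozen=True)
class TrajectoryStats:
    n_min: float
    year_min: int
    status_by_year: dict[int, float]
    max_depletion: float


def step(N: float, params: PopulationParams, removal: float = 0.0) -> float:
    """One annual update: growth first, removals subtracted after."""
    if N <= 0:
        raise ValueError("step requires positive abundance; trajectory is invalid")
    return N + N * params.r_max * (1.0 - (N / params.K) ** params.z) - removal


def project(
    params: PopulationParams,
    removals: RemovalSeries,
    end_year: int = END_YEAR,
) -> Trajectory:
    """Forward projection from equilibrium at K in 1830.

    Removals apply on the 1830-1972 grid and are zero afterwards.  If
    abundance ever drops below the extinction floor the trajectory is marked
    invalid and held at zero (the generalized-logistic growth term is not
    defined for negative abundance).
    """
    if end_year < LAST_CATCH_YEAR:
        raise ValueError("end_year must not precede the end of the catch series")
    n_years = end_year - FIRST_YEAR + 1
    values = np.empty(n_years)
    values[0] = params.K
    valid = True
    N = params.K
    for i in range(1, n_years):
        year = FIRST_YEAR + i - 1
        if N > 0:
            removal = removals.at(year)
            N = N + N * params.r_max * (1.0 - (N / params.K) ** params.z) - removal
        if N < EXTINCTION_FLOOR:
            N = 0.0
            valid = False
        values[i] = N
    return Trajectory(start_year=FIRST_YEAR, values=values, valid=valid)


def msyl_fraction(z: float) -> float:
    """Fraction of K at which annual production peaks: (1+z)^(-1/z)."""
    if z <= 0:
        raise ValueError("z must be positive")
    return (1.0 + z) ** (-1.0 / z)


def trajectory_stats(traj: Trajectory, K: float) -> TrajectoryStats:
    """Minimum abundance and depletion statuses for a valid trajectory."""
    if not traj.valid:
        raise ValueError("trajectory is invalid (crossed the extinction floor)")
    idx = int(np.argmin(traj.values))
    n_min = float(traj.values[idx])
    statuses = {y: traj.at(y) / K for y in STATUS_YEARS if y <= traj.years[-1]}
    return TrajectoryStats(
        n_min=n_min,
        year_min=traj.start_year + idx,
        status_by_year=statuses,
        max_depletion=n_min / K,
    )


def solve_K(
    n_recent: float,
    recent_year: int,
    r_max: float,
    z: float,
    removals: RemovalSeries,
    rel_tol: float = 1e-8,
) -> float | None:
    """Backwards approach: find K whose projection hits n_recent at recent_year.

    Returns None (a rejected draw, not an exception) when no K in
    [n_recent, 5e5] - expanded by doubling if needed - attains n_recent.
    """
    if n_recent <= 0:
        raise ValueError("n_recent must be positive")
    ks, _ = solve_K_batch(
        np.array([n_recent]), recent_year, np.array([r_max]), z, removals,
        rel_tol=rel_tol,
    )
    return None if np.isnan(ks[0]) else float(ks[0])


# ---------------------------------------------------------------------------
# Vectorized engine used by the importance sampler.  Removals may be supplied
# per draw as a callable year -> array so the (draws x years) matrix is never
# materialized.
# ---------------------------------------------------------------------------


def _removal_fn(removals):
    if isinstance(removals, RemovalSeries):
        return removals.at
    return removals


def project_batch(K, r_max, z, removals, end_year, record_years=()):
    """Project many draws at once.

    Parameters are 1-D arrays of equal length (z may be scalar).  Returns
    (snapshots, n_min, year_min, crashed): ``snapshots`` maps each requested
    record year to the abundance array; minima are tracked over the full
    span 1830..end_year.  Crashed trajectories are pinned at zero.
    """
    rem_at = _removal_fn(removals)
    K = np.asarray(K, float)
    r = np.asarray(r_max, float)
    N = K.copy()
    n_min = K.copy()
    year_min = np.full(K.shape, FIRST_YEAR, dtype=int)
    crashed = np.zeros(K.shape, dtype=bool)
    snapshots = {}
    if FIRST_YEAR in record_years:
        snapshots[FIRST_YEAR] = N.copy()
    for year in range(FIRST_YEAR + 1, end_year + 1):
        removal = rem_at(year - 1)
        N = N + r * N * (1.0 - (N / K) ** z) - removal
        newly_dead = N < EXTINCTION_FLOOR
        if newly_dead.any():
            N = np.where(newly_dead, 0.0, N)
            crashed |= newly_dead
        lower = N < n_min
        if lower.any():
            n_min = np.where(lower, N, n_min)
            year_min = np.where(lower, year, year_min)
        if year in record_years:
            snapshots[year] = N.copy()
    return snapshots, n_min, year_min, crashed


def _recent_abundance(K, r, z, removals, recent_year):
    rem_at = _removal_fn(removals)
    N = K.copy()
    for year in range(FIRST_YEAR, recent_year):
        N = N + r * N * (1.0 - (N / K) ** z) - rem_at(year)
        N = np.where(N < EXTINCTION_FLOOR, 0.0, N)
    return N


def solve_K_batch(
    n_recent,
    recent_year,
    r_max,
    z,
    removals,
    rel_tol: float = 1e-8,
    iters: int = _BISECTION_ITERS,
):
    """Vectorized bisection on K for many draws.

    The lower bracket is the target abundance itself (removals can only push
    the trajectory below its equilibrium start), the upper bracket 5e5 whales
    doubled until it covers the target.  Returns (K, feasible); infeasible
    draws get NaN.
    """
    n_recent = np.asarray(n_recent, float)
    r = np.asarray(r_max, float)
    lo = n_recent.copy()
    hi = np.full_like(lo, _K_UPPER_BOUND)
    # expand the upper bracket if some draw cannot reach its target there
    for _ in range(10):
        short = _recent_abundance(hi, r, z, removals, recent_year) < n_recent
        if not short.any():
            break
        hi = np.where(short, 2.0 * hi, hi)
    feasible = _recent_abundance(hi, r, z, removals, recent_year) >= n_recent
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        reached = _recent_abundance(mid, r, z, removals, recent_year) >= n_recent
        lo = np.where(reached, lo, mid)
        hi = np.where(reached, mid, hi)
        if np.max((hi - lo) / hi) < rel_tol * 1e-3:
            break
    K = 0.5 * (lo + hi)
    return np.where(feasible, K, np.nan), feasible
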