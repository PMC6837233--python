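"""Likelihood of a population trajectory given the abundance data.

Absolute abundance estimates are lognormal around the model abundance with
log-scale s.d. derived from the estimate's CV.  Relative indices are
lognormal up to an unknown multiplicative catchability q per series; with a
flat prior on ln q the catchability integrates out analytically, leaving a
marginal likelihood that depends only on the weighted spread of the
log-residuals around their weighted mean.  All additive constants (the
-0.5*ln(2*pi) terms and the -0.5*ln(W) from the q integral) are retained so
that marginal likelihoods are comparable across scenarios fitted to the same
data, which the Bayes-factor averaging requires.

A genetic lower bound applies on top: trajectories whose minimum falls below
the haplotype-derived floor get zero likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import ObservationSet
from .dynamics import Trajectory

__all__ = [
    "LogLikelihood",
    "lognormal_sigma",
    "abs_abundance_loglik",
    "index_marginal_loglik",
    "genetic_floor_indicator",
    "n_floor_from_haplotypes",
    "total_loglik",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class LogLikelihood:
    total: float
    components: dict[str, float] = field(default_factory=dict)
    floor_ok: bool = True


def lognormal_sigma(cv) -> float:
    """Log-scale standard deviation implied by a coefficient of variation."""
    cv = np.asarray(cv, float)
    if (cv <= 0).any():
        raise ValueError("cv must be positive")
    out = np.sqrt(np.log1p(cv**2))
    return float(out) if out.ndim == 0 else out


def _model_log_abundance(traj: Trajectory, years) -> np.ndarray | None:
    values = np.array([traj.at(int(y)) for y in years])
    if (values <= 0).any():
        return None
    return np.log(values)


def abs_abundance_loglik(traj: Trajectory, estimates) -> float:
    """Lognormal log-likelihood of the absolute abundance estimates.

    Sum over estimate years of the normal log-density of ln(estimate) around
    ln(model abundance) with sigma from the CV.  -inf if the model abundance
    is non-positive at any estimate year.
    """
    log_n = _model_log_abundance(traj, estimates["year"])
    if log_n is None:
        return -np.inf
    sigma = lognormal_sigma(estimates["cv"].to_numpy())
    resid = np.log(estimates["estimate"].to_numpy(float)) - log_n
    return float(
        np.sum(-0.5 * _LOG_2PI - np.log(sigma) - 0.5 * (resid / sigma) ** 2)
    )


def index_marginal_loglik(traj: Trajectory, series) -> float:
    """Marginal log-likelihood of one relative index, catchability integrated out.

    With residuals e_t = ln I_t - ln N_t, weights w_t = sigma_t^-2 and
    W = sum w_t, integrating the lognormal likelihood over ln q under a flat
    prior gives

        -((n-1)/2) ln 2pi - sum ln sigma_t - 0.5 ln W
        - 0.5 * sum w_t (e_t - e_bar)^2,

    where e_bar is the weighted mean residual.  A single-observation series
    therefore contributes a constant: one free residual is absorbed entirely
    by the free catchability.
    """
    if len(series) < 1:
        raise ValueError("index series needs at least one observation")
    log_n = _model_log_abundance(traj, series["year"])
    if log_n is None:
        return -np.inf
    sigma = lognormal_sigma(series["cv"].to_numpy())
    e = np.log(series["estimate"].to_numpy(float)) - log_n
    w = sigma**-2.0
    W = w.sum()
    e_bar = np.sum(w * e) / W
    n = len(e)
    return float(
        -0.5 * (n - 1) * _LOG_2PI
        - np.sum(np.log(sigma))
        - 0.5 * np.log(W)
        - 0.5 * np.sum(w * (e - e_bar) ** 2)
    )


def genetic_floor_indicator(n_min: float, n_floor: float) -> bool:
    """True when the trajectory minimum respects the haplotype floor."""
    if n_min <= 0:
        raise ValueError("n_min must be positive")
    if n_floor < 0:
        raise ValueError("n_floor must be non-negative")
    return n_min >= n_floor


def n_floor_from_haplotypes(h: int) -> int:
    """Census floor from a surviving mtDNA haplotype count.

    Each haplotype marks at least one female at the bottleneck; tripling
    scales contributing females up to the census population (33% contributing
    females, 1:1 sex ratio, overlapping generations).
    """
    if h < 0 or int(h) != h:
        raise ValueError("haplotype count must be a non-negative integer")
    return 3 * int(h)


def total_loglik(
    traj: Trajectory, obs: ObservationSet, n_floor: float = 0.0
) -> LogLikelihood:
    """Full log-likelihood of a trajectory: absolute terms, marginalized index
    terms and the floor indicator; -inf for invalid or floor-violating
    trajectories."""
    if not traj.valid:
        return LogLikelihood(total=-np.inf, components={}, floor_ok=False)
    floor_ok = genetic_floor_indicator(float(np.min(traj.values)), n_floor)
    components = {"ABS": abs_abundance_loglik(traj, obs.absolute)}
    for sid, series in obs.indices.items():
        components[sid] = index_marginal_loglik(traj, series)
    total = sum(components.values()) if floor_ok else -np.inf
    return LogLikelihood(total=total, components=components, floor_ok=floor_ok)


# Vectorized forms used by the importance sampler: model log-abundances are
# supplied as (n_draws,) arrays per observation year.


def abs_loglik_batch(log_model: dict[int, np.ndarray], estimates) -> np.ndarray:
    total = 0.0
    for row in estimates.itertuples(index=False):
        sigma = lognormal_sigma(row.cv)
        resid = math.log(row.estimate) - log_model[int(row.year)]
        total = total + (-0.5 * _LOG_2PI - math.log(sigma) - 0.5 * (resid / sigma) ** 2)
    return total


def index_marginal_loglik_batch(log_model: dict[int, np.ndarray], series) -> np.ndarray:
    sigma = lognormal_sigma(series["cv"].to_numpy())
    w = sigma**-2.0
    W = w.sum()
    n = len(series)
    e = np.stack(
        [
            math.log(row.estimate) - log_model[int(row.year)]
            for row in series.itertuples(index=False)
        ]
    )  # (n_obs, n_draws)
    e_bar = (w[:, None] * e).sum(axis=0) / W
    quad = (w[:, None] * (e - e_bar[None, :]) ** 2).sum(axis=0)
    return (
        -0.5 * (n - 1) * _LOG_2PI
        - np.sum(np.log(sigma))
        - 0.5 * math.log(W)
        - 0.5 * quad
    )
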