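"""Posterior summaries, trajectory envelopes, krill-consumption arithmetic
and file outputs."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_QUANTITIES",
    "SummaryRow",
    "ConsumptionEstimate",
    "summarize",
    "trajectory_envelope",
    "krill_consumption",
    "krill_fraction",
    "write_outputs",
]

DEFAULT_QUANTITIES = (
    "r_max",
    "K",
    "n_min",
    "N_2006",
    "N_2008",
    "N_2012",
    "N_2019",
    "N_2030",
    "max_depletion",
    "status_2006",
    "status_2008",
    "status_2012",
    "status_2019",
    "status_2030",
)

_ENVELOPE_LEVELS = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass(frozen=True)
class SummaryRow:
    quantity: str
    mean: float
    median: float
    pi_2_5: float
    pi_97_5: float


@dataclass(frozen=True)
class ConsumptionEstimate:
    population: float
    daily_rate: float
    season_days: float
    total: float
    biomass_fraction: float | None = None


def summarize(draws: pd.DataFrame, quantities=DEFAULT_QUANTITIES) -> pd.DataFrame:
    """Posterior mean, median and central 95% interval per quantity.

    Quantiles use the inclusive linear-interpolation convention (the numpy
    default), which is deterministic and standard.
    """
    if len(draws) == 0:
        raise ValueError("empty posterior")
    rows = []
    for q in quantities:
        if q not in draws.columns:
            raise KeyError(f"unknown quantity {q!r}")
        x = draws[q].to_numpy(float)
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
        rows.append(SummaryRow(q, float(x.mean()), float(med), float(lo), float(hi)))
    return pd.DataFrame(
        {
            "quantity": [r.quantity for r in rows],
            "mean": [r.mean for r in rows],
            "median": [r.median for r in rows],
            "pi_2_5": [r.pi_2_5 for r in rows],
            "pi_97_5": [r.pi_97_5 for r in rows],
        }
    )


def trajectory_envelope(trajectories: np.ndarray, years: np.ndarray) -> pd.DataFrame:
    """Year-wise posterior median with 50% and 95% bands.

    ``trajectories`` is (n_draws, n_years); returns one row per year with the
    2.5/25/50/75/97.5 percentiles.
    """
    qs = np.percentile(np.atleast_2d(trajectories), _ENVELOPE_LEVELS, axis=0)
    out = pd.DataFrame({"year": np.asarray(years)})
    for level, row in zip(_ENVELOPE_LEVELS, qs):
        out[f"q{level:g}"] = row
    return out


def krill_consumption(
    population: float, daily_rate: float, season_days: float
) -> float:
    """Seasonal krill consumption in tonnes: whales x kg/day x days / 1000."""
    if population < 0 or daily_rate <= 0 or season_days <= 0:
        raise ValueError("population must be >= 0; rate and season positive")
    return population * daily_rate * season_days / 1000.0


def krill_fraction(consumption: float, biomass: float) -> float:
    """Consumption as a percentage of the krill biomass estimate."""
    if biomass <= 0:
        raise ValueError("biomass must be positive")
    return 100.0 * consumption / biomass


def write_outputs(
    out_dir: str | Path,
    draws: pd.DataFrame,
    trajectories: np.ndarray,
    years: np.ndarray,
    manifest: dict,
    quantities=DEFAULT_QUANTITIES,
) -> None:
    """Write summary.csv, trajectory_envelope.csv, draws.csv and manifest.json.

    Reported tables round abundances to the nearest whale and rates to three
    decimals; draws.csv keeps full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = summarize(draws, quantities)
    display = summary.copy()
    for col in ("mean", "median", "pi_2_5", "pi_97_5"):
        display[col] = [
            round(v) if q.startswith(("K", "N_", "n_min")) else round(v, 3)
            for q, v in zip(display["quantity"], display[col])
        ]
    display.to_csv(out / "summary.csv", index=False)
    trajectory_envelope(trajectories, years).to_csv(
        out / "trajectory_envelope.csv", index=False
    )
    draws.to_csv(out / "draws.csv", index=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
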