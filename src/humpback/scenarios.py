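"""Scenario grid execution and Bayes-factor model averaging.

Nineteen scenarios vary the reference case (RC) one ingredient at a time:
which abundance year anchors the backwards prior, which indices are fitted,
the r_max prior, catch allocation, struck-and-lost treatment, the genetic
floor and the production shape.  Nine of them - those fitted to identical
data and not deliberately stripped of plausible inputs - are combined by
normalized marginal likelihoods under equal prior model probabilities, by
resampling whole parameter vectors from the member posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datasets import (
    CatchTables,
    MODEL_AVERAGING_SET,
    ObservationSet,
    ScenarioSpec,
    data_signature,
    load_catch_tables,
    load_observation_set,
    load_scenario,
)
from .reporting import DEFAULT_QUANTITIES, summarize
from .sir import DEFAULT_N_OUT, DEFAULT_N_PRIOR, PosteriorSet, run_sir

__all__ = [
    "ScenarioResult",
    "AveragedPosterior",
    "run_scenario",
    "relative_model_probabilities",
    "model_average",
    "run_assessment",
]


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    posterior: PosteriorSet
    summary: pd.DataFrame
    data_signature: str


@dataclass
class AveragedPosterior:
    member_names: tuple[str, ...]
    probabilities: dict[str, float]
    draws: pd.DataFrame
    trajectories: np.ndarray
    years: np.ndarray


def run_scenario(
    name: str | ScenarioSpec,
    rng: np.random.Generator,
    n_prior: int = DEFAULT_N_PRIOR,
    n_out: int = DEFAULT_N_OUT,
    data: ObservationSet | None = None,
    tables: CatchTables | None = None,
) -> ScenarioResult:
    """Full SIR run for one named scenario, with posterior summary table."""
    spec = load_scenario(name) if isinstance(name, str) else name
    if data is None:
        data = load_observation_set(spec.index_set)
    posterior = run_sir(
        spec, rng, n_prior=n_prior, n_out=n_out, data=data, tables=tables
    )
    return ScenarioResult(
        spec=spec,
        posterior=posterior,
        summary=summarize(posterior.draws, DEFAULT_QUANTITIES),
        data_signature=data_signature(data),
    )


def relative_model_probabilities(
    log_marginals: dict[str, float],
    signatures: dict[str, str] | None = None,
) -> dict[str, float]:
    """Normalized marginal likelihoods under equal prior model probabilities.

    When data signatures are supplied they must be identical across members:
    Bayes factors between models fitted to different data are meaningless.
    """
    if signatures is not None:
        if len(set(signatures[k] for k in log_marginals)) > 1:
            raise ValueError(
                "model averaging requires identical likelihood data across members"
            )
    names = list(log_marginals)
    lm = np.array([log_marginals[k] for k in names], float)
    probs = np.exp(lm - logsumexp(lm))
    return dict(zip(names, probs))


def model_average(
    results: dict[str, ScenarioResult],
    probabilities: dict[str, float],
    n_out: int,
    rng: np.random.Generator,
) -> AveragedPosterior:
    """Pool posteriors by sampling a member per draw, then one of its draws."""
    names = list(probabilities)
    p = np.array([probabilities[k] for k in names])
    if not np.isclose(p.sum(), 1.0, atol=1e-12):
        raise ValueError("model probabilities must sum to 1")
    for k in names:
        if len(results[k].posterior.draws) == 0:
            raise ValueError(f"member {k} has an empty posterior")
    member_idx = rng.choice(len(names), size=n_out, p=p)
    rows, traj_rows = [], []
    for m, name in enumerate(names):
        take = np.flatnonzero(member_idx == m)
        if take.size == 0:
            continue
        post = results[name].posterior
        j = rng.integers(0, len(post.draws), take.size)
        block = post.draws.iloc[j].copy()
        block["scenario"] = name
        rows.append(block)
        traj_rows.append(post.trajectories[j])
    draws = pd.concat(rows, ignore_index=True)
    years = next(iter(results.values())).posterior.years
    return AveragedPosterior(
        member_names=tuple(names),
        probabilities=probabilities,
        draws=draws,
        trajectories=np.vstack(traj_rows),
        years=years,
    )


def run_assessment(
    seed: int,
    names: tuple[str, ...] = MODEL_AVERAGING_SET,
    n_prior: int = DEFAULT_N_PRIOR,
    n_out: int = DEFAULT_N_OUT,
    tables: CatchTables | None = None,
) -> tuple[dict[str, ScenarioResult], AveragedPosterior]:
    """Run the averaging members and combine them.

    Each scenario gets an independent child stream of the seed so results do
    not depend on the order scenarios are run in.
    """
    if tables is None:
        tables = load_catch_tables()
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(len(names) + 1)
    results = {
        name: run_scenario(
            name,
            np.random.default_rng(children[i]),
            n_prior=n_prior,
            n_out=n_out,
            tables=tables,
        )
        for i, name in enumerate(names)
    }
    probs = relative_model_probabilities(
        {k: results[k].posterior.log_marginal for k in names},
        {k: results[k].data_signature for k in names},
    )
    averaged = model_average(
        results, probs, n_out, np.random.default_rng(children[-1])
    )
    return results, averaged
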