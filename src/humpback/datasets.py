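"""Input tables for the western South Atlantic humpback whale assessment.

All inputs to the assessment are small printed tables: pre-modern (1830-1924)
and modern (1904-1972) catch records, struck-and-lost rate priors, absolute
abundance estimates from breeding-ground ship surveys (2008, 2012), three
indices of relative abundance (FG, BG1, BG2), and the grid of 19 modelling
scenarios.  They ship with the package as versioned CSVs and are validated on
load against the tables' printed column totals, so that any digitization or
editing error refuses to run rather than silently biasing the assessment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CatchTables",
    "LossRatePrior",
    "ObservationSet",
    "ScenarioSpec",
    "ChecksumResult",
    "ValidationReport",
    "PRINTED_TOTALS",
    "SCENARIO_NAMES",
    "MODEL_AVERAGING_SET",
    "load_catch_tables",
    "load_abundance",
    "load_observation_set",
    "load_loss_rate_priors",
    "load_scenario",
    "validate_checksums",
    "data_signature",
]

_DATA_PKG = "humpback.data"

# Column totals as printed in the source catch tables.  The digitized CSVs
# must reproduce every one of these exactly.
PRINTED_TOTALS = {
    "premodern_brazil_min": 11_481,
    "premodern_brazil_max": 34_708,
    "premodern_pelagic": 257,
    "premodern_total_min": 11_738,
    "premodern_total_max": 34_965,
    "modern_core": 31_170,
    "modern_falkland": 219,
    "modern_fringe": 31_847,
    "modern_overlap": 27_334,
}

SCENARIO_NAMES = (
    "RC",
    "D-1", "D-2", "D-3", "D-4", "D-5", "D-6", "D-7",
    "C-1", "C-2", "C-3", "C-4", "C-5", "C-6", "C-7",
    "G-1", "G-2",
    "M-1", "M-2",
)

#: Scenarios combined by Bayes-factor model averaging.  Scenarios that drop
#: plausible data (D-2..D-6, C-1..C-3) have non-comparable likelihoods or are
#: exploratory only, and the genetic-floor scenarios duplicate the reference
#: case, so none of them enter the average.
MODEL_AVERAGING_SET = ("RC", "D-1", "D-7", "C-4", "C-5", "C-6", "C-7", "M-1", "M-2")

INDEX_SERIES = ("FG", "BG1", "BG2")
ALLOCATIONS = ("core", "core+falkland", "fringe", "overlap")
SLR_MODES = ("both_eras", "none", "modern_only", "C4_split")


class FixtureError(RuntimeError):
    """A packaged data table is missing or fails validation."""


def _read_csv(name: str, base: str | Path | None = None) -> pd.DataFrame:
    if base is not None:
        path = Path(base) / name
        if not path.exists():
            raise FixtureError(f"data table not found: {path}")
        return pd.read_csv(path)
    ref = resources.files(_DATA_PKG).joinpath(name)
    try:
        with ref.open("r", encoding="utf-8") as fh:
            return pd.read_csv(fh)
    except FileNotFoundError as exc:  # pragma: no cover - packaging fault
        raise FixtureError(f"packaged data table not found: {name}") from exc


@dataclass(frozen=True)
class CatchTables:
    """Digitized catch records: per-period pre-modern rows and annual modern rows.

    ``premodern`` columns: start_year, end_year, brazil_min, brazil_max,
    pelagic (whales per period).  ``modern`` columns: year and the four
    allocation hypotheses core, falkland, fringe, overlap (whales per year;
    fringe contains fractional values from proportional area allocation).
    """

    premodern: pd.DataFrame
    modern: pd.DataFrame

    def __post_init__(self) -> None:
        pre, mod = self.premodern, self.modern
        required_pre = {"start_year", "end_year", "brazil_min", "brazil_max", "pelagic"}
        required_mod = {"year", "core", "falkland", "fringe", "overlap"}
        if not required_pre.issubset(pre.columns):
            raise FixtureError("premodern catch table: missing columns")
        if not required_mod.issubset(mod.columns):
            raise FixtureError("modern catch table: missing columns")
        if (pre["start_year"] > pre["end_year"]).any():
            raise FixtureError("premodern catch table: start_year > end_year")
        if (pre["brazil_min"] > pre["brazil_max"]).any():
            raise FixtureError("premodern catch table: brazil_min > brazil_max")
        if (pre[["brazil_min", "brazil_max", "pelagic"]] < 0).to_numpy().any():
            raise FixtureError("premodern catch table: negative catches")
        if pre["start_year"].min() < 1830 or pre["end_year"].max() > 1924:
            raise FixtureError("premodern catch table: period outside 1830-1924")
        spans = sorted(zip(pre["start_year"], pre["end_year"]))
        for (_, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise FixtureError("premodern catch table: overlapping periods")
        if (mod[["core", "falkland", "fringe", "overlap"]] < 0).to_numpy().any():
            raise FixtureError("modern catch table: negative catches")
        if mod["year"].min() < 1904 or mod["year"].max() > 1972:
            raise FixtureError("modern catch table: year outside 1904-1972")


@dataclass(frozen=True)
class LossRatePrior:
    """Prior on a struck-and-lost rate factor (total kills / landed catch)."""

    era_label: str  # premodern | modern | early_modern_C4
    family: str  # "normal" or "offset_halfnormal"
    location: float
    scale: float
    lower_trunc: float
    upper_trunc: float

    def __post_init__(self) -> None:
        if self.family == "normal" and self.location < 1.0:
            raise ValueError("normal loss-rate prior must have location >= 1")
        if self.lower_trunc > self.upper_trunc:
            raise ValueError("loss-rate prior truncation bounds out of order")


@dataclass(frozen=True)
class ObservationSet:
    """Abundance data entering the likelihood for one scenario.

    ``absolute`` holds the total-population estimates (series ABS);
    ``indices`` maps series id to the relative-index rows actually fitted.
    """

    absolute: pd.DataFrame
    indices: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df in [self.absolute, *self.indices.values()]:
            if len(df) and ((df["cv"] <= 0).any() or (df["estimate"] <= 0).any()):
                raise ValueError("abundance rows must have positive estimate and CV")


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the scenario grid: priors, data, catches and shape choices."""

    name: str
    recent_year: int
    rmax_prior: str  # "uniform" or "informative"
    index_set: tuple[str, ...]
    include_premodern: bool
    allocation: str
    slr_mode: str
    n_floor: float
    z: float

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.allocation not in ALLOCATIONS:
            raise ValueError(f"unknown allocation {self.allocation!r}")
        if self.slr_mode not in SLR_MODES:
            raise ValueError(f"unknown slr_mode {self.slr_mode!r}")
        if self.z <= 0:
            raise ValueError("shape parameter z must be positive")
        if self.n_floor < 0:
            raise ValueError("n_floor must be non-negative")
        for s in self.index_set:
            if s not in INDEX_SERIES:
                raise ValueError(f"unknown index series {s!r}")


@dataclass(frozen=True)
class ChecksumResult:
    name: str
    expected: float
    actual: float

    @property
    def ok(self) -> bool:
        return abs(self.expected - self.actual) < 1e-9


@dataclass(frozen=True)
class ValidationReport:
    results: tuple[ChecksumResult, ...]

    @property
    def ok(self) -> bool:
        return all(r.ok for r in self.results)

    def failures(self) -> list[ChecksumResult]:
        return [r for r in self.results if not r.ok]

    def __str__(self) -> str:
        lines = [
            f"{r.name}: expected {r.expected:g}, got {r.actual:g} "
            f"[{'ok' if r.ok else 'FAIL'}]"
            for r in self.results
        ]
        return "\n".join(lines)


def load_catch_tables(base: str | Path | None = None) -> CatchTables:
    """Load the packaged catch tables (or from ``base`` for round-trip tests)."""
    return CatchTables(
        premodern=_read_csv("premodern_catches.csv", base),
        modern=_read_csv("modern_catches.csv", base),
    )


def validate_checksums(tables: CatchTables) -> ValidationReport:
    """Compare every digitized column against its printed total row."""
    pre, mod = tables.premodern, tables.modern
    if len(pre) == 0 or len(mod) == 0:
        raise FixtureError("catch table validation: no rows")
    sums = {
        "premodern_brazil_min": pre["brazil_min"].sum(),
        "premodern_brazil_max": pre["brazil_max"].sum(),
        "premodern_pelagic": pre["pelagic"].sum(),
        "premodern_total_min": (pre["brazil_min"] + pre["pelagic"]).sum(),
        "premodern_total_max": (pre["brazil_max"] + pre["pelagic"]).sum(),
        "modern_core": mod["core"].sum(),
        "modern_falkland": mod["falkland"].sum(),
        "modern_fringe": mod["fringe"].sum(),
        "modern_overlap": mod["overlap"].sum(),
    }
    return ValidationReport(
        tuple(
            ChecksumResult(name, float(PRINTED_TOTALS[name]), float(actual))
            for name, actual in sums.items()
        )
    )


def require_valid(tables: CatchTables) -> None:
    """Refuse to run the assessment on catch tables that fail a checksum."""
    report = validate_checksums(tables)
    if not report.ok:
        bad = ", ".join(r.name for r in report.failures())
        raise FixtureError(f"catch table checksum failure in: {bad}\n{report}")


def load_abundance(base: str | Path | None = None) -> pd.DataFrame:
    df = _read_csv("abundance.csv", base)
    abs_years = set(df.loc[df["series_id"] == "ABS", "year"])
    if abs_years != {2008, 2012}:
        raise FixtureError("abundance table: ABS entries must be 2008 and 2012")
    return df


def load_observation_set(
    index_set: tuple[str, ...] = ("FG", "BG1"),
    base: str | Path | None = None,
) -> ObservationSet:
    """Assemble the likelihood data for a scenario: both absolute estimates
    plus the requested relative-index series."""
    df = load_abundance(base)
    absolute = df[df["series_id"] == "ABS"].reset_index(drop=True)
    indices = {
        s: df[df["series_id"] == s].reset_index(drop=True) for s in index_set
    }
    return ObservationSet(absolute=absolute, indices=indices)


def load_loss_rate_priors(base: str | Path | None = None) -> dict[str, LossRatePrior]:
    df = _read_csv("loss_rate_priors.csv", base)
    priors = {}
    for row in df.itertuples(index=False):
        priors[row.era_label] = LossRatePrior(
            era_label=row.era_label,
            family=row.family,
            location=float(row.location),
            scale=float(row.scale),
            lower_trunc=float(row.lower_trunc),
            upper_trunc=float(row.upper_trunc),
        )
    missing = {"premodern", "modern", "early_modern_C4"} - set(priors)
    if missing:
        raise FixtureError(f"loss-rate prior table: missing eras {sorted(missing)}")
    return priors


def _scenario_frame(base: str | Path | None = None) -> pd.DataFrame:
    df = _read_csv("scenarios.csv", base)
    if set(df["name"]) != set(SCENARIO_NAMES):
        raise FixtureError("scenario table does not match the 19-name registry")
    return df


def load_scenario(name: str, base: str | Path | None = None) -> ScenarioSpec:
    """Look up one scenario from the packaged grid."""
    df = _scenario_frame(base)
    match = df[df["name"] == name]
    if match.empty:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    row = match.iloc[0]
    index_set = tuple(s for s in str(row["index_set"]).split("+") if s and s != "nan")
    return ScenarioSpec(
        name=row["name"],
        recent_year=int(row["recent_year"]),
        rmax_prior=row["rmax_prior"],
        index_set=index_set,
        include_premodern=bool(int(row["include_premodern"])),
        allocation=row["allocation"],
        slr_mode=row["slr_mode"],
        n_floor=float(row["n_floor"]),
        z=float(row["z"]),
    )


def data_signature(obs: ObservationSet) -> str:
    """Hash of exactly which observations enter a likelihood.

    Bayes factors are only meaningful between scenarios fitted to identical
    data; the model-averaging step compares these signatures before combining
    marginal likelihoods.
    """
    parts = ["ABS"]
    for row in obs.absolute.itertuples(index=False):
        parts.append(f"{row.year}:{row.estimate}:{row.cv}")
    for sid in sorted(obs.indices):
        parts.append(sid)
        for row in obs.indices[sid].itertuples(index=False):
            parts.append(f"{row.year}:{row.estimate}:{row.cv}")
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def write_tables(tables: CatchTables, out_dir: str | Path) -> None:
    """Write catch tables back to CSV (round-trip support for provenance checks)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables.premodern.to_csv(out / "premodern_catches.csv", index=False)
    tables.modern.to_csv(out / "modern_catches.csv", index=False)
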