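"""Scenario schedulers and runners.

Four scenarios describe the futures the simulator explores from the current
year onward:

* **status quo** — every existing source keeps loading; nothing new is built.
* **buildout** (upper bound) — each parcel flagged as buildable receives its
  additional load at a year drawn uniformly at random inside the 20-year
  planning window; base loads continue unchanged.
* **source control** (lower bound) — every unsewered, loading parcel is
  upgraded (sewered or fitted with an advanced septic system). A random
  permutation fixes the upgrade order and parcels are spread evenly across
  the window years; load already in the groundwater still arrives.
* **legacy** — all inputs stop instantaneously at the shutoff year, and the
  load still reaching each bay afterwards is the *legacy nitrogen*: mass in
  transit in the aquifer.

The two stochastic scenarios are run as Monte Carlo ensembles with
reproducible per-iteration sub-seeds (``SeedSequence([seed, iteration])``)
and summarized as per-year min/mean/max envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import EngineConfig, LoadingSeries, build_windows, delivered_series
from .exceptions import ConfigurationError
from .parcels import ParcelTable

EVENT_KINDS = ("buildout_update", "source_control_shutoff")
SCENARIO_KINDS = ("status_quo", "buildout", "source_control", "legacy")


@dataclass(frozen=True)
class LoadEvent:
    """A dated change to one parcel's groundwater input."""

    parcel_id: str
    year: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigurationError(f"event kind must be one of {EVENT_KINDS}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario parameters.

    The scheduling window [window_start, window_end) spans the 20 planning
    years 2020-2039 by default. Legacy accounting shuts all inputs off in
    ``legacy_shutoff_year`` and tallies arrivals over
    [legacy_tally_start, legacy_tally_end].
    """

    kind: str = "status_quo"
    window_start: int = 2020
    window_end: int = 2040
    n_iterations: int = 1000
    seed: int = 0
    legacy_shutoff_year: int = 2020
    legacy_tally_start: int = 2025
    legacy_tally_end: int = 2150

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigurationError(f"kind must be one of {SCENARIO_KINDS}")
        if self.window_start > self.window_end:
            raise ConfigurationError("window_start must not exceed window_end")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.legacy_tally_start > self.legacy_tally_end:
            raise ConfigurationError("legacy_tally_start must not exceed legacy_tally_end")


@dataclass
class MonteCarloEnvelope:
    """Per-watershed, per-year min/mean/max delivered load across iterations."""

    watershed_ids: list[str]
    start_year: int
    minimum: dict[str, np.ndarray]
    mean: dict[str, np.ndarray]
    maximum: dict[str, np.ndarray]
    n_iterations: int
    seed: int
    scenario_kind: str
    iterations: list[dict[str, LoadingSeries]] | None = None

    @property
    def years(self) -> np.ndarray:
        n = len(next(iter(self.minimum.values())))
        return np.arange(self.start_year, self.start_year + n)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for ws in self.watershed_ids:
            frames.append(
                pd.DataFrame(
                    {
                        "scenario": self.scenario_kind,
                        "watershed_id": ws,
                        "year": self.years,
                        "load_min_kg": self.minimum[ws],
                        "load_mean_kg": self.mean[ws],
                        "load_max_kg": self.maximum[ws],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class LegacyResult:
    """Output of the legacy-nitrogen scenario.

    ``legacy_mass_kg`` tallies arrivals over the configured window (default
    2025-2150); ``mass_from_shutoff_kg`` is a companion total over
    [shutoff year, tally end] reported alongside because the five-year gap
    before the default tally start excludes short-travel-time mass.
    """

    series: dict[str, LoadingSeries]
    legacy_mass_kg: dict[str, float]
    mass_from_shutoff_kg: dict[str, float]
    scenario: ScenarioConfig


def iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    """The documented sub-seed mechanism: generator for one MC iteration.

    Uses ``SeedSequence([seed, iteration])`` so any single iteration can be
    replayed in isolation without generating its predecessors.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, iteration]))


def schedule_buildout(
    parcels: ParcelTable,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> list[LoadEvent]:
    """Assign each buildable parcel one buildout_update event at a year drawn
    uniformly from [window_start, window_end)."""
    if config.kind != "buildout":
        raise ConfigurationError(f"expected kind='buildout', got {config.kind!r}")
    buildable = [p for p in parcels if p.buildout_delta > 0]
    if not buildable:
        return []
    years = rng.integers(config.window_start, config.window_end, size=len(buildable))
    return [
        LoadEvent(p.parcel_id, int(y), "buildout_update")
        for p, y in zip(buildable, years)
    ]


def schedule_source_control(
    parcels: ParcelTable,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> list[LoadEvent]:
    """Assign shutoff events to all unsewered, loading parcels.

    A uniform random permutation fixes the upgrade order; parcels are divided
    evenly across the window years with any remainder filling the earliest
    years (quota = ceil(n / n_years)).
    """
    if config.kind != "source_control":
        raise ConfigurationError(f"expected kind='source_control', got {config.kind!r}")
    eligible = [p for p in parcels if (not p.sewered) and p.raw_load > 0]
    n = len(eligible)
    if n == 0:
        return []
    n_years = max(config.window_end - config.window_start, 1)
    order = rng.permutation(n)
    base, rem = divmod(n, n_years)
    events: list[LoadEvent] = []
    pos = 0
    for j in range(n_years):
        quota = base + (1 if j < rem else 0)
        year = config.window_start + j
        for k in range(quota):
            events.append(
                LoadEvent(eligible[order[pos]].parcel_id, year, "source_control_shutoff")
            )
            pos += 1
    return events


def run_status_quo(
    parcels: ParcelTable,
    engine: EngineConfig = EngineConfig(),
    watershed_ids: Sequence[str] | None = None,
) -> dict[str, LoadingSeries]:
    """Delivered-load series with no future events: existing sources only."""
    windows = build_windows(parcels, (), engine)
    ids = watershed_ids if watershed_ids is not None else parcels.watershed_ids
    return delivered_series(windows, engine, watershed_ids=ids)


def run_monte_carlo(
    parcels: ParcelTable,
    scenario: ScenarioConfig,
    engine: EngineConfig = EngineConfig(),
    keep_iterations: bool = False,
) -> MonteCarloEnvelope:
    """Monte Carlo ensemble for the buildout or source-control scenario.

    Runs ``scenario.n_iterations`` independent schedules (sub-seeded from the
    master seed) and aggregates min/mean/max per watershed-year. Set
    ``keep_iterations`` to retain every iteration's series (memory permitting).
    """
    if scenario.kind not in ("buildout", "source_control"):
        raise ConfigurationError(
            f"run_monte_carlo handles buildout/source_control, got {scenario.kind!r}"
        )
    scheduler = (
        schedule_buildout if scenario.kind == "buildout" else schedule_source_control
    )
    ws_ids = parcels.watershed_ids
    n = engine.n_years
    lo = {ws: np.full(n, np.inf) for ws in ws_ids}
    hi = {ws: np.full(n, -np.inf) for ws in ws_ids}
    total = {ws: np.zeros(n) for ws in ws_ids}
    kept: list[dict[str, LoadingSeries]] | None = [] if keep_iterations else None
    for i in range(scenario.n_iterations):
        rng = iteration_rng(scenario.seed, i)
        events = scheduler(parcels, scenario, rng)
        windows = build_windows(parcels, events, engine)
        series = delivered_series(windows, engine, watershed_ids=ws_ids)
        for ws in ws_ids:
            v = series[ws].values
            np.minimum(lo[ws], v, out=lo[ws])
            np.maximum(hi[ws], v, out=hi[ws])
            total[ws] += v
        if kept is not None:
            kept.append(series)
    mean = {ws: total[ws] / scenario.n_iterations for ws in ws_ids}
    return MonteCarloEnvelope(
        watershed_ids=list(ws_ids),
        start_year=engine.start_year,
        minimum=lo,
        mean=mean,
        maximum=hi,
        n_iterations=scenario.n_iterations,
        seed=scenario.seed,
        scenario_kind=scenario.kind,
        iterations=kept,
    )


def run_legacy(
    parcels: ParcelTable,
    scenario: ScenarioConfig = ScenarioConfig(kind="legacy"),
    engine: EngineConfig = EngineConfig(),
) -> LegacyResult:
    """Legacy-nitrogen accounting: shut off every input at the shutoff year
    and tally what still arrives.

    Every parcel's input window is truncated at legacy_shutoff_year - 1; the
    legacy mass per watershed is the sum of delivered load over the tally
    window. Mass still in the aquifer is exactly what was input before
    shutoff but had not yet arrived.
    """
    if scenario.kind != "legacy":
        raise ConfigurationError(f"expected kind='legacy', got {scenario.kind!r}")
    if not (
        engine.start_year <= scenario.legacy_tally_start
        and scenario.legacy_tally_end <= engine.end_year
    ):
        raise ConfigurationError(
            "legacy tally window "
            f"[{scenario.legacy_tally_start}, {scenario.legacy_tally_end}] outside "
            f"engine range [{engine.start_year}, {engine.end_year}]"
        )
    events = [
        LoadEvent(p.parcel_id, scenario.legacy_shutoff_year, "source_control_shutoff")
        for p in parcels
        if max(p.year_built, engine.start_year) < scenario.legacy_shutoff_year
    ]
    # Parcels first active at/after the shutoff year never load in this scenario;
    # they are excluded from both events and windows.
    active_ids = {e.parcel_id for e in events}
    active = ParcelTable(
        tuple(p for p in parcels if p.parcel_id in active_ids),
        provenance=parcels.provenance,
    )
    windows = build_windows(active, events, engine)
    series = delivered_series(windows, engine, watershed_ids=parcels.watershed_ids)
    legacy_mass = {
        ws: series[ws].window_sum(scenario.legacy_tally_start, scenario.legacy_tally_end)
        for ws in series
    }
    from_shutoff = {
        ws: series[ws].window_sum(scenario.legacy_shutoff_year, scenario.legacy_tally_end)
        for ws in series
    }
    return LegacyResult(
        series=series,
        legacy_mass_kg=legacy_mass,
        mass_from_shutoff_kg=from_shutoff,
        scenario=scenario,
    )
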