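"""Annual time-step delivered-load simulator.

The model is a discrete-delay mass balance. Each parcel injects nitrogen into
groundwater at a constant attenuated rate over an *input window* (from the
year it was built, possibly truncated by a source-control shutoff, possibly
augmented by a buildout increment). Nitrogen injected in year ``y`` by a
parcel with integer travel time ``tau`` arrives at the embayment in year
``y + tau`` (the *inclusive* arrival rule) or ``y + tau + 1`` (*strict*).
The delivered load at the bay in year ``t`` is the sum, over all windows, of
the window's rate whenever ``t`` minus the arrival shift falls inside the
window.

Two implementations are provided: :func:`delivered_series` (vectorized
interval arithmetic, the production path) and :func:`packet_oracle` (an
exhaustive per-year "packet" enumeration kept as an independent check; the
two must agree exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ReferentialError, SchedulingError
from .parcels import ParcelTable

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import LoadEvent

ARRIVAL_RULES = ("inclusive", "strict")


@dataclass(frozen=True)
class EngineConfig:
    """Simulation window and arrival convention.

    start_year/end_year bound the annual grid (defaults 1880-2150);
    current_year (default 2020) separates hindcast from projection.
    arrival_rule chooses whether input in year y with travel time tau first
    arrives in year y + tau ("inclusive", default) or y + tau + 1 ("strict").
    """

    start_year: int = 1880
    end_year: int = 2150
    current_year: int = 2020
    arrival_rule: str = "inclusive"

    def __post_init__(self) -> None:
        if not (self.start_year < self.current_year < self.end_year):
            raise ConfigurationError(
                "require start_year < current_year < end_year, got "
                f"{self.start_year}, {self.current_year}, {self.end_year}"
            )
        if self.arrival_rule not in ARRIVAL_RULES:
            raise ConfigurationError(
                f"arrival_rule must be one of {ARRIVAL_RULES}, got {self.arrival_rule!r}"
            )

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def arrival_offset(self) -> int:
        """Extra shift beyond the travel time: 0 (inclusive) or 1 (strict)."""
        return 0 if self.arrival_rule == "inclusive" else 1


@dataclass(frozen=True)
class ContributionWindow:
    """One constant-rate groundwater input interval for one parcel.

    ``input_end is None`` means the window is open-ended (capped internally at
    the simulation horizon). ``delivered_rate`` is already attenuated.
    """

    parcel_id: str
    watershed_id: str
    input_start: int
    input_end: int | None
    delivered_rate: float
    travel_time: int

    def __post_init__(self) -> None:
        if self.input_end is not None and self.input_end < self.input_start:
            raise ValueError(
                f"window for {self.parcel_id}: input_end {self.input_end} < "
                f"input_start {self.input_start}"
            )
        if self.delivered_rate < 0:
            raise ValueError(f"window for {self.parcel_id}: negative delivered rate")


@dataclass
class LoadingSeries:
    """Annual delivered nitrogen load (kg N/yr) at one embayment over the
    full simulation window."""

    watershed_id: str
    start_year: int
    values: np.ndarray

    @property
    def end_year(self) -> int:
        return self.start_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def at(self, year: int) -> float:
        """Delivered load in a given calendar year."""
        if not (self.start_year <= year <= self.end_year):
            raise IndexError(
                f"year {year} outside series range [{self.start_year}, {self.end_year}]"
            )
        return float(self.values[year - self.start_year])

    def window_sum(self, first_year: int, last_year: int) -> float:
        """Total mass (kg) delivered over [first_year, last_year] inclusive."""
        if first_year > last_year:
            raise ValueError("first_year must not exceed last_year")
        a = max(first_year, self.start_year) - self.start_year
        b = min(last_year, self.end_year) - self.start_year
        if b < a:
            return 0.0
        return float(self.values[a : b + 1].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "watershed_id": self.watershed_id,
                "year": self.years,
                "load_kg": self.values,
            }
        )


def build_windows(
    parcels: ParcelTable,
    events: Iterable["LoadEvent"] = (),
    config: EngineConfig = EngineConfig(),
) -> list[ContributionWindow]:
    """Convert parcels plus scheduled load events into contribution windows.

    Each parcel yields a base window starting at its year built (clamped to
    the simulation start) and running until the year before its shutoff event,
    or open-ended if it has none. A buildout event adds a second, open window
    at the attenuated buildout rate from the update year on. Travel times are
    floored to whole years to match the annual step.

    Raises :class:`ReferentialError` for events naming unknown parcels,
    :class:`SchedulingError` for events dated before the parcel existed or
    duplicated per kind.
    """
    known = {p.parcel_id for p in parcels}
    shutoffs: dict[str, int] = {}
    buildouts: dict[str, int] = {}
    for ev in events:
        if ev.parcel_id not in known:
            raise ReferentialError(f"event references unknown parcel_id {ev.parcel_id!r}")
        book = shutoffs if ev.kind == "source_control_shutoff" else buildouts
        if ev.parcel_id in book:
            raise SchedulingError(
                f"parcel {ev.parcel_id!r} has more than one {ev.kind} event"
            )
        book[ev.parcel_id] = ev.year

    windows: list[ContributionWindow] = []
    for p in parcels:
        start = max(p.year_built, config.start_year)
        tau = math.floor(p.travel_time)
        for book, label in ((shutoffs, "shutoff"), (buildouts, "buildout")):
            if p.parcel_id in book and book[p.parcel_id] < start:
                raise SchedulingError(
                    f"{label} event for {p.parcel_id!r} in {book[p.parcel_id]} "
                    f"predates the parcel's activity start {start}"
                )
        end = shutoffs[p.parcel_id] - 1 if p.parcel_id in shutoffs else None
        if end is None or end >= start:
            windows.append(
                ContributionWindow(
                    parcel_id=p.parcel_id,
                    watershed_id=p.watershed_id,
                    input_start=start,
                    input_end=end,
                    delivered_rate=p.delivered_rate,
                    travel_time=tau,
                )
            )
        if p.parcel_id in buildouts:
            windows.append(
                ContributionWindow(
                    parcel_id=p.parcel_id,
                    watershed_id=p.watershed_id,
                    input_start=buildouts[p.parcel_id],
                    input_end=None,
                    delivered_rate=p.delivered_buildout_rate,
                    travel_time=tau,
                )
            )
    return windows


def _resolve_watersheds(
    windows: Sequence[ContributionWindow],
    watershed_ids: Sequence[str] | None,
) -> list[str]:
    if watershed_ids is not None:
        return list(watershed_ids)
    seen: dict[str, None] = {}
    for w in windows:
        seen.setdefault(w.watershed_id, None)
    return list(seen)


def delivered_series(
    windows: Sequence[ContributionWindow],
    config: EngineConfig = EngineConfig(),
    watershed_ids: Sequence[str] | None = None,
) -> dict[str, LoadingSeries]:
    """Delivered annual load per watershed via interval arithmetic.

    A window inputting over [a, b] with travel time tau delivers its rate over
    arrival years [a + tau + o, b + tau + o] (o = 0 inclusive, 1 strict),
    clipped to the simulation horizon; open windows are capped at end_year.
    """
    ws_ids = _resolve_watersheds(windows, watershed_ids)
    acc = {ws: np.zeros(config.n_years) for ws in ws_ids}
    off = config.arrival_offset
    for w in windows:
        if w.watershed_id not in acc:
            raise ReferentialError(
                f"window for parcel {w.parcel_id!r} names watershed "
                f"{w.watershed_id!r} absent from watershed_ids"
            )
        b_in = config.end_year if w.input_end is None else min(w.input_end, config.end_year)
        a = w.input_start + w.travel_time + off
        b = b_in + w.travel_time + off
        a = max(a, config.start_year)
        b = min(b, config.end_year)
        if b < a:
            continue
        acc[w.watershed_id][a - config.start_year : b - config.start_year + 1] += (
            w.delivered_rate
        )
    return {
        ws: LoadingSeries(ws, config.start_year, values) for ws, values in acc.items()
    }


def packet_oracle(
    windows: Sequence[ContributionWindow],
    config: EngineConfig = EngineConfig(),
    watershed_ids: Sequence[str] | None = None,
) -> dict[str, LoadingSeries]:
    """Brute-force reference: enumerate every (window, input year) packet.

    Each input year contributes one packet of mass ``delivered_rate`` arriving
    after the travel-time shift; packets are binned per watershed per year.
    Deliberately unoptimized so it stays an independent check on
    :func:`delivered_series`.
    """
    ws_ids = _resolve_watersheds(windows, watershed_ids)
    acc = {ws: np.zeros(config.n_years) for ws in ws_ids}
    off = config.arrival_offset
    for w in windows:
        last_input = config.end_year if w.input_end is None else min(w.input_end, config.end_year)
        for y in range(w.input_start, last_input + 1):
            arrival = y + w.travel_time + off
            if config.start_year <= arrival <= config.end_year:
                acc[w.watershed_id][arrival - config.start_year] += w.delivered_rate
    return {
        ws: LoadingSeries(ws, config.start_year, values) for ws, values in acc.items()
    }


def series_to_tidy_frame(
    series: Mapping[str, LoadingSeries],
    scenario: str = "status_quo",
    iteration: int | None = None,
) -> pd.DataFrame:
    """Stack per-watershed series into the tidy output layout
    (scenario, iteration, watershed_id, year, load_kg)."""
    frames = []
    for ws in series:
        f = series[ws].to_frame()
        f.insert(0, "scenario", scenario)
        f.insert(1, "iteration", iteration if iteration is not None else 0)
        frames.append(f)
    if not frames:
        return pd.DataFrame(
            columns=["scenario", "iteration", "watershed_id", "year", "load_kg"]
        )
    return pd.concat(frames, ignore_index=True)
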