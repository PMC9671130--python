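"""Equilibrium diagnostics, legacy summaries, watershed summaries, and
concentration/growth arithmetic.

A watershed is *in equilibrium* when the annual load arriving at its bay
already equals the eventual maximum implied by its current sources — no
lagged increase remains in transit. The diagnostics here quantify how far a
watershed is from that state (ratio of maximum future to current load, years
until the load plateaus) and convert legacy-scenario output into mass
summaries (metric tons, and multiples of the current annual load).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import EngineConfig, LoadingSeries
from .parcels import ParcelTable, Watershed
from .scenarios import ScenarioConfig


@dataclass(frozen=True)
class EquilibriumMetrics:
    """How a watershed's delivered load compares with its eventual maximum.

    ratio = max future load / current load (inf when the current load is zero
    but future load is not); years_to_equilibrium is the wait, from the
    current year, until the series first reaches (1 - epsilon) of its future
    maximum (0 when already there).
    """

    watershed_id: str
    current_load: float
    max_future_load: float
    ratio: float
    in_equilibrium: bool
    years_to_equilibrium: int


@dataclass(frozen=True)
class LegacySummary:
    """Legacy nitrogen per watershed: absolute metric tons, and expressed as
    years of loading at the current annual rate (None when the current load
    is zero)."""

    watershed_id: str
    legacy_mass_tons: float
    multiples_of_current: float | None
    tmdl_status: str


@dataclass(frozen=True)
class WatershedSummary:
    """Property counts, year-built and travel-time statistics, and the
    maximal annual load for one watershed. Standard deviations are sample
    (n - 1) values and are missing (None) when a column has fewer than two
    distinct values."""

    watershed_id: str
    property_count: int
    mean_year_built: float | None
    sd_year_built: float | None
    mean_travel_time: float | None
    sd_travel_time: float | None
    annual_max_load: float | None


def equilibrium_metrics(
    series: LoadingSeries,
    engine: EngineConfig = EngineConfig(),
    epsilon: float = 0.01,
) -> EquilibriumMetrics:
    """Equilibrium diagnostics from a status-quo loading series.

    ``ratio`` is the maximum load over (current_year, end_year] divided by
    the load at current_year; the watershed is in equilibrium iff
    ratio <= 1 + epsilon. ``years_to_equilibrium`` is the first year the
    series reaches (1 - epsilon) x max future load, minus the current year,
    clamped to >= 0 — the near-maximum crossing avoids horizon-edge
    artifacts from the exact maximum.
    """
    current = series.at(engine.current_year)
    future = series.values[engine.current_year - series.start_year + 1 :]
    max_future = float(future.max()) if future.size else current
    if current > 0:
        ratio = max_future / current
    elif max_future > 0:
        ratio = math.inf
    else:
        ratio = 1.0
    in_eq = ratio <= 1.0 + epsilon
    threshold = (1.0 - epsilon) * max_future
    reached = np.nonzero(series.values >= threshold)[0]
    first = int(reached[0]) + series.start_year if reached.size else series.end_year
    years = max(first - engine.current_year, 0)
    return EquilibriumMetrics(
        watershed_id=series.watershed_id,
        current_load=current,
        max_future_load=max_future,
        ratio=ratio,
        in_equilibrium=in_eq,
        years_to_equilibrium=0 if in_eq else years,
    )


def legacy_summary(
    legacy_series: LoadingSeries,
    current_load: float,
    watershed: Watershed,
    scenario: ScenarioConfig = ScenarioConfig(kind="legacy"),
) -> LegacySummary:
    """Summarize a legacy-scenario series for one watershed.

    legacy mass (tons) = tally-window sum / 1000; multiples of current =
    tally sum / current annual load, None when that load is zero.
    """
    tally = legacy_series.window_sum(
        scenario.legacy_tally_start, scenario.legacy_tally_end
    )
    multiples = tally / current_load if current_load > 0 else None
    return LegacySummary(
        watershed_id=legacy_series.watershed_id,
        legacy_mass_tons=tally / 1000.0,
        multiples_of_current=multiples,
        tmdl_status=watershed.tmdl_status,
    )


def _mean_sd(values: Sequence[float]) -> tuple[float | None, float | None]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return None, None
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if np.unique(arr).size >= 2 else None
    return mean, sd


def summarize_watershed(
    parcels: ParcelTable,
    status_quo: LoadingSeries | None = None,
) -> WatershedSummary:
    """Per-watershed summary statistics over a single watershed's parcels.

    Means and sample (n - 1) standard deviations of year built and travel
    time; the annual maximal load is the maximum of the status-quo delivered
    series over the full horizon (None when no series is given). sd fields
    are missing when a column has fewer than two distinct values — e.g. a
    watershed whose parcels all sit in one travel-time zone.
    """
    ws_ids = parcels.watershed_ids
    if len(ws_ids) > 1:
        raise ValueError(f"parcels span several watersheds: {ws_ids}")
    ws = ws_ids[0] if ws_ids else (status_quo.watershed_id if status_quo else "")
    mean_yb, sd_yb = _mean_sd([p.year_built for p in parcels])
    mean_tt, sd_tt = _mean_sd([p.travel_time for p in parcels])
    max_load = float(status_quo.values.max()) if status_quo is not None else None
    return WatershedSummary(
        watershed_id=ws,
        property_count=len(parcels),
        mean_year_built=mean_yb,
        sd_year_built=sd_yb,
        mean_travel_time=mean_tt,
        sd_travel_time=sd_tt,
        annual_max_load=max_load,
    )


def summarize_region(
    parcels: ParcelTable,
    status_quo: dict[str, LoadingSeries] | None = None,
) -> pd.DataFrame:
    """One summary row per watershed, in the packaged reference-table column
    order."""
    rows = []
    for ws in parcels.watershed_ids:
        s = summarize_watershed(
            parcels.subset(ws), status_quo.get(ws) if status_quo else None
        )
        rows.append(
            {
                "watershed_id": s.watershed_id,
                "property_count": s.property_count,
                "mean_year_built": s.mean_year_built,
                "sd_year_built": s.sd_year_built,
                "mean_travel_time_yr": s.mean_travel_time,
                "sd_travel_time_yr": s.sd_travel_time,
                "annual_max_load_kg": s.annual_max_load,
            }
        )
    return pd.DataFrame(rows)


def cagr(total_growth: float, n_years: float) -> float:
    """Compound annual growth rate equivalent to a total fractional growth
    over n_years: (1 + g)^(1/n) - 1."""
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    if total_growth <= -1:
        raise ValueError("total_growth must exceed -1")
    return (1.0 + total_growth) ** (1.0 / n_years) - 1.0


def net_concentration_reduction(
    delivered_concentration: float, treated_concentration: float
) -> float:
    """Net concentration benefit (mg/L) of source control at one property:
    what actually reaches the bay today minus the treated effluent
    concentration, floored at zero — natural attenuation en route means the
    realized benefit is smaller than the at-source reduction."""
    if delivered_concentration < 0 or treated_concentration < 0:
        raise ValueError("concentrations must be non-negative")
    return max(delivered_concentration - treated_concentration, 0.0)


def attenuate_concentration(initial: float, factors: Iterable[float]) -> float:
    """Concentration remaining after passing through a chain of attenuating
    features (soil, ponds, wetlands), each removing its fraction:
    initial x prod(1 - f_i)."""
    if initial < 0:
        raise ValueError("initial concentration must be non-negative")
    out = float(initial)
    for f in factors:
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"attenuation factor {f} outside [0, 1]")
        out *= 1.0 - f
    return out


def load_reference_table() -> pd.DataFrame:
    """The packaged 54-embayment reference table (property counts, year-built
    and travel-time statistics, maximal annual load); '-' cells are NaN."""
    with resources.files("nload.data").joinpath("table1.csv").open("r") as fh:
        return pd.read_csv(fh)


def metrics_frame(
    equilibrium: Iterable[EquilibriumMetrics],
    legacy: Iterable[LegacySummary] = (),
    summaries: Iterable[WatershedSummary] = (),
) -> pd.DataFrame:
    """Join the three per-watershed metric families into one tidy frame
    (one row per watershed; missing families leave NaN columns)."""
    eq = pd.DataFrame(
        [
            {
                "watershed_id": m.watershed_id,
                "current_load_kg_yr": m.current_load,
                "max_future_load_kg_yr": m.max_future_load,
                "ratio": m.ratio,
                "in_equilibrium": m.in_equilibrium,
                "years_to_equilibrium": m.years_to_equilibrium,
            }
            for m in equilibrium
        ]
    )
    lg = pd.DataFrame(
        [
            {
                "watershed_id": s.watershed_id,
                "legacy_mass_tons": s.legacy_mass_tons,
                "legacy_multiples_of_current": s.multiples_of_current,
                "tmdl_status": s.tmdl_status,
            }
            for s in legacy
        ]
    )
    sm = pd.DataFrame(
        [
            {
                "watershed_id": s.watershed_id,
                "property_count": s.property_count,
                "mean_year_built": s.mean_year_built,
                "sd_year_built": s.sd_year_built,
                "mean_travel_time_yr": s.mean_travel_time,
                "sd_travel_time_yr": s.sd_travel_time,
                "annual_max_load_kg": s.annual_max_load,
            }
            for s in summaries
        ]
    )
    out = eq
    for other in (lg, sm):
        if not other.empty:
            out = out.merge(other, on="watershed_id", how="outer") if not out.empty else other
    return out
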