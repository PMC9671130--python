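import math

import numpy as np
import pytest

from nload.engine import EngineConfig
from nload.parcels import Parcel, ParcelTable, Watershed


def mk_parcel(
    parcel_id="P1",
    watershed_id="W1",
    year_built=2000,
    raw_load=10.0,
    attenuation=0.0,
    travel_time=5.0,
    sewered=False,
    buildout_delta=0.0,
):
    return Parcel(
        parcel_id=parcel_id,
        watershed_id=watershed_id,
        year_built=year_built,
        raw_load=raw_load,
        attenuation=attenuation,
        travel_time=travel_time,
        sewered=sewered,
        buildout_delta=buildout_delta,
    )


def random_table(rng: np.random.Generator, n_parcels: int, n_watersheds: int = 3,
                 config: EngineConfig = EngineConfig()) -> ParcelTable:
    """A randomized parcel table for invariant tests (heavy-tailed loads,
    arbitrary attenuation/travel times, some sewered/buildable parcels)."""
    parcels = []
    for i in range(n_parcels):
        parcels.append(
            Parcel(
                parcel_id=f"P{i:04d}",
                watershed_id=f"W{rng.integers(n_watersheds)}",
                year_built=int(rng.integers(config.start_year - 30, config.current_year + 1)),
                raw_load=float(rng.lognormal(2.0, 1.0)),
                attenuation=float(rng.uniform(0, 1)),
                travel_time=float(rng.uniform(0, 60)),
                sewered=bool(rng.random() < 0.2),
                buildout_delta=float(rng.lognormal(1.5, 1.0)) if rng.random() < 0.3 else 0.0,
            )
        )
    return ParcelTable(tuple(parcels), provenance="random test table")


def closed_form_legacy(parcels, scenario, engine=EngineConfig()):
    """Independent per-parcel legacy-mass count used as an oracle.

    For each parcel, inputs run from its (clamped) year built through the
    year before shutoff; each input year's packet arrives after the
    travel-time shift; mass inside the tally window is rate x overlap.
    """
    off = engine.arrival_offset
    masses = {ws: 0.0 for ws in parcels.watershed_ids}
    for p in parcels:
        tau = math.floor(p.travel_time)
        start = max(p.year_built, engine.start_year)
        last_input = scenario.legacy_shutoff_year - 1
        if last_input < start:
            continue
        first_arrival = start + tau + off
        last_arrival = last_input + tau + off
        a = max(first_arrival, scenario.legacy_tally_start, engine.start_year)
        b = min(last_arrival, scenario.legacy_tally_end, engine.end_year)
        if b >= a:
            masses[p.watershed_id] += p.delivered_rate * (b - a + 1)
    return masses


@pytest.fixture
def three_watersheds():
    return [
        Watershed("W1", "First Bay", "final"),
        Watershed("W2", "Second Bay", "none_or_pending"),
        Watershed("W3", "Third Bay", "final"),
    ]


@pytest.fixture
def small_table():
    return ParcelTable(
        (
            mk_parcel("P1", "W1", 1950, 10.0, 0.0, 0.0),
            mk_parcel("P2", "W1", 2010, 10.0, 0.2, 30.0),
            mk_parcel("P3", "W2", 1990, 20.0, 0.5, 10.0, sewered=True),
        ),
        provenance="three-parcel fixture",
    )
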