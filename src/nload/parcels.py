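"""Parcel-level domain types, validation, and CSV input/output.

A *parcel* is a single nitrogen source in an estuary watershed: typically a
residential or commercial property whose wastewater (septic or cesspool)
recharges the groundwater. Each parcel carries the attributes the annual
simulator needs: the year it started loading (year built), the raw nitrogen
load entering groundwater, the fraction removed by natural attenuation en
route to the bay (soils, ponds, wetlands), the groundwater travel time to the
embayment, whether the parcel is sewered, and the additional load it could
contribute if developed further ("buildout").

The on-disk format is a flat CSV (schema version "1") with columns::

    parcel_id, watershed_id, year_built, raw_load_kg_yr,
    attenuation_fraction, travel_time_yr, sewered, buildout_delta_kg_yr

Watersheds live in a companion CSV: ``watershed_id, name, tmdl_status``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .exceptions import SchemaError, ValidationError

SCHEMA_VERSION = "1"

PARCEL_COLUMNS = [
    "parcel_id",
    "watershed_id",
    "year_built",
    "raw_load_kg_yr",
    "attenuation_fraction",
    "travel_time_yr",
    "sewered",
    "buildout_delta_kg_yr",
]

WATERSHED_COLUMNS = ["watershed_id", "name", "tmdl_status"]

TMDL_STATUSES = ("final", "none_or_pending")


@dataclass(frozen=True)
class Parcel:
    """One nitrogen source with its load, attenuation, travel time, and
    activity window.

    Parameters
    ----------
    parcel_id : str
        Unique identifier.
    watershed_id : str
        Watershed (embayment contributing area) the parcel drains to.
    year_built : int
        Calendar year the property was built; loading starts this year.
    raw_load : float
        kg N per year entering groundwater before attenuation.
    attenuation : float
        Fraction in [0, 1] removed en route to the bay.
    travel_time : float
        Groundwater travel time to the bay in years (>= 0); the engine
        discretizes it to whole years by flooring.
    sewered : bool
        True if connected to a sewer (not a candidate for septic upgrades).
    buildout_delta : float
        kg N per year of potential additional load under development
        (0 if the parcel is not buildable).
    """

    parcel_id: str
    watershed_id: str
    year_built: int
    raw_load: float
    attenuation: float
    travel_time: float
    sewered: bool
    buildout_delta: float = 0.0

    @property
    def delivered_rate(self) -> float:
        """kg N/yr reaching the bay once in steady state: raw_load x (1 - attenuation)."""
        return self.raw_load * (1.0 - self.attenuation)

    @property
    def delivered_buildout_rate(self) -> float:
        """Attenuated buildout increment, kg N/yr."""
        return self.buildout_delta * (1.0 - self.attenuation)


@dataclass(frozen=True)
class Watershed:
    """An embayment's contributing watershed."""

    watershed_id: str
    name: str
    tmdl_status: str = "none_or_pending"

    def __post_init__(self) -> None:
        if self.tmdl_status not in TMDL_STATUSES:
            raise ValueError(
                f"tmdl_status must be one of {TMDL_STATUSES}, got {self.tmdl_status!r}"
            )


@dataclass(frozen=True)
class ParcelTable:
    """An ordered, id-unique collection of parcels plus a provenance note
    (source path or generator seed)."""

    parcels: tuple[Parcel, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.parcels)

    def __iter__(self) -> Iterator[Parcel]:
        return iter(self.parcels)

    def __getitem__(self, i: int) -> Parcel:
        return self.parcels[i]

    @property
    def watershed_ids(self) -> list[str]:
        """Distinct watershed ids in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.parcels:
            seen.setdefault(p.watershed_id, None)
        return list(seen)

    def by_watershed(self) -> dict[str, list[Parcel]]:
        out: dict[str, list[Parcel]] = {}
        for p in self.parcels:
            out.setdefault(p.watershed_id, []).append(p)
        return out

    def subset(self, watershed_id: str) -> "ParcelTable":
        return ParcelTable(
            tuple(p for p in self.parcels if p.watershed_id == watershed_id),
            provenance=f"{self.provenance}[{watershed_id}]",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": [p.parcel_id for p in self.parcels],
                "watershed_id": [p.watershed_id for p in self.parcels],
                "year_built": [p.year_built for p in self.parcels],
                "raw_load_kg_yr": [p.raw_load for p in self.parcels],
                "attenuation_fraction": [p.attenuation for p in self.parcels],
                "travel_time_yr": [p.travel_time for p in self.parcels],
                "sewered": [p.sewered for p in self.parcels],
                "buildout_delta_kg_yr": [p.buildout_delta for p in self.parcels],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "ParcelTable":
        missing = [c for c in PARCEL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"parcel table missing required columns: {missing}")
        parcels = tuple(
            Parcel(
                parcel_id=str(row.parcel_id),
                watershed_id=str(row.watershed_id),
                year_built=int(row.year_built),
                raw_load=float(row.raw_load_kg_yr),
                attenuation=float(row.attenuation_fraction),
                travel_time=float(row.travel_time_yr),
                sewered=_parse_bool(row.sewered),
                buildout_delta=float(row.buildout_delta_kg_yr),
            )
            for row in df.itertuples(index=False)
        )
        return cls(parcels, provenance=provenance)


@dataclass(frozen=True)
class Violation:
    """One validation problem: category, offending parcel (if any), row number
    (1-based data row, if known), and a human-readable message."""

    kind: str
    message: str
    parcel_id: str | None = None
    row: int | None = None

    def __str__(self) -> str:
        loc = f" (row {self.row})" if self.row is not None else ""
        who = f" [{self.parcel_id}]" if self.parcel_id else ""
        return f"{self.kind}{who}{loc}: {self.message}"


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_parcels`: empty iff the table is valid."""

    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def __str__(self) -> str:
        if self.ok:
            return "valid: no violations"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  - {v}" for v in self.violations]
        return "\n".join(lines)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def validate_parcels(
    table: ParcelTable,
    watersheds: Iterable[Watershed] | None = None,
    current_year: int | None = None,
) -> ValidationReport:
    """Check every domain invariant and return a report (never raises).

    Checks per parcel: raw_load >= 0, buildout_delta >= 0, attenuation in
    [0, 1], travel_time >= 0, and (when ``current_year`` is given)
    year_built <= current_year. Across parcels: no duplicate parcel_id.
    When ``watersheds`` is given, every parcel's watershed_id must resolve.
    """
    report = ValidationReport()
    known_ws = {w.watershed_id for w in watersheds} if watersheds is not None else None
    seen: dict[str, int] = {}
    for i, p in enumerate(table, start=1):
        if p.parcel_id in seen:
            report.violations.append(
                Violation(
                    "duplicate_id",
                    f"parcel_id also appears at row {seen[p.parcel_id]}",
                    parcel_id=p.parcel_id,
                    row=i,
                )
            )
        else:
            seen[p.parcel_id] = i
        for name, value, lo, hi in (
            ("raw_load_kg_yr", p.raw_load, 0.0, None),
            ("buildout_delta_kg_yr", p.buildout_delta, 0.0, None),
            ("attenuation_fraction", p.attenuation, 0.0, 1.0),
            ("travel_time_yr", p.travel_time, 0.0, None),
        ):
            if not (value >= lo) or (hi is not None and value > hi):
                bound = f"in [{lo}, {hi}]" if hi is not None else f">= {lo}"
                report.violations.append(
                    Violation(
                        "bounds",
                        f"{name} = {value} must be {bound}",
                        parcel_id=p.parcel_id,
                        row=i,
                    )
                )
        if current_year is not None and p.year_built > current_year:
            report.violations.append(
                Violation(
                    "bounds",
                    f"year_built = {p.year_built} is after the analysis year {current_year}",
                    parcel_id=p.parcel_id,
                    row=i,
                )
            )
        if known_ws is not None and p.watershed_id not in known_ws:
            report.violations.append(
                Violation(
                    "missing_watershed",
                    f"watershed_id {p.watershed_id!r} not in the watershed table",
                    parcel_id=p.parcel_id,
                    row=i,
                )
            )
    return report


def read_parcel_table(path: str | Path, schema_version: str = SCHEMA_VERSION) -> ParcelTable:
    """Read and validate a parcel CSV.

    Raises :class:`SchemaError` for a wrong schema version or missing columns
    and :class:`ValidationError` (carrying the full row-numbered report) when
    any row violates the domain bounds or duplicates an id.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported parcel schema version {schema_version!r}; this reader "
            f"handles version {SCHEMA_VERSION!r}"
        )
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"parcel_id": str, "watershed_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in PARCEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    table = ParcelTable.from_frame(df, provenance=str(path))
    report = validate_parcels(table)
    if not report.ok:
        raise ValidationError(report)
    return table


def write_parcel_table(table: ParcelTable, path: str | Path) -> Path:
    """Write a parcel table as CSV; re-reading yields an equal table."""
    path = Path(path)
    # %.17g guarantees binary round-trip for doubles
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_watershed_table(path: str | Path) -> list[Watershed]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in WATERSHED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(Watershed(str(row.watershed_id), str(row.name), str(row.tmdl_status)))
    ids = [w.watershed_id for w in out]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(
            ValidationReport(
                [Violation("duplicate_id", f"duplicate watershed_id {d!r}") for d in dupes]
            )
        )
    return out


def write_watershed_table(watersheds: Sequence[Watershed], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "watershed_id": [w.watershed_id for w in watersheds],
            "name": [w.name for w in watersheds],
            "tmdl_status": [w.tmdl_status for w in watersheds],
        }
    ).to_csv(path, index=False)
    return path


def watershed_index(watersheds: Iterable[Watershed]) -> Mapping[str, Watershed]:
    return {w.watershed_id: w for w in watersheds}
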