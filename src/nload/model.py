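"""Model/Results facade over the simulator.

:class:`NitrogenLoadingModel` bundles a validated parcel table, the
watershed register, and an engine configuration; its ``run_*`` methods
execute the scenarios and return results objects carrying the series,
the derived metrics, and a ``summary()`` table. The model is mechanistic —
parcels and travel times are inputs, nothing is estimated — so the entry
points are runs rather than fits; Monte Carlo envelopes quantify the
scheduling uncertainty within a scenario.

Typical use::

    from nload import NitrogenLoadingModel, synthetic

    table, sheds = synthetic.generate_region()
    model = NitrogenLoadingModel(table, sheds)
    res = model.run_status_quo()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import metrics as _metrics
from .engine import EngineConfig, LoadingSeries, series_to_tidy_frame
from .exceptions import ValidationError
from .parcels import (
    ParcelTable,
    Watershed,
    read_parcel_table,
    read_watershed_table,
    validate_parcels,
)
from .scenarios import (
    LegacyResult,
    MonteCarloEnvelope,
    ScenarioConfig,
    run_legacy,
    run_monte_carlo,
    run_status_quo,
)


class NitrogenLoadingModel:
    """Dynamic nitrogen-loading model for a set of estuary watersheds.

    Parameters
    ----------
    parcels : ParcelTable
        The nitrogen sources.
    watersheds : sequence of Watershed, optional
        The watershed register; synthesized from the parcel table (all
        statuses ``none_or_pending``) when omitted.
    engine : EngineConfig, optional
        Simulation window and arrival rule.

    Raises :class:`ValidationError` when the inputs violate the domain
    invariants.
    """

    def __init__(
        self,
        parcels: ParcelTable,
        watersheds: Sequence[Watershed] | None = None,
        engine: EngineConfig = EngineConfig(),
    ):
        if watersheds is None:
            watersheds = [Watershed(ws, ws) for ws in parcels.watershed_ids]
        report = validate_parcels(parcels, watersheds)
        if not report.ok:
            raise ValidationError(report)
        self.parcels = parcels
        self.watersheds = list(watersheds)
        self.engine = engine
        self._ws_index = {w.watershed_id: w for w in self.watersheds}

    # ------------------------------------------------------------------ io
    @classmethod
    def from_csv(
        cls,
        parcel_path: str | Path,
        watershed_path: str | Path | None = None,
        engine: EngineConfig = EngineConfig(),
    ) -> "NitrogenLoadingModel":
        parcels = read_parcel_table(parcel_path)
        watersheds = (
            read_watershed_table(watershed_path) if watershed_path is not None else None
        )
        return cls(parcels, watersheds, engine)

    @classmethod
    def from_dataframes(
        cls,
        parcel_df: pd.DataFrame,
        watershed_df: pd.DataFrame | None = None,
        engine: EngineConfig = EngineConfig(),
    ) -> "NitrogenLoadingModel":
        parcels = ParcelTable.from_frame(parcel_df, provenance="<dataframe>")
        watersheds = None
        if watershed_df is not None:
            watersheds = [
                Watershed(str(r.watershed_id), str(r.name), str(r.tmdl_status))
                for r in watershed_df.itertuples(index=False)
            ]
        return cls(parcels, watersheds, engine)

    # ---------------------------------------------------------------- runs
    def run_status_quo(self, epsilon: float = 0.01) -> "StatusQuoResults":
        """Simulate existing sources with no future events."""
        series = run_status_quo(self.parcels, self.engine)
        return StatusQuoResults(self, series, epsilon)

    def run_buildout(
        self, n_iterations: int = 1000, seed: int = 0, keep_iterations: bool = False
    ) -> "MonteCarloResults":
        """Upper-bound development scenario (Monte Carlo over update years)."""
        cfg = ScenarioConfig(kind="buildout", n_iterations=n_iterations, seed=seed)
        env = run_monte_carlo(self.parcels, cfg, self.engine, keep_iterations)
        return MonteCarloResults(self, env)

    def run_source_control(
        self, n_iterations: int = 1000, seed: int = 0, keep_iterations: bool = False
    ) -> "MonteCarloResults":
        """Lower-bound abatement scenario (Monte Carlo over upgrade order)."""
        cfg = ScenarioConfig(kind="source_control", n_iterations=n_iterations, seed=seed)
        env = run_monte_carlo(self.parcels, cfg, self.engine, keep_iterations)
        return MonteCarloResults(self, env)

    def run_legacy(self, scenario: ScenarioConfig | None = None) -> "LegacyResults":
        """Legacy-nitrogen accounting: instantaneous shutoff plus arrival tally."""
        cfg = scenario if scenario is not None else ScenarioConfig(kind="legacy")
        res = run_legacy(self.parcels, cfg, self.engine)
        return LegacyResults(self, res)

    def watershed(self, watershed_id: str) -> Watershed:
        return self._ws_index[watershed_id]


@dataclass
class StatusQuoResults:
    """Status-quo series plus equilibrium diagnostics and Table-1-style
    watershed summaries."""

    model: NitrogenLoadingModel
    series: dict[str, LoadingSeries]
    epsilon: float = 0.01

    def equilibrium(self, epsilon: float | None = None) -> pd.DataFrame:
        eps = self.epsilon if epsilon is None else epsilon
        rows = [
            _metrics.equilibrium_metrics(self.series[ws], self.model.engine, eps)
            for ws in self.series
        ]
        return _metrics.metrics_frame(rows)

    def watershed_summaries(self) -> pd.DataFrame:
        return _metrics.summarize_region(self.model.parcels, self.series)

    def to_tidy_frame(self) -> pd.DataFrame:
        return series_to_tidy_frame(self.series, scenario="status_quo")

    def summary(self) -> str:
        eq = self.equilibrium()
        n = len(eq)
        n_out = int((~eq["in_equilibrium"]).sum())
        finite = eq.loc[eq["ratio"].apply(lambda r: r != float("inf")), "ratio"]
        lines = [
            "Status-quo nitrogen loading results",
            "===================================",
            f"Watersheds:                  {n}",
            f"Not in equilibrium:          {n_out} ({n_out / n:.0%})" if n else "",
            f"Mean ratio (max future/now): {finite.mean():.2f}" if len(finite) else "",
            (
                "Mean years to equilibrium:   "
                f"{eq.loc[~eq['in_equilibrium'], 'years_to_equilibrium'].mean():.1f}"
                if n_out
                else "Mean years to equilibrium:   0.0"
            ),
            f"Current total load (kg/yr):  {eq['current_load_kg_yr'].sum():.0f}",
            f"Max future total (kg/yr):    {eq['max_future_load_kg_yr'].sum():.0f}",
            f"Epsilon (equilibrium tol.):  {self.epsilon}",
        ]
        return "\n".join(s for s in lines if s)

    def plot(self, watershed_id: str, ax=None):
        from .plotting import plot_loading

        return plot_loading(
            self.series[watershed_id], current_year=self.model.engine.current_year, ax=ax
        )


@dataclass
class MonteCarloResults:
    """Monte Carlo envelope (min/mean/max per watershed-year) for a
    stochastic scenario."""

    model: NitrogenLoadingModel
    envelope: MonteCarloEnvelope

    def to_frame(self) -> pd.DataFrame:
        return self.envelope.to_frame()

    def summary(self) -> str:
        env = self.envelope
        idx = self.model.engine.end_year - self.model.engine.start_year
        end_mean = sum(env.mean[ws][idx] for ws in env.watershed_ids)
        end_min = sum(env.minimum[ws][idx] for ws in env.watershed_ids)
        end_max = sum(env.maximum[ws][idx] for ws in env.watershed_ids)
        return "\n".join(
            [
                f"Monte Carlo results: {env.scenario_kind}",
                "===================================",
                f"Watersheds:            {len(env.watershed_ids)}",
                f"Iterations:            {env.n_iterations} (seed {env.seed})",
                f"Horizon-end total load (kg/yr):",
                f"  min  {end_min:.0f}",
                f"  mean {end_mean:.0f}",
                f"  max  {end_max:.0f}",
            ]
        )

    def plot(self, watershed_id: str, ax=None):
        from .plotting import plot_envelope

        return plot_envelope(
            self.envelope, watershed_id, current_year=self.model.engine.current_year, ax=ax
        )


@dataclass
class LegacyResults:
    """Legacy-nitrogen series and mass summaries."""

    model: NitrogenLoadingModel
    result: LegacyResult
    _current: dict[str, float] = field(default_factory=dict)

    def _current_loads(self) -> dict[str, float]:
        if not self._current:
            sq = run_status_quo(self.model.parcels, self.model.engine)
            cy = self.model.engine.current_year
            self._current = {ws: sq[ws].at(cy) for ws in sq}
        return self._current

    def summaries(self) -> pd.DataFrame:
        current = self._current_loads()
        rows = [
            _metrics.legacy_summary(
                self.result.series[ws],
                current.get(ws, 0.0),
                self.model.watershed(ws),
                self.result.scenario,
            )
            for ws in self.result.series
        ]
        df = _metrics.metrics_frame([], legacy=rows)
        df["legacy_mass_from_shutoff_tons"] = [
            self.result.mass_from_shutoff_kg[ws] / 1000.0 for ws in self.result.series
        ]
        return df

    def summary(self) -> str:
        df = self.summaries()
        mult = df["legacy_multiples_of_current"].dropna()
        return "\n".join(
            [
                "Legacy nitrogen results",
                "===================================",
                f"Watersheds:               {len(df)}",
                f"Legacy mass (tons): min   {df['legacy_mass_tons'].min():.1f}",
                f"                    max   {df['legacy_mass_tons'].max():.1f}",
                f"                    total {df['legacy_mass_tons'].sum():.1f}",
                (
                    f"Years-of-loading equiv.:  {mult.min():.1f} to {mult.max():.1f}"
                    if len(mult)
                    else "Years-of-loading equiv.:  n/a"
                ),
                f"Tally window:             "
                f"{self.result.scenario.legacy_tally_start}-"
                f"{self.result.scenario.legacy_tally_end}",
            ]
        )

    def plot(self, ax=None, in_multiples: bool = False):
        from .plotting import plot_legacy_bars

        return plot_legacy_bars(self.summaries(), ax=ax, in_multiples=in_multiples)
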