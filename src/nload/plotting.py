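"""Figures: loading time series with scenario envelopes, equilibrium-ratio
bars, and legacy-mass bars."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .engine import LoadingSeries
from .scenarios import MonteCarloEnvelope


def _axes(ax):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    return ax


def plot_loading(
    series: LoadingSeries,
    current_year: int | None = 2020,
    upper: MonteCarloEnvelope | None = None,
    lower: MonteCarloEnvelope | None = None,
    legacy: LoadingSeries | None = None,
    ax=None,
):
    """One watershed's annual delivered load; optional upper/lower Monte
    Carlo bands and legacy trace, with a dashed current-year marker."""
    ax = _axes(ax)
    ws = series.watershed_id
    ax.plot(series.years, series.values, color="black", lw=1.5, label="status quo")
    for env, color, label in ((upper, "tab:red", "buildout"), (lower, "0.6", "source control")):
        if env is not None and ws in env.minimum:
            ax.fill_between(
                env.years, env.minimum[ws], env.maximum[ws],
                color=color, alpha=0.35, label=label,
            )
            ax.plot(env.years, env.mean[ws], color=color, lw=1.0)
    if legacy is not None:
        ax.plot(legacy.years, legacy.values, color="black", ls=":", lw=1.0, label="legacy")
    if current_year is not None:
        ax.axvline(current_year, color="black", ls="--", lw=0.8)
    ax.set_xlabel("Year")
    ax.set_ylabel("Delivered N load (kg/yr)")
    ax.set_title(ws)
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_envelope(
    envelope: MonteCarloEnvelope,
    watershed_id: str,
    current_year: int | None = 2020,
    ax=None,
):
    """Monte Carlo band (min-max, with the mean traced) for one watershed."""
    ax = _axes(ax)
    color = "tab:red" if envelope.scenario_kind == "buildout" else "0.6"
    ax.fill_between(
        envelope.years,
        envelope.minimum[watershed_id],
        envelope.maximum[watershed_id],
        color=color,
        alpha=0.35,
        label=envelope.scenario_kind,
    )
    ax.plot(envelope.years, envelope.mean[watershed_id], color=color, lw=1.2)
    if current_year is not None:
        ax.axvline(current_year, color="black", ls="--", lw=0.8)
    ax.set_xlabel("Year")
    ax.set_ylabel("Delivered N load (kg/yr)")
    ax.set_title(watershed_id)
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_ratio_bars(metrics: pd.DataFrame, ax=None):
    """Bar chart of max-future-to-current load ratios, sorted descending;
    the horizontal line at 1 marks equilibrium."""
    ax = _axes(ax)
    df = metrics.replace(float("inf"), pd.NA).dropna(subset=["ratio"])
    df = df.sort_values("ratio", ascending=False)
    ax.bar(df["watershed_id"], df["ratio"], color="tab:orange")
    ax.axhline(1.0, color="black", lw=0.8)
    ax.set_ylabel("Max future load / current load")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    return ax


def plot_legacy_bars(summaries: pd.DataFrame, ax=None, in_multiples: bool = False):
    """Legacy nitrogen per watershed, in tons or in multiples of the current
    annual load; watersheds with a final TMDL drawn in red."""
    ax = _axes(ax)
    col = "legacy_multiples_of_current" if in_multiples else "legacy_mass_tons"
    df = summaries.dropna(subset=[col]).sort_values(col, ascending=False)
    colors = [
        "tab:red" if s == "final" else "tab:green" for s in df["tmdl_status"]
    ]
    ax.bar(df["watershed_id"], df[col], color=colors)
    ax.set_ylabel(
        "Legacy N (multiples of current annual load)" if in_multiples else "Legacy N (tons)"
    )
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    return ax
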