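"""Cumulative emission aggregation and regime contrasts.

Twelve 20-min chamber sessions, one every 2 h, give per-head hourly fluxes
f_i at hours-of-day t_i. The day cumulative emission is the trapezoidal sum

    E_day = sum_i (f_i + f_{i+1})/2 * (t_{i+1} - t_i)

closed periodically: a final trapezoid from t_n back to t_1 + 24 h (using
(f_n + f_1)/2) makes the integral span a full day, since the open sum over a
12-session protocol covers only 22 h. Seasonal cumulative emission is
day * season_length / 1000 (kg head^-1); annual totals per regime add the
warm and cold seasonal values (traditional grazing TG = warm grazing YWG +
cold grazing YCG; warm-grazing-cold-feeding WGCF = YWG + cold indoor
feeding YCF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: regime -> (warm-season group, cold-season group)
REGIME_SEASONS = {"TG": ("YWG", "YCG"), "WGCF": ("YWG", "YCF")}

HOURS_PER_DAY = 24.0


@dataclass
class EmissionSeries:
    """Daily session fluxes for one animal and gas."""

    animal_id: str
    gas: str
    times_h: np.ndarray  # hours of day, strictly increasing, within [0, 24)
    fluxes: np.ndarray  # g head^-1 h^-1

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.fluxes = np.asarray(self.fluxes, dtype=float)
        if self.times_h.shape != self.fluxes.shape or self.times_h.ndim != 1:
            raise ValueError("times_h and fluxes must be 1-D and equal length")
        if len(self.times_h) < 1:
            raise ValueError("need at least one session")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("session times must be strictly increasing")
        if not np.all(np.isfinite(self.fluxes)):
            raise ValueError("fluxes must be finite")


@dataclass
class EmissionSummary:
    """Day / seasonal (and, at regime level, annual) cumulative emissions."""

    label: str  # group or regime name
    gas: str
    day_g: float | None = None  # g head^-1 d^-1
    seasonal_kg: float | None = None  # kg head^-1
    annual_kg: float | None = None  # kg head^-1 (regime level)
    season_length_days: int = 180


def day_cumulative(series: EmissionSeries, closure: str = "periodic") -> float:
    """Trapezoidal day cumulative emission, g head^-1 d^-1.

    closure="periodic" (default) appends the wrap-around trapezoid from the
    last session back to the first at t_1 + 24 h; "open" returns the bare
    sum over consecutive sessions only (which under-covers the day).
    """
    if closure not in ("periodic", "open"):
        raise ValueError("closure must be 'periodic' or 'open'")
    t = series.times_h
    f = series.fluxes
    if len(t) < 2:
        raise ValueError("day_cumulative needs >= 2 sessions")
    open_sum = float(np.trapezoid(f, t))
    if closure == "open":
        return open_sum
    closing = (f[-1] + f[0]) / 2.0 * (t[0] + HOURS_PER_DAY - t[-1])
    return open_sum + float(closing)


def seasonal_cumulative(day_g: float, season_length_days: int) -> float:
    """Scale a day total (g head^-1 d^-1) to a seasonal total in kg head^-1."""
    if not np.isfinite(day_g):
        raise ValueError("day emission must be finite")
    return day_g * season_length_days / 1000.0


def annual_cumulative(warm_kg: float | None, cold_kg: float | None) -> float:
    """Annual cumulative emission as warm + cold seasonal totals (kg head^-1)."""
    if warm_kg is None or cold_kg is None:
        raise ValueError("both warm and cold seasonal values are required")
    return warm_kg + cold_kg


def percent_difference(a: float, b: float) -> float:
    """(a - b) / b * 100: how much higher a is than the comparison value b."""
    if b == 0:
        raise ValueError("comparison value b must be non-zero")
    return (a - b) / b * 100.0


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero, as printed in report tables."""
    factor = 10.0**decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


def summarize_emissions(
    day_by_group: dict[tuple[str, str], float], season_length_days: int = 180
) -> pd.DataFrame:
    """Build the group + regime emission summary table.

    Parameters
    ----------
    day_by_group:
        (group, gas) -> day cumulative emission in g head^-1 d^-1, for groups
        YWG/YCG/YCF and gases CO2/CH4.

    Returns a tidy frame with one row per (label, gas): groups carry day and
    seasonal values, regimes carry the annual total.
    """
    gases = sorted({gas for (_, gas) in day_by_group})
    rows = []
    seasonal: dict[tuple[str, str], float] = {}
    for (group, gas), day_g in sorted(day_by_group.items()):
        s_kg = seasonal_cumulative(day_g, season_length_days)
        seasonal[(group, gas)] = s_kg
        rows.append(
            {"label": group, "level": "group", "gas": gas, "day_g": day_g,
             "seasonal_kg": s_kg, "annual_kg": np.nan}
        )
    for regime, (warm, cold) in REGIME_SEASONS.items():
        for gas in gases:
            if (warm, gas) in seasonal and (cold, gas) in seasonal:
                rows.append(
                    {"label": regime, "level": "regime", "gas": gas,
                     "day_g": np.nan, "seasonal_kg": np.nan,
                     "annual_kg": annual_cumulative(seasonal[(warm, gas)], seasonal[(cold, gas)])}
                )
    return pd.DataFrame(rows)


def mean_series_by_group(
    estimates: pd.DataFrame, metadata: pd.DataFrame
) -> dict[tuple[str, str], EmissionSeries]:
    """Average QC-passed fluxes within (group, gas, hour) and build one
    EmissionSeries per group and gas.

    ``estimates`` needs columns sample_id, gas, hour, flux_g_head_h (QC
    already applied); ``metadata`` maps sample_id -> group. The join is by
    sample (a season-specific observation of an animal), not by animal: the
    same animal is measured in both the warm and cold season under a
    different group label.
    """
    merged = estimates.merge(metadata[["sample_id", "group"]], on="sample_id")
    out: dict[tuple[str, str], EmissionSeries] = {}
    for (group, gas), sub in merged.groupby(["group", "gas"]):
        hourly = sub.groupby("hour")["flux_g_head_h"].mean().sort_index()
        out[(group, gas)] = EmissionSeries(
            animal_id=f"<{group}>", gas=gas,
            times_h=hourly.index.to_numpy(dtype=float),
            fluxes=hourly.to_numpy(dtype=float),
        )
    return out
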