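"""Per-session gas flux estimation from static-chamber concentration series.

A sealed breathing chamber is lowered over the animal and the head-space
CO2/CH4 concentration is recorded for ~20 min. Under steady emission the
concentration rises linearly; the flux per head follows from the ideal-gas
relation

    F = dc/dt * (V/N) * (M/22.4) * (P/P0) * (273/(273+T))

with dc/dt in ppm s^-1, chamber volume V in m^3, N animals, molar mass M
(44 for CO2, 16 for CH4), molar volume 22.4 L mol^-1 at STP, and a pressure/
temperature density correction. Evaluated in these units the product is in
mg s^-1 per head; an explicit *3600/1000 = *3.6 converts to g head^-1 h^-1.
Sessions whose linear fit has R^2 below a threshold (default 0.9) are
discarded by the QC gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: molar mass of the measured gases, g mol^-1
MOLAR_MASS = {"CO2": 44.0, "CH4": 16.0}
#: molar volume at standard temperature and pressure, L mol^-1
MOLAR_VOLUME_L = 22.4
#: standard atmospheric pressure, Pa
P0_PA = 1.013e5
#: default chamber volume, m^3 (2.40 x 1.80 x 1.80 sealed outer cage)
DEFAULT_VOLUME_M3 = 2.40 * 1.80 * 1.80

GASES = tuple(MOLAR_MASS)


@dataclass
class ChamberSession:
    """One sealed-chamber measurement: a concentration time series plus the
    physical constants needed to convert its slope to a flux."""

    session_id: str
    animal_id: str
    gas: str
    times: np.ndarray  # seconds from chamber closure, strictly increasing
    concentrations: np.ndarray  # ppm
    volume_m3: float = DEFAULT_VOLUME_M3
    n_heads: int = 1
    pressure_pa: float = P0_PA
    temp_c: float = 0.0
    p0_pa: float = P0_PA

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.gas not in MOLAR_MASS:
            raise ValueError(f"gas must be one of {sorted(MOLAR_MASS)}, got {self.gas!r}")
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(self.times) < 3:
            raise ValueError(f"session {self.session_id}: need >= 3 points, got {len(self.times)}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"session {self.session_id}: times must be strictly increasing")
        if self.volume_m3 <= 0:
            raise ValueError(f"session {self.session_id}: chamber volume must be positive")
        if self.n_heads < 1:
            raise ValueError(f"session {self.session_id}: n_heads must be >= 1")
        if self.pressure_pa <= 0:
            raise ValueError(f"session {self.session_id}: pressure must be positive")
        if self.temp_c <= -273:
            raise ValueError(f"session {self.session_id}: temperature below absolute zero")

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass
class FluxEstimate:
    """Fitted slope, fit quality and the converted per-head flux."""

    session_id: str
    animal_id: str
    gas: str
    slope_ppm_per_s: float
    r_squared: float
    flux_g_per_head_h: float
    qc_pass: bool
    flux_mg_per_head_s: float = field(default=math.nan)
    molar_mass: float = field(default=math.nan)
    molar_volume_l: float = MOLAR_VOLUME_L


def fit_slope(session: ChamberSession) -> tuple[float, float]:
    """Ordinary least squares of concentration on time.

    Returns ``(slope_ppm_per_s, r_squared)``. A constant series has zero
    total sum of squares; its R^2 is defined as 0 (a flat trace carries no
    flux information and must fail QC), with slope 0.
    """
    t = session.times
    c = session.concentrations
    t_bar = t.mean()
    c_bar = c.mean()
    s_tt = float(np.sum((t - t_bar) ** 2))
    s_tc = float(np.sum((t - t_bar) * (c - c_bar)))
    slope = s_tc / s_tt
    ss_tot = float(np.sum((c - c_bar) ** 2))
    if ss_tot == 0.0:
        return 0.0, 0.0
    residuals = c - (c_bar + slope * (t - t_bar))
    ss_res = float(np.sum(residuals**2))
    r_squared = 1.0 - ss_res / ss_tot
    return slope, min(max(r_squared, 0.0), 1.0)


def flux_conversion_factor(session: ChamberSession) -> float:
    """Multiplier taking a slope in ppm s^-1 to a flux in g head^-1 h^-1."""
    m = MOLAR_MASS[session.gas]
    mg_per_s_per_ppm = (
        (session.volume_m3 / session.n_heads)
        * (m / MOLAR_VOLUME_L)
        * (session.pressure_pa / session.p0_pa)
        * (273.0 / (273.0 + session.temp_c))
    )
    return mg_per_s_per_ppm * 3.6  # mg s^-1 -> g h^-1


def concentration_flux(slope: float, session: ChamberSession) -> float:
    """Convert a fitted concentration slope (ppm s^-1) to g head^-1 h^-1."""
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    return slope * flux_conversion_factor(session)


def slope_for_flux(flux_g_per_head_h: float, session: ChamberSession) -> float:
    """Inverse conversion: the concentration slope (ppm s^-1) a given true
    per-head flux produces in this chamber. Used by the simulator."""
    return flux_g_per_head_h / flux_conversion_factor(session)


def estimate_flux(session: ChamberSession, qc_r2_min: float = 0.9) -> FluxEstimate:
    """Fit the slope, convert to a flux, and apply the R^2 QC rule."""
    slope, r2 = fit_slope(session)
    factor = flux_conversion_factor(session)
    return FluxEstimate(
        session_id=session.session_id,
        animal_id=session.animal_id,
        gas=session.gas,
        slope_ppm_per_s=slope,
        r_squared=r2,
        flux_g_per_head_h=slope * factor,
        qc_pass=r2 >= qc_r2_min,
        flux_mg_per_head_s=slope * factor / 3.6,
        molar_mass=MOLAR_MASS[session.gas],
    )


def qc_filter(
    estimates: list[FluxEstimate], r2_min: float = 0.9
) -> tuple[list[FluxEstimate], list[FluxEstimate]]:
    """Partition estimates into (kept, dropped) by ``r_squared >= r2_min``.

    The threshold is inclusive and input order is preserved in both lists.
    """
    kept = [e for e in estimates if e.r_squared >= r2_min]
    dropped = [e for e in estimates if e.r_squared < r2_min]
    return kept, dropped
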