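"""Soil thermal and moisture state: 20 cm soil temperature and a bucket
water balance expressed as water-filled pore space (WFPS).

Soil temperature follows a first-order monthly relaxation toward air
temperature, which attenuates and lags the seasonal cycle the way a
shallow soil layer does without solving the heat equation.  The water
balance is a single-layer bucket: Thornthwaite potential
evapotranspiration, an actual-ET ramp that saturates at half capacity,
and instantaneous runoff of any overflow.  Both states drive the carbon
fluxes -- soil temperature and WFPS set heterotrophic respiration, WFPS
co-limits photosynthesis.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SoilState",
    "WaterFluxes",
    "update_soil_temperature",
    "thornthwaite_heat_index",
    "day_length_hours",
    "potential_evapotranspiration",
    "update_soil_water",
    "wfps",
]

#: Default relaxation rate of 20 cm soil temperature toward air temperature.
DEFAULT_ALPHA = 0.6

#: Mid-month day of year on the 365-day calendar.
_MID_MONTH_DOY = np.array([16, 45, 75, 105, 136, 166, 197, 228, 258, 289, 319, 350])

_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)


@dataclass
class SoilState:
    """Per-cell soil state: 20 cm temperature (degC) and bucket store (mm)."""

    t_soil20: np.ndarray
    water: np.ndarray

    def copy(self) -> "SoilState":
        return SoilState(np.array(self.t_soil20, copy=True),
                         np.array(self.water, copy=True))


@dataclass
class WaterFluxes:
    """Monthly water fluxes, mm: potential ET, actual ET, runoff."""

    pet: np.ndarray
    aet: np.ndarray
    runoff: np.ndarray


def update_soil_temperature(t_prev, t_air, alpha: float = DEFAULT_ALPHA):
    """One monthly step of t' = t + alpha*(t_air - t), fixed point at t_air.

    alpha in (0, 1]: 1 means the soil tracks the air instantly; smaller
    values attenuate the seasonal amplitude by the discrete low-pass gain
    alpha / sqrt(alpha^2 + 2(1-alpha)(1-cos w)) at frequency w.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    return t_prev + alpha * (np.asarray(t_air) - t_prev)


def thornthwaite_heat_index(monthly_tair) -> np.ndarray:
    """Annual heat index I = sum over months of (T/5)^1.514 for T > 0.

    monthly_tair: (..., 12) mean monthly air temperature, degC.
    """
    t = np.maximum(np.asarray(monthly_tair, dtype=float), 0.0)
    return np.sum((t / 5.0) ** 1.514, axis=-1)


def day_length_hours(latitude, month) -> np.ndarray:
    """Mid-month day length from the standard solar-declination formula,
    clamped to [0, 24] toward the poles."""
    doy = _MID_MONTH_DOY[np.asarray(month) - 1]
    decl = -23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.0)
    phi = np.deg2rad(np.asarray(latitude, dtype=float))
    x = -np.tan(phi) * np.tan(np.deg2rad(decl))
    ha = np.arccos(np.clip(x, -1.0, 1.0))
    return 24.0 * ha / np.pi


def potential_evapotranspiration(t_air, month, latitude, heat_index) -> np.ndarray:
    """Thornthwaite monthly PET, mm/month.

    Unadjusted e = 16*(10*T/I)^a for T > 0 (zero at or below freezing),
    a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239, then scaled by
    (day length / 12) * (month days / 30).  ``heat_index`` is the annual
    heat index of the cell's temperature climatology
    (:func:`thornthwaite_heat_index`).
    """
    t = np.asarray(t_air, dtype=float)
    i_idx = np.maximum(np.asarray(heat_index, dtype=float), 1e-9)
    a = (6.75e-7 * i_idx**3 - 7.71e-5 * i_idx**2 + 1.792e-2 * i_idx + 0.49239)
    with np.errstate(invalid="ignore"):
        e = 16.0 * (10.0 * np.maximum(t, 0.0) / i_idx) ** a
    e = np.where(t > 0.0, e, 0.0)
    corr = (day_length_hours(latitude, month) / 12.0) \
        * (_MONTH_DAYS[np.asarray(month) - 1] / 30.0)
    return e * corr


def update_soil_water(water, precip, pet, capacity):
    """One monthly bucket step.

    AET ramps with store: aet = pet * min(1, water/(0.5*capacity)), capped
    at the water actually available (store + rain) so the store never goes
    negative; overflow above capacity leaves as runoff.  The balance
    closes exactly: water' - water = precip - aet - runoff.

    Returns (new_water, WaterFluxes).
    """
    water = np.asarray(water, dtype=float)
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    capacity = np.asarray(capacity, dtype=float)
    if np.any(precip < 0) or np.any(pet < 0):
        raise ValueError("precip and pet must be non-negative")
    aet = pet * np.minimum(1.0, water / (0.5 * capacity))
    aet = np.minimum(aet, water + precip)
    w1 = water + precip - aet
    runoff = np.maximum(w1 - capacity, 0.0)
    new_water = w1 - runoff
    return new_water, WaterFluxes(pet=pet + np.zeros_like(new_water),
                                  aet=aet, runoff=runoff)


def wfps(water, capacity) -> np.ndarray:
    """Water-filled pore space, percent: 100 * store / capacity."""
    capacity = np.asarray(capacity, dtype=float)
    if np.any(capacity <= 0):
        raise ValueError("water capacity must be positive")
    return 100.0 * np.asarray(water, dtype=float) / capacity
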