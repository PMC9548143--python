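"""Annual land-cover transitions with conservative carbon bookkeeping.

Cropland expansion clears the vegetation of the converted area: a burn
fraction of that biomass is released to the atmosphere (spread over the
12 months of the transition year) and the remainder enters the cropland
cohort's soil pool together with the converted area's soil carbon.
Abandonment moves cropland area (and its carbon) back to the natural
types with no release; the abandoned land regrows through ordinary
NPP-litterfall dynamics, which is what makes mid-century afforestation
show up as a lagged carbon sink.

Cohort pools are per unit area (g C m-2 of the cohort), so a transition
mixes the receiving cohort's pools area-weighted with the incoming
carbon.  Total cell carbon plus the released flux is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_forcing import COVER_TYPES

__all__ = ["ConversionFlux", "apply_transition", "net_carbon_exchange"]

_ICROP = COVER_TYPES.index("cropland")
_DEFAULT_BURN = 0.5


@dataclass
class ConversionFlux:
    """Cell-mean conversion carbon, g C m-2 (annual totals).

    released: to the atmosphere in the transition year;
    transferred_to_soil: cleared biomass routed into cropland soil.
    """

    released: np.ndarray
    transferred_to_soil: np.ndarray


def apply_transition(c_veg: np.ndarray, c_soil: np.ndarray,
                     fracs_old: np.ndarray, fracs_new: np.ndarray,
                     burn_fraction: float = _DEFAULT_BURN):
    """Apply one year's cover change to cohort pools.

    Arrays are (..., n_types) with the trailing axis in COVER_TYPES order;
    pools are per-area within each cohort.  Types whose fraction shrinks
    donate area at their current per-area carbon; growing types absorb it
    area-weighted.  Vegetation carbon entering cropland is cleared
    (burn_fraction released, the rest to cropland soil); all other
    transfers move carbon pool-to-pool with no release.

    Returns (c_veg', c_soil', ConversionFlux).
    """
    if burn_fraction < 0 or burn_fraction > 1:
        raise ValueError("burn_fraction must be in [0, 1]")
    c_veg = np.asarray(c_veg, dtype=float)
    c_soil = np.asarray(c_soil, dtype=float)
    old = np.asarray(fracs_old, dtype=float)
    new = np.asarray(fracs_new, dtype=float)
    for f, name in ((old, "fracs_old"), (new, "fracs_new")):
        if np.any(np.abs(f.sum(axis=-1) - 1.0) > 1e-9):
            raise ValueError(f"{name} does not sum to 1")
        if np.any(f < -1e-12):
            raise ValueError(f"{name} has negative fractions")

    delta = new - old
    loss = np.maximum(-delta, 0.0)          # donated area per type
    gain = np.maximum(delta, 0.0)           # absorbed area per type
    total_gain = gain.sum(axis=-1)
    safe_gain = np.where(total_gain > 0, total_gain, 1.0)

    # donated carbon, split into what heads to cropland vs to natural types
    don_veg = (loss * c_veg).sum(axis=-1)
    don_soil = (loss * c_soil).sum(axis=-1)
    gain_to_crop = gain[..., _ICROP] / safe_gain

    released = burn_fraction * don_veg * gain_to_crop
    to_crop_soil = (1.0 - burn_fraction) * don_veg * gain_to_crop

    # area-weighted mixing of receiving cohorts
    share = gain / safe_gain[..., None]     # each receiver's share of donations
    in_veg = share * don_veg[..., None]
    in_soil = share * don_soil[..., None]
    # cropland receives no standing biomass; its share of cleared
    # vegetation goes to soil (minus the burned part)
    in_soil[..., _ICROP] = in_soil[..., _ICROP] + to_crop_soil
    in_veg[..., _ICROP] = 0.0

    new_veg = c_veg.copy()
    new_soil = c_soil.copy()
    grow = new > old
    with np.errstate(invalid="ignore", divide="ignore"):
        mixed_veg = (old * c_veg + in_veg) / np.where(new > 0, new, 1.0)
        mixed_soil = (old * c_soil + in_soil) / np.where(new > 0, new, 1.0)
    new_veg = np.where(grow, mixed_veg, new_veg)
    new_soil = np.where(grow, mixed_soil, new_soil)
    # vanished cohorts keep their per-area pools (zero area; inert bookkeeping)
    flux = ConversionFlux(released=released, transferred_to_soil=to_crop_soil)
    return new_veg, new_soil, flux


def net_carbon_exchange(nep, released):
    """Net carbon exchange diagnostic: NEP minus land-conversion release.
    Equals NEP whenever no conversion occurred."""
    return np.asarray(nep, dtype=float) - np.asarray(released, dtype=float)
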