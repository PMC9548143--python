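"""Monthly carbon fluxes and pools per vegetation cohort.

A transparent multiplicative-limitation model with the bookkeeping
identities of process-based terrestrial ecosystem models:

    GPP = c_max * f_temp * f_co2 * f_light * f_water
    RA  = maintenance (Q10 on vegetation carbon) + growth share of the surplus
    NPP = GPP - RA
    RH  = k_d * Cs * Q10(soil T) * f_water(WFPS)
    NEP = NPP - RH

with two pools per cohort: vegetation carbon Cv (gains NPP, sheds litter
at rate l_f) and soil organic carbon Cs (gains litter, loses RH).  The
identities hold exactly at every step and carbon is conserved: over any
run without land-cover change, cumulative NEP equals the total pool
change to rounding error.

Parameter defaults are calibration choices of this package, tabulated per
cover type below and overridable from YAML.  Nitrogen limitation is
deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic_forcing import COVER_TYPES

__all__ = [
    "BiomeParams",
    "BiomeTable",
    "EnvScalars",
    "default_biome_table",
    "load_biome_table",
    "environmental_scalars",
    "water_scalar",
    "gross_primary_production",
    "autotrophic_respiration",
    "heterotrophic_respiration",
    "step_cohort",
]

#: CO2 reference at which the fertilisation scalar is anchored to 1.
CO2_REFERENCE_PPM = 340.0


@dataclass(frozen=True)
class BiomeParams:
    """Flux parameters of one cover type.

    c_max       maximum monthly GPP, g C m-2 month-1
    t_min/t_opt/t_max  photosynthesis temperature envelope, degC
    k_c         CO2 half-saturation, ppm
    r_m         maintenance respiration per unit Cv, month-1
    r_g         growth-respiration share of the surplus, fraction
    l_f         litterfall rate on Cv, month-1
    k_d         base decomposition rate on Cs at 10 degC, month-1
    q10_veg / q10_soil  respiration temperature sensitivities
    cloud_ext   light-limitation strength per unit cloud fraction
    """

    c_max: float
    t_min: float
    t_opt: float
    t_max: float
    k_c: float = 400.0
    r_m: float = 0.010
    r_g: float = 0.25
    l_f: float = 0.02
    k_d: float = 0.004
    q10_veg: float = 2.0
    q10_soil: float = 2.0
    cloud_ext: float = 0.5

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError("require t_min < t_opt < t_max")
        if not (0.0 <= self.r_g < 1.0):
            raise ValueError("r_g must be in [0, 1)")
        for name in ("c_max", "k_c", "r_m", "l_f", "k_d", "cloud_ext"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.q10_veg < 1.0 or self.q10_soil < 1.0:
            raise ValueError("Q10 must be >= 1")


# Default table: c_max ranks the biomes by productivity (forest > cropland
# > wetland > grassland > shrubland >> bare); litter turnover is slow for
# woody types and fast for herbaceous ones; wetland decomposition is slow.
_DEFAULTS: dict[str, BiomeParams] = {
    "forest":    BiomeParams(c_max=150.0, t_min=-1.0, t_opt=21.0, t_max=42.0,
                             r_m=0.010, l_f=0.012, k_d=0.0045),
    "shrubland": BiomeParams(c_max=60.0, t_min=-3.0, t_opt=18.0, t_max=40.0,
                             r_m=0.011, l_f=0.020, k_d=0.0040),
    "grassland": BiomeParams(c_max=70.0, t_min=-4.0, t_opt=17.0, t_max=38.0,
                             r_m=0.012, l_f=0.045, k_d=0.0040),
    "wetland":   BiomeParams(c_max=90.0, t_min=-2.0, t_opt=18.0, t_max=38.0,
                             r_m=0.011, l_f=0.035, k_d=0.0022),
    "cropland":  BiomeParams(c_max=110.0, t_min=0.0, t_opt=22.0, t_max=42.0,
                             r_m=0.013, l_f=0.060, k_d=0.0050),
    "bare":      BiomeParams(c_max=5.0, t_min=-5.0, t_opt=15.0, t_max=40.0,
                             r_m=0.012, l_f=0.050, k_d=0.0040),
}


@dataclass
class BiomeTable:
    """Parameters for all cover types, with vectorised per-field access."""

    params: dict[str, BiomeParams]

    def __post_init__(self) -> None:
        missing = set(COVER_TYPES) - set(self.params)
        if missing:
            raise ValueError(f"missing biome parameters for {sorted(missing)}")

    def __getitem__(self, cover: str) -> BiomeParams:
        return self.params[cover]

    def vector(self, name: str) -> np.ndarray:
        """(n_types,) array of one parameter in COVER_TYPES order."""
        return np.array([getattr(self.params[t], name) for t in COVER_TYPES])


def default_biome_table() -> BiomeTable:
    return BiomeTable(dict(_DEFAULTS))


def load_biome_table(path) -> BiomeTable:
    """Load biome parameters from YAML: a mapping cover-type -> field
    overrides on top of the defaults."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    table = dict(_DEFAULTS)
    for cover, overrides in doc.items():
        if cover not in table:
            raise KeyError(f"unknown cover type {cover!r}")
        table[cover] = replace(table[cover], **(overrides or {}))
    return BiomeTable(table)


# ---------------------------------------------------------------------------
# Environmental scalars
# ---------------------------------------------------------------------------

@dataclass
class EnvScalars:
    """Dimensionless limitation scalars.  f_temp, f_light and f_water lie
    in [0, 1]; f_co2 is anchored to 1 at 340 ppm and exceeds 1 above it
    (the fertilisation effect must keep growing as CO2 passes the
    reference, so it is floored at 0 but not capped)."""

    f_temp: np.ndarray
    f_co2: np.ndarray
    f_light: np.ndarray
    f_water: np.ndarray


def water_scalar(wfps_percent) -> np.ndarray:
    """Moisture limitation on both photosynthesis and decomposition:
    linear 0 -> 1 over WFPS 0 -> 60%, then declining to 0.6 at saturation
    (anoxia / waterlogging)."""
    w = np.asarray(wfps_percent, dtype=float)
    rising = w / 60.0
    falling = 1.0 - 0.4 * (w - 60.0) / 40.0
    return np.clip(np.where(w <= 60.0, rising, falling), 0.0, 1.0)


def environmental_scalars(t_air, co2, cloud, wfps_percent,
                          params: BiomeParams) -> EnvScalars:
    """Temperature, CO2, light and water scalars for one cover type.

    f_temp is the parabolic-ratio envelope: zero outside (t_min, t_max),
    1 at t_opt.  f_co2 is Michaelis-Menten in CO2 normalised to 1 at
    340 ppm.  f_light = 1 - cloud_ext*cloud.  f_water is the shared
    moisture ramp of :func:`water_scalar`.
    """
    t = np.asarray(t_air, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    if np.any(co2 <= 0):
        raise ValueError("CO2 must be positive")
    num = (t - params.t_min) * (params.t_max - t)
    den = num - (t - params.t_opt) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_temp = np.where((t > params.t_min) & (t < params.t_max) & (den != 0),
                          num / np.where(den == 0, 1.0, den), 0.0)
    f_temp = np.clip(f_temp, 0.0, 1.0)
    ref = CO2_REFERENCE_PPM / (params.k_c + CO2_REFERENCE_PPM)
    f_co2 = np.maximum((co2 / (params.k_c + co2)) / ref, 0.0)
    f_light = np.clip(1.0 - params.cloud_ext * np.asarray(cloud, dtype=float), 0.0, 1.0)
    f_water = water_scalar(wfps_percent)
    return EnvScalars(f_temp=f_temp, f_co2=f_co2, f_light=f_light, f_water=f_water)


# ---------------------------------------------------------------------------
# Fluxes
# ---------------------------------------------------------------------------

def gross_primary_production(scalars: EnvScalars, params: BiomeParams) -> np.ndarray:
    """GPP = c_max times the product of the four scalars; zero whenever any
    limitation is total."""
    return params.c_max * scalars.f_temp * scalars.f_co2 * scalars.f_light \
        * scalars.f_water


def autotrophic_respiration(c_veg, t_air, gpp, params: BiomeParams) -> np.ndarray:
    """RA = maintenance + growth respiration.

    Maintenance rm = r_m * Cv * q10_veg^((T-10)/10); growth respiration is
    r_g of the assimilate left after maintenance (never negative).
    """
    c_veg = np.asarray(c_veg, dtype=float)
    rm = params.r_m * c_veg * params.q10_veg ** ((np.asarray(t_air, dtype=float) - 10.0) / 10.0)
    return rm + params.r_g * np.maximum(np.asarray(gpp, dtype=float) - rm, 0.0)


def heterotrophic_respiration(c_soil, t_soil20, wfps_percent,
                              params: BiomeParams) -> np.ndarray:
    """RH = k_d * Cs * q10_soil^((Tsoil-10)/10) * moisture ramp, capped at
    the soil pool so decomposition cannot overdraw it in a month."""
    c_soil = np.asarray(c_soil, dtype=float)
    rh = params.k_d * c_soil \
        * params.q10_soil ** ((np.asarray(t_soil20, dtype=float) - 10.0) / 10.0) \
        * water_scalar(wfps_percent)
    return np.minimum(rh, c_soil)


def step_cohort(c_veg, c_soil, t_air, t_soil20, co2, cloud, wfps_percent,
                params: BiomeParams):
    """One monthly update of a cohort's pools.

    Returns (c_veg', c_soil', fluxes) where fluxes is a dict with keys
    gpp, ra, npp, rh, nep, litter (g C m-2 month-1).  Pools are floored at
    zero with the deficit deducted from the responsible flux (RA, then
    litter), so (dCv + dCs) == NEP holds exactly even in pathological
    parameter corners.
    """
    c_veg = np.asarray(c_veg, dtype=float)
    c_soil = np.asarray(c_soil, dtype=float)
    scal = environmental_scalars(t_air, co2, cloud, wfps_percent, params)
    gpp = gross_primary_production(scal, params)
    ra = autotrophic_respiration(c_veg, t_air, gpp, params)
    litter = params.l_f * c_veg
    npp = gpp - ra
    # floor Cv at 0: first relax RA, then litter, keeping the balance exact
    new_veg = c_veg + npp - litter
    deficit = np.maximum(-new_veg, 0.0)
    ra_relief = np.minimum(deficit, ra)
    ra = ra - ra_relief
    npp = npp + ra_relief
    deficit = deficit - ra_relief
    litter = litter - np.minimum(deficit, litter)
    new_veg = np.maximum(c_veg + npp - litter, 0.0)

    rh = heterotrophic_respiration(c_soil, t_soil20, wfps_percent, params)
    rh = np.minimum(rh, c_soil + litter)
    new_soil = c_soil + litter - rh
    nep = npp - rh
    fluxes = {"gpp": gpp, "ra": ra, "npp": npp, "rh": rh, "nep": nep,
              "litter": litter}
    return new_veg, new_soil, fluxes
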