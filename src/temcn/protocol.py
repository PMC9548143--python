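"""Simulation protocol: equilibrium, spin-up, transient, and the S1-S4
factorial experiments.

Every grid run follows the same three stages:

1. equilibrium -- each cohort is brought to carbon balance under the
   1900-2000 mean monthly climatology and mean CO2 (|annual NEP| below a
   tolerance for five consecutive years);
2. spin-up -- 150 years cycling the 1900-1949 climate (three passes of
   the 50-year block) with CO2 and land cover held at 1900, which puts
   realistic interannual memory into the initial pools;
3. transient -- 1900-2000 with the drivers set by an ExperimentSpec:
   S1 all transient, S2 CO2 fixed at 1900, S3 climate replaced by the
   1900-1919 mean monthly climatology, S4 land use frozen at 1900.

Factor effects are decadal national NEP differences: CO2 = S1-S2,
climate = S1-S3, land use = S1-S4, with the interaction left as a
residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import carbon_core as cc
from . import land_use as lu
from . import soil_physics as sp
from .synthetic_forcing import (COVER_TYPES, CO2Series, ClimateForcing,
                                GridSpec, LandCoverGrid, SoilProperties)

__all__ = [
    "ExperimentSpec",
    "EXPERIMENTS",
    "CellState",
    "FluxArchive",
    "AttributionResult",
    "run_equilibrium",
    "run_spinup",
    "run_transient",
    "run_factorial",
    "attribution_effects",
]

DEFAULT_TOL = 0.1        # g C m-2 yr-1 equilibrium tolerance
DEFAULT_MAX_ITER = 3000  # years
_CONSEC = 5              # consecutive in-tolerance years required

MONTHLY_FIELDS = ("gpp", "ra", "npp", "rh", "nep", "conversion_flux",
                  "t_soil20", "wfps", "c_veg", "c_soil")


@dataclass(frozen=True)
class ExperimentSpec:
    """Which drivers vary in a transient run (Table-1 style factorial)."""

    co2_mode: str = "transient"       # transient | fixed_1900
    climate_mode: str = "transient"   # transient | fixed_1900_1919_climatology
    luc_mode: str = "transient"       # transient | fixed_1900

    def __post_init__(self) -> None:
        if self.co2_mode not in ("transient", "fixed_1900"):
            raise ValueError(f"bad co2_mode {self.co2_mode!r}")
        if self.climate_mode not in ("transient", "fixed_1900_1919_climatology"):
            raise ValueError(f"bad climate_mode {self.climate_mode!r}")
        if self.luc_mode not in ("transient", "fixed_1900"):
            raise ValueError(f"bad luc_mode {self.luc_mode!r}")


EXPERIMENTS: dict[str, ExperimentSpec] = {
    "S1": ExperimentSpec(),
    "S2": ExperimentSpec(co2_mode="fixed_1900"),
    "S3": ExperimentSpec(climate_mode="fixed_1900_1919_climatology"),
    "S4": ExperimentSpec(luc_mode="fixed_1900"),
}


@dataclass
class CellState:
    """Full model state: per-cohort pools plus per-cell soil state."""

    c_veg: np.ndarray   # (n_cells, n_types) g C m-2
    c_soil: np.ndarray  # (n_cells, n_types) g C m-2
    soil: sp.SoilState  # per-cell
    converged: np.ndarray | None = None  # (n_cells, n_types) bool
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "CellState":
        return CellState(self.c_veg.copy(), self.c_soil.copy(),
                         self.soil.copy(),
                         None if self.converged is None else self.converged.copy(),
                         dict(self.metadata))


@dataclass
class FluxArchive:
    """Monthly cell-mean fields plus annual per-cohort fluxes of one run."""

    grid: GridSpec
    year_start: int
    year_end: int
    monthly: dict[str, np.ndarray]          # (n_months, n_cells)
    annual_by_type: dict[str, np.ndarray]   # (n_years, n_cells, n_types)
    frac: np.ndarray                        # (n_years, n_cells, n_types) as run
    land_fraction: np.ndarray               # (n_cells,)
    c_veg_init: np.ndarray                  # (n_cells,) cell-mean at t0
    c_soil_init: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def annual(self, name: str) -> np.ndarray:
        """(n_years, n_cells) annual sums for fluxes, annual means for
        state variables."""
        a = self.monthly[name].reshape(self.n_years, 12, -1)
        if name in ("t_soil20", "wfps", "c_veg", "c_soil"):
            return a.mean(axis=1)
        return a.sum(axis=1)


@dataclass
class AttributionResult:
    """Decadal national NEP attribution, Tg C yr-1 (1900s..1990s)."""

    decades: np.ndarray          # decade start years
    nep_s1: np.ndarray
    effect_co2: np.ndarray
    effect_climate: np.ndarray
    effect_luc: np.ndarray
    interaction_residual: np.ndarray


# ---------------------------------------------------------------------------
# Shared monthly stepping
# ---------------------------------------------------------------------------

def _climatology(forcing: ClimateForcing, year_a: int, year_b: int):
    """12-month mean cycle of each climate variable over [year_a, year_b]."""
    i0 = forcing.year_start
    sel = slice((year_a - i0) * 12, (year_b - i0 + 1) * 12)
    out = {}
    for name in ("tair", "precip", "cloud"):
        a = getattr(forcing, name)[sel]
        out[name] = a.reshape(-1, 12, a.shape[1]).mean(axis=0)
    return out


def _soil_month(state: sp.SoilState, tair_m, precip_m, lat, month_1based,
                heat_index, props: SoilProperties, alpha: float):
    """Advance soil temperature and the bucket by one month in place;
    returns the month's WFPS (percent)."""
    state.t_soil20 = sp.update_soil_temperature(state.t_soil20, tair_m, alpha)
    pet = sp.potential_evapotranspiration(tair_m, month_1based, lat, heat_index)
    state.water, _ = sp.update_soil_water(state.water, precip_m, pet,
                                          props.water_capacity)
    return sp.wfps(state.water, props.water_capacity)


def _cohort_month(state: CellState, tair_m, co2_y, cloud_m, wfps_m,
                  table: cc.BiomeTable):
    """Advance all cohorts one month; returns per-type flux dict with
    (n_cells, n_types) arrays."""
    n_cells, n_types = state.c_veg.shape
    out = {k: np.empty((n_cells, n_types)) for k in
           ("gpp", "ra", "npp", "rh", "nep", "litter")}
    for j, cover in enumerate(COVER_TYPES):
        p = table[cover]
        nv, ns, fx = cc.step_cohort(state.c_veg[:, j], state.c_soil[:, j],
                                    tair_m, state.soil.t_soil20, co2_y,
                                    cloud_m, wfps_m, p)
        state.c_veg[:, j] = nv
        state.c_soil[:, j] = ns
        for k in out:
            out[k][:, j] = fx[k]
    return out


# ---------------------------------------------------------------------------
# Equilibrium
# ---------------------------------------------------------------------------

def _soil_cycle(clim: dict, props: SoilProperties, grid: GridSpec,
                alpha: float, spin_years: int = 40):
    """Periodic steady annual cycle of soil temperature and WFPS under a
    12-month climatology.  Returns (t_soil (12,n), wfps (12,n), SoilState)."""
    lat, _ = grid.cell_latlon()
    heat_index = sp.thornthwaite_heat_index(clim["tair"].T)
    state = sp.SoilState(t_soil20=clim["tair"].mean(axis=0),
                         water=0.5 * props.water_capacity.copy())
    t_cycle = np.empty_like(clim["tair"])
    w_cycle = np.empty_like(clim["tair"])
    for year in range(spin_years):
        for m in range(12):
            w = _soil_month(state, clim["tair"][m], clim["precip"][m], lat,
                            m + 1, heat_index, props, alpha)
            t_cycle[m] = state.t_soil20
            w_cycle[m] = w
    return t_cycle, w_cycle, state


def _soil_pool_fixed_point(litter_cycle: np.ndarray, decay_cycle: np.ndarray):
    """Fixed point of the periodic linear soil-pool map
    c <- c*(1-d_m) + L_m applied for m = 0..11."""
    n_months = litter_cycle.shape[0]
    one_minus = 1.0 - decay_cycle
    a = np.prod(one_minus, axis=0)
    b = np.zeros_like(litter_cycle[0])
    for m in range(n_months):
        tail = np.prod(one_minus[m + 1:], axis=0) if m + 1 < n_months else 1.0
        b = b + litter_cycle[m] * tail
    denom = np.maximum(1.0 - a, 1e-12)
    return b / denom


def run_equilibrium(forcing_clim: dict, co2_ref: float, props: SoilProperties,
                    grid: GridSpec, table: cc.BiomeTable | None = None,
                    tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                    alpha: float = sp.DEFAULT_ALPHA) -> CellState:
    """Bring every cohort of every cell to equilibrium under a 12-month
    climatology and a reference CO2.

    ``forcing_clim`` holds (12, n_cells) arrays tair/precip/cloud.
    Convergence requires |annual NEP| < tol for five consecutive years;
    cohorts that fail within ``max_iter`` years are flagged (never
    silently accepted).  Because the vegetation pool's dynamics are
    linear in the pool given forcing, the solver closes the soil pool's
    periodic fixed point analytically once vegetation has settled, then
    verifies the stated criterion by plain iteration.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    table = table or cc.default_biome_table()
    t_cycle, w_cycle, soil_state = _soil_cycle(forcing_clim, props, grid, alpha)
    n_cells = grid.n_cells
    n_types = len(COVER_TYPES)
    state = CellState(c_veg=np.zeros((n_cells, n_types)),
                      c_soil=np.zeros((n_cells, n_types)),
                      soil=soil_state,
                      converged=np.zeros((n_cells, n_types), dtype=bool))

    streak = np.zeros((n_cells, n_types), dtype=int)
    accelerated = False
    for year in range(max_iter):
        veg0 = state.c_veg.copy()
        soil0 = state.c_soil.copy()
        litter_cycle = np.empty((12, n_cells, n_types))
        decay_cycle = np.empty((12, n_cells, n_types))
        for m in range(12):
            # replay the periodic soil cycle (same values the transient
            # stepping would produce under this climatology)
            state.soil.t_soil20 = t_cycle[m]
            fx = _cohort_month(state, forcing_clim["tair"][m], co2_ref,
                               forcing_clim["cloud"][m], w_cycle[m], table)
            litter_cycle[m] = fx["litter"]
            for j, cover in enumerate(COVER_TYPES):
                p = table[cover]
                decay_cycle[m, :, j] = (
                    p.k_d * p.q10_soil ** ((t_cycle[m] - 10.0) / 10.0)
                    * cc.water_scalar(w_cycle[m]))
        annual_nep = (state.c_veg - veg0) + (state.c_soil - soil0)
        streak = np.where(np.abs(annual_nep) < tol, streak + 1, 0)
        state.converged = streak >= _CONSEC
        if state.converged.all():
            break
        # once vegetation has settled, jump the slow soil pool to its
        # periodic fixed point (one-time acceleration)
        if not accelerated and year >= 60 and \
                np.max(np.abs(state.c_veg - veg0)) < 0.5 * tol:
            state.c_soil = _soil_pool_fixed_point(litter_cycle, decay_cycle)
            streak[:] = 0
            accelerated = True
    state.metadata = {"equilibrium_years": year + 1,
                      "n_unconverged": int((~state.converged).sum())}
    return state


# ---------------------------------------------------------------------------
# Spin-up and transient
# ---------------------------------------------------------------------------

def run_spinup(state: CellState, forcing: ClimateForcing, co2_1900: float,
               props: SoilProperties, table: cc.BiomeTable | None = None,
               years: int = 150, block: tuple[int, int] = (1900, 1949),
               alpha: float = sp.DEFAULT_ALPHA) -> CellState:
    """Cycle the 1900-1949 climate block (150 years = three passes by
    default) with CO2 and land cover held at 1900.  Returns a new state;
    ``years == 0`` is a no-op copy."""
    if block[1] > forcing.year_end or block[0] < forcing.year_start:
        raise ValueError("spin-up block outside forcing years")
    state = state.copy()
    if years == 0:
        return state
    grid = forcing.grid
    lat, _ = grid.cell_latlon()
    i0 = (block[0] - forcing.year_start) * 12
    block_years = block[1] - block[0] + 1
    heat_index = sp.thornthwaite_heat_index(
        _climatology(forcing, block[0], block[1])["tair"].T)
    table = table or cc.default_biome_table()
    for y in range(years):
        yb = i0 + (y % block_years) * 12
        for m in range(12):
            tair_m = forcing.tair[yb + m]
            w = _soil_month(state.soil, tair_m, forcing.precip[yb + m], lat,
                            m + 1, heat_index, props, alpha)
            _cohort_month(state, tair_m, co2_1900, forcing.cloud[yb + m], w,
                          table)
    return state


def run_transient(state: CellState, forcing: ClimateForcing, co2: CO2Series,
                  land: LandCoverGrid, spec: ExperimentSpec = EXPERIMENTS["S1"],
                  props: SoilProperties | None = None,
                  table: cc.BiomeTable | None = None,
                  burn_fraction: float = 0.5,
                  alpha: float = sp.DEFAULT_ALPHA,
                  metadata: dict | None = None) -> FluxArchive:
    """Run 1900-2000 (the forcing's span) under an ExperimentSpec.

    Drivers are resolved per the spec: fixed-1900 CO2 replays the first
    year's value; the fixed-climatology mode replays the 1900-1919 mean
    monthly cycle; fixed-1900 land use freezes the first year's cover.
    Land transitions apply each January before fluxes, with the
    conversion release spread over the year's 12 months.
    """
    if props is None:
        raise ValueError("soil properties are required")
    table = table or cc.default_biome_table()
    grid = forcing.grid
    lat, _ = grid.cell_latlon()
    n_years = forcing.n_years
    n_cells = grid.n_cells
    n_types = len(COVER_TYPES)
    if land.frac.shape[0] < n_years:
        raise ValueError("land-cover record shorter than the forcing")

    # resolve drivers per experiment spec
    if spec.climate_mode == "fixed_1900_1919_climatology":
        if forcing.year_start > 1900 or forcing.year_end < 1919:
            raise ValueError("fixed-climatology mode needs 1900-1919 climate")
        clim = _climatology(forcing, 1900, 1919)
        tair = np.tile(clim["tair"], (n_years, 1))
        precip = np.tile(clim["precip"], (n_years, 1))
        cloud = np.tile(clim["cloud"], (n_years, 1))
    else:
        tair, precip, cloud = forcing.tair, forcing.precip, forcing.cloud
    if spec.co2_mode == "fixed_1900":
        co2_by_year = np.full(n_years, co2.at(forcing.year_start))
    else:
        co2_by_year = np.array([co2.at(y) for y in forcing.years])
    if spec.luc_mode == "fixed_1900":
        frac = np.repeat(land.frac[:1], n_years, axis=0)
    else:
        frac = land.frac[:n_years].copy()

    heat_index = sp.thornthwaite_heat_index(
        tair.reshape(n_years, 12, n_cells).mean(axis=0).T)

    state = state.copy()
    monthly = {k: np.zeros((n_years * 12, n_cells)) for k in MONTHLY_FIELDS}
    annual_by_type = {k: np.zeros((n_years, n_cells, n_types))
                      for k in ("gpp", "npp", "rh", "nep")}
    c_veg_init = (frac[0] * state.c_veg).sum(axis=1)
    c_soil_init = (frac[0] * state.c_soil).sum(axis=1)

    for iy in range(n_years):
        conv_month = np.zeros(n_cells)
        if iy > 0:
            prev, cur = frac[iy - 1], frac[iy]
            if not np.array_equal(prev, cur):
                nv, ns, flux = lu.apply_transition(state.c_veg, state.c_soil,
                                                   prev, cur, burn_fraction)
                state.c_veg, state.c_soil = nv, ns
                conv_month = flux.released / 12.0
        f_now = frac[iy]
        for m in range(12):
            t_idx = iy * 12 + m
            tair_m = tair[t_idx]
            w = _soil_month(state.soil, tair_m, precip[t_idx], lat, m + 1,
                            heat_index, props, alpha)
            fx = _cohort_month(state, tair_m, co2_by_year[iy], cloud[t_idx],
                               w, table)
            for k in ("gpp", "ra", "npp", "rh", "nep"):
                monthly[k][t_idx] = (f_now * fx[k]).sum(axis=1)
            for k in annual_by_type:
                annual_by_type[k][iy] += fx[k]
            monthly["conversion_flux"][t_idx] = conv_month
            monthly["t_soil20"][t_idx] = state.soil.t_soil20
            monthly["wfps"][t_idx] = w
            monthly["c_veg"][t_idx] = (f_now * state.c_veg).sum(axis=1)
            monthly["c_soil"][t_idx] = (f_now * state.c_soil).sum(axis=1)

    meta = dict(metadata or {})
    meta.update({"co2_mode": spec.co2_mode, "climate_mode": spec.climate_mode,
                 "luc_mode": spec.luc_mode})
    return FluxArchive(grid=grid, year_start=forcing.year_start,
                       year_end=forcing.year_end, monthly=monthly,
                       annual_by_type=annual_by_type, frac=frac,
                       land_fraction=land.cell_land_fraction.copy(),
                       c_veg_init=c_veg_init, c_soil_init=c_soil_init,
                       metadata=meta)


def run_factorial(state: CellState, forcing: ClimateForcing, co2: CO2Series,
                  land: LandCoverGrid, props: SoilProperties,
                  table: cc.BiomeTable | None = None,
                  experiments: dict[str, ExperimentSpec] | None = None,
                  **kw) -> dict[str, FluxArchive]:
    """Run S1-S4 from one shared spun-up state; returns name -> archive."""
    experiments = experiments or EXPERIMENTS
    return {name: run_transient(state.copy(), forcing, co2, land, spec,
                                props=props, table=table,
                                metadata={"experiment": name}, **kw)
            for name, spec in experiments.items()}


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

def attribution_effects(archives: dict[str, FluxArchive],
                        areas: np.ndarray) -> AttributionResult:
    """Decadal national carbon-balance attribution from the four
    factorial archives.

    The attributed series is the net carbon exchange
    NEP - conversion release (identical to NEP in any run without land
    transitions): conversion emissions are the dominant carbon
    consequence of cropland expansion and belong to the land-use factor.
    Effects are differences of decadal national means (Tg C yr-1):
    CO2 = S1-S2, climate = S1-S3, land use = S1-S4; the interaction
    residual is the part of S1's change since the 1900s the three
    single-factor effects do not explain.
    """
    from .aggregation_stats import decadal_means

    for need in ("S1", "S2", "S3", "S4"):
        if need not in archives:
            raise KeyError(f"missing archive {need}")

    def national_nep(arch: FluxArchive) -> np.ndarray:
        w = areas * arch.land_fraction * 1e-12  # g m-2 -> Tg
        nce = arch.annual("nep") - arch.annual("conversion_flux")
        return nce @ w

    dec = {k: decadal_means(national_nep(a)) for k, a in archives.items()}
    eff_co2 = dec["S1"] - dec["S2"]
    eff_cli = dec["S1"] - dec["S3"]
    eff_luc = dec["S1"] - dec["S4"]
    base = dec["S1"][0]
    resid = (dec["S1"] - base) - ((eff_co2 - eff_co2[0])
                                  + (eff_cli - eff_cli[0])
                                  + (eff_luc - eff_luc[0]))
    decades = np.arange(1900, 2000, 10)
    return AttributionResult(decades=decades, nep_s1=dec["S1"],
                             effect_co2=eff_co2, effect_climate=eff_cli,
                             effect_luc=eff_luc, interaction_residual=resid)
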