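"""File formats, run manifests, and the end-to-end pipeline.

Gridded output goes to NetCDF (dimensions time, lat, lon; CF-like units
attributes; written through xarray's scipy backend), summaries to plain
CSV (comma, '.' decimal, header, UTF-8).  Coordinates are cell-center
degrees with latitude ascending; time is months since 1900-01 on a
365-day no-leap calendar.  Every file carries the JSON manifest of the
run that produced it, so any output is reproducible from its own
metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import aggregation_stats as agg
from . import protocol as proto
from . import synthetic_forcing as sf
from .carbon_core import default_biome_table, load_biome_table

__all__ = [
    "RunManifest",
    "write_archive",
    "read_archive",
    "write_forcing",
    "read_forcing",
    "write_land_cover_csv",
    "read_land_cover_csv",
    "write_summary_csv",
    "run_pipeline",
]

log = logging.getLogger("temcn")

_UNITS = {
    "gpp": "g C m-2 month-1", "ra": "g C m-2 month-1",
    "npp": "g C m-2 month-1", "rh": "g C m-2 month-1",
    "nep": "g C m-2 month-1", "conversion_flux": "g C m-2 month-1",
    "t_soil20": "degC", "wfps": "percent",
    "c_veg": "g C m-2", "c_soil": "g C m-2",
    "tair": "degC", "precip": "mm month-1", "cloud": "fraction",
}


@dataclass
class RunManifest:
    """Provenance of one run: enough to reproduce every output bit."""

    seed: int
    grid: dict
    scenario: str = "default"
    landuse_scenario: str = "default"
    software_version: str = "temcn 0.1.0"
    config_hash: str = ""
    convergence: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunManifest":
        return cls(**json.loads(s))


def _grid_to_dict(grid: sf.GridSpec) -> dict:
    return {"lat_min": grid.lat_min, "lat_max": grid.lat_max,
            "lon_min": grid.lon_min, "lon_max": grid.lon_max,
            "resolution": grid.resolution}


def _grid_from_attrs(attrs) -> sf.GridSpec:
    g = json.loads(attrs["grid"])
    return sf.GridSpec(**g)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Archives
# ---------------------------------------------------------------------------

def _to_3d(grid: sf.GridSpec, a: np.ndarray) -> np.ndarray:
    return a.reshape(a.shape[0], grid.n_lat, grid.n_lon)


def write_archive(archive: proto.FluxArchive, path,
                  manifest: RunManifest | None = None) -> None:
    """Write a flux archive to NetCDF; refuses incomplete archives."""
    grid = archive.grid
    missing = [v for v in proto.MONTHLY_FIELDS if v not in archive.monthly]
    if missing:
        raise ValueError(f"archive is missing variables: {missing}")
    n = archive.n_years * 12
    coords = {
        "time": ("time", np.arange(n), {"units": "months since 1900-01",
                                        "calendar": "noleap"}),
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
    }
    data = {}
    for name in proto.MONTHLY_FIELDS:
        data[name] = (("time", "lat", "lon"),
                      _to_3d(grid, archive.monthly[name]),
                      {"units": _UNITS[name]})
    ds = xr.Dataset(data, coords={k: xr.Variable(v[0], v[1], v[2])
                                  for k, v in coords.items()})
    ds.attrs["grid"] = json.dumps(_grid_to_dict(grid))
    ds.attrs["year_start"] = archive.year_start
    ds.attrs["year_end"] = archive.year_end
    ds.attrs["metadata"] = json.dumps(archive.metadata)
    if manifest is not None:
        ds.attrs["manifest"] = manifest.to_json()
    ds.to_netcdf(path, engine="scipy")


def read_archive(path) -> xr.Dataset:
    """Open an archive as an xarray Dataset (lazy helper; the rich
    FluxArchive object only exists in-process).  The time axis is a plain
    month index, not a CF datetime, so decoding is disabled."""
    return xr.open_dataset(path, engine="scipy", decode_times=False)


# ---------------------------------------------------------------------------
# Forcing
# ---------------------------------------------------------------------------

def write_forcing(forcing: sf.ClimateForcing, path,
                  manifest: RunManifest | None = None) -> None:
    grid = forcing.grid
    n = forcing.n_years * 12
    ds = xr.Dataset(
        {name: (("time", "lat", "lon"),
                _to_3d(grid, getattr(forcing, name)),
                {"units": _UNITS[name]})
         for name in ("tair", "precip", "cloud")},
        coords={"time": ("time", np.arange(n)),
                "lat": ("lat", grid.lat_centers),
                "lon": ("lon", grid.lon_centers)},
    )
    ds["time"].attrs.update(units="months since 1900-01", calendar="noleap")
    ds.attrs["grid"] = json.dumps(_grid_to_dict(grid))
    ds.attrs["year_start"] = forcing.year_start
    ds.attrs["year_end"] = forcing.year_end
    if manifest is not None:
        ds.attrs["manifest"] = manifest.to_json()
    ds.to_netcdf(path, engine="scipy")


def read_forcing(path) -> sf.ClimateForcing:
    """Load and validate a forcing file; every out-of-range value is a
    named, located error rather than a silent load."""
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds.load()
    for name in ("tair", "precip", "cloud"):
        if name not in ds:
            raise ValueError(f"forcing file lacks variable {name!r}")
    grid = _grid_from_attrs(ds.attrs)
    year_start = int(ds.attrs["year_start"])
    year_end = int(ds.attrs["year_end"])
    n_months = ds.sizes["time"]
    if n_months != 12 * (year_end - year_start + 1):
        raise ValueError(
            f"time axis has {n_months} months; {year_end - year_start + 1} "
            "years require a multiple of 12 (calendar gap?)")
    flat = {name: ds[name].values.reshape(n_months, -1)
            for name in ("tair", "precip", "cloud")}
    bad = np.argwhere(flat["precip"] < 0)
    if bad.size:
        t, c = bad[0]
        raise ValueError(f"negative precipitation at month {t}, cell {c}")
    bad = np.argwhere((flat["cloud"] < 0) | (flat["cloud"] > 1))
    if bad.size:
        t, c = bad[0]
        raise ValueError(f"cloud fraction out of [0,1] at month {t}, cell {c}")
    forcing = sf.ClimateForcing(grid, year_start, year_end,
                                flat["tair"], flat["precip"], flat["cloud"])
    forcing.validate()
    return forcing


# ---------------------------------------------------------------------------
# Land cover CSV
# ---------------------------------------------------------------------------

def write_land_cover_csv(land: sf.LandCoverGrid, path) -> None:
    """Long-format CSV: cell_id, year, type, frac."""
    n_years, n_cells, n_types = land.frac.shape
    years = np.repeat(np.arange(land.year_start, land.year_start + n_years),
                      n_cells * n_types)
    cells = np.tile(np.repeat(np.arange(n_cells), n_types), n_years)
    types = np.tile(list(sf.COVER_TYPES), n_years * n_cells)
    pd.DataFrame({"cell_id": cells, "year": years, "type": types,
                  "frac": land.frac.ravel()}).to_csv(path, index=False)


def read_land_cover_csv(path, grid: sf.GridSpec, year_start: int = 1900) -> sf.LandCoverGrid:
    df = pd.read_csv(path)
    years = np.sort(df["year"].unique())
    n_years = len(years)
    frac = np.zeros((n_years, grid.n_cells, len(sf.COVER_TYPES)))
    tmap = {t: j for j, t in enumerate(sf.COVER_TYPES)}
    frac[df["year"] - years[0], df["cell_id"],
         df["type"].map(tmap)] = df["frac"]
    lc = sf.LandCoverGrid(grid, int(years[0]), frac, np.ones(grid.n_cells))
    lc.validate()
    return lc


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def write_summary_csv(summary: agg.RegionalSummary, path) -> None:
    cols = {"year": summary.years,
            "national_nep_Tg": summary.national_nep,
            "national_npp_Tg": summary.national_npp,
            "national_rh_Tg": summary.national_rh,
            "national_gpp_Tg": summary.national_gpp,
            "soil_pool_Pg": summary.soil_pool,
            "veg_pool_Pg": summary.veg_pool}
    for cover in sf.COVER_TYPES:
        cols[f"nep_{cover}_Tg"] = summary.biome_nep[cover]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "grid": {"resolution": 2.0},
    "climate_scenario": "default",
    "landuse_scenario": "default",
    "co2": {"start_ppm": 296.0, "end_ppm": 369.0, "shape": "exponential"},
    "experiments": ["S1", "S2", "S3", "S4"],
    "equilibrium": {"tol": 0.1, "max_iter": 3000},
    "spinup_years": 150,
    "burn_fraction": 0.5,
    "biome_params": None,   # path to a YAML override table
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in user.items():
        if k not in cfg:
            raise KeyError(f"unknown configuration key {k!r}")
        if isinstance(cfg[k], dict) and isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config: dict | None = None, out_dir=None,
                 write_outputs: bool = True):
    """End-to-end: generate inputs -> equilibrium -> spin-up -> factorial
    transients -> attribution -> summaries, all from one seed.

    Returns a dict with forcing, archives, attribution, summaries and the
    manifest; optionally writes NetCDF archives and summary CSVs.
    """
    cfg = json.loads(json.dumps(config if config is not None else DEFAULT_CONFIG))
    base = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in cfg.items():
        if isinstance(base.get(k), dict) and isinstance(v, dict):
            base[k].update(v)
        else:
            base[k] = v
    cfg = base
    seed = int(cfg["seed"])
    grid = sf.china_grid(cfg["grid"].get("resolution", 2.0))
    if "lat_min" in cfg["grid"]:
        grid = sf.GridSpec(**cfg["grid"])
    manifest = RunManifest(seed=seed, grid=_grid_to_dict(grid),
                           scenario=str(cfg["climate_scenario"]),
                           landuse_scenario=str(cfg["landuse_scenario"]),
                           config_hash=config_hash(cfg))

    log.info("generating forcing (seed=%d)", seed)
    forcing = sf.generate_climate(grid, cfg["climate_scenario"], seed)
    co2 = sf.generate_co2_series(**cfg["co2"])
    areas = agg.grid_cell_areas(grid)
    land = sf.generate_land_cover(grid, cfg["landuse_scenario"], seed, areas)
    props = sf.generate_soil(grid, seed)
    table = (load_biome_table(cfg["biome_params"]) if cfg["biome_params"]
             else default_biome_table())

    unknown = [e for e in cfg["experiments"] if e not in proto.EXPERIMENTS]
    if unknown:
        raise KeyError(f"unknown experiments {unknown}")
    needs_s3 = "S3" in cfg["experiments"]
    if needs_s3 and (forcing.year_start > 1900 or forcing.year_end < 1919):
        raise ValueError("experiment S3 requires climate data for 1900-1919")

    log.info("equilibrium stage")
    clim = proto._climatology(forcing, forcing.year_start, forcing.year_end)
    co2_ref = float(np.mean(co2.ppm))
    eq = proto.run_equilibrium(clim, co2_ref, props, grid, table,
                               tol=cfg["equilibrium"]["tol"],
                               max_iter=cfg["equilibrium"]["max_iter"])
    manifest.convergence = dict(eq.metadata)
    if eq.metadata.get("n_unconverged"):
        log.warning("equilibrium left %d cohorts unconverged",
                    eq.metadata["n_unconverged"])

    log.info("spin-up stage (%d years)", cfg["spinup_years"])
    block_end = min(1949, forcing.year_end)
    spun = proto.run_spinup(eq, forcing, co2.at(forcing.year_start), props,
                            table, years=cfg["spinup_years"],
                            block=(forcing.year_start, block_end))

    log.info("transient factorial: %s", ",".join(cfg["experiments"]))
    experiments = {e: proto.EXPERIMENTS[e] for e in cfg["experiments"]}
    archives = proto.run_factorial(spun, forcing, co2, land, props, table,
                                   experiments=experiments,
                                   burn_fraction=cfg["burn_fraction"])
    attribution = None
    if all(e in archives for e in ("S1", "S2", "S3", "S4")):
        attribution = proto.attribution_effects(archives, areas)

    summaries = {name: agg.aggregate_region(arch, areas=areas)
                 for name, arch in archives.items()}

    if write_outputs:
        if out_dir is None:
            raise ValueError("out_dir required when write_outputs=True")
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(manifest.to_json())
        write_forcing(forcing, out / "forcing.nc", manifest)
        write_land_cover_csv(land, out / "land_cover.csv")
        for name, arch in archives.items():
            write_archive(arch, out / f"{name.lower()}.nc", manifest)
            write_summary_csv(summaries[name], out / f"summary_{name.lower()}.csv")
        if attribution is not None:
            pd.DataFrame({
                "decade": attribution.decades,
                "nep_s1_Tg": attribution.nep_s1,
                "effect_co2_Tg": attribution.effect_co2,
                "effect_climate_Tg": attribution.effect_climate,
                "effect_luc_Tg": attribution.effect_luc,
                "interaction_residual_Tg": attribution.interaction_residual,
            }).to_csv(out / "attribution.csv", index=False, float_format="%.6f")

    return {"forcing": forcing, "co2": co2, "land": land, "soil": props,
            "equilibrium": eq, "spun": spun, "archives": archives,
            "attribution": attribution, "summaries": summaries,
            "manifest": manifest, "grid": grid, "areas": areas}
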