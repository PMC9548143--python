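"""Diagnostics over flux archives: national and biome bookkeeping in Tg C,
decadal means, OLS trends, latitude/longitude strip anomalies, the Hu
Huanyong line partition, carbon-source year counting, and Spearman /
partial rank correlations between fluxes and their drivers.

Aggregation is area-true on the sphere (zonal-band formula, no
equal-area reprojection); fluxes in g C m-2 yr-1 scale to Tg C yr-1 by
cell area times land fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_forcing import COVER_TYPES, GridSpec

__all__ = [
    "EARTH_RADIUS_M",
    "RegionalSummary",
    "cell_area",
    "grid_cell_areas",
    "aggregate_region",
    "decadal_means",
    "linear_trend",
    "strip_anomalies",
    "hu_line_side",
    "count_source_years",
    "spearman",
    "partial_correlation",
    "correlation_table",
]

EARTH_RADIUS_M = 6_371_000.0

#: Endpoints of the Hu Huanyong line, (lon E, lat N).
HU_HEIHE = (127.5, 50.25)
HU_TENGCHONG = (98.5, 25.0)


# ---------------------------------------------------------------------------
# Areas and aggregation
# ---------------------------------------------------------------------------

def cell_area(lat_south, lat_north, lon_west, lon_east) -> np.ndarray:
    """Spherical-zone area of a lat/lon box, m^2:
    R^2 * (lam_e - lam_w) * (sin(phi_n) - sin(phi_s))."""
    lat_south = np.asarray(lat_south, dtype=float)
    lat_north = np.asarray(lat_north, dtype=float)
    lon_west = np.asarray(lon_west, dtype=float)
    lon_east = np.asarray(lon_east, dtype=float)
    if np.any(lat_south >= lat_north) or np.any(lon_west >= lon_east):
        raise ValueError("inverted cell bounds")
    return (EARTH_RADIUS_M ** 2
            * np.deg2rad(lon_east - lon_west)
            * (np.sin(np.deg2rad(lat_north)) - np.sin(np.deg2rad(lat_south))))


def grid_cell_areas(grid: GridSpec) -> np.ndarray:
    """(n_cells,) areas of all grid cells, lat-major flattening."""
    lat, _ = grid.cell_latlon()
    half = 0.5 * grid.resolution
    lon0 = np.zeros_like(lat)
    return cell_area(lat - half, lat + half, lon0, lon0 + grid.resolution)


@dataclass
class RegionalSummary:
    """Annual regional totals and biome breakdown of one archive."""

    years: np.ndarray
    national_nep: np.ndarray      # Tg C yr-1
    national_npp: np.ndarray
    national_rh: np.ndarray
    national_gpp: np.ndarray
    soil_pool: np.ndarray         # Pg C (annual mean)
    veg_pool: np.ndarray          # Pg C
    biome_nep: dict[str, np.ndarray]       # Tg C yr-1 per cover type
    biome_nep_per_area: dict[str, np.ndarray]  # g C m-2 yr-1
    biome_area: dict[str, np.ndarray]      # m^2 per year


def aggregate_region(archive, land_fraction: np.ndarray | None = None,
                     mask: np.ndarray | None = None,
                     areas: np.ndarray | None = None) -> RegionalSummary:
    """Aggregate a flux archive over a cell mask.

    Totals are sum over cells of flux * area * land_fraction * 1e-12 Tg;
    biome totals weight each cohort by its cover fraction; per-area biome
    means divide the biome total by the biome's area.
    """
    grid = archive.grid
    if areas is None:
        areas = grid_cell_areas(grid)
    if land_fraction is None:
        land_fraction = archive.land_fraction
    if mask is None:
        mask = np.ones(grid.n_cells, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")

    w = (areas * land_fraction * mask) * 1e-12    # g m-2 -> Tg
    out = {}
    for name in ("nep", "npp", "rh", "gpp"):
        out[name] = archive.annual(name) @ w
    soil_pool = archive.annual("c_soil") @ w * 1e-3   # Tg -> Pg
    veg_pool = archive.annual("c_veg") @ w * 1e-3

    biome_nep, biome_per_area, biome_area = {}, {}, {}
    nep_t = archive.annual_by_type["nep"]             # (years, cells, types)
    for j, cover in enumerate(COVER_TYPES):
        aw = archive.frac[:, :, j] * (areas * land_fraction * mask)[None, :]
        tot = (nep_t[:, :, j] * aw).sum(axis=1)
        area_j = aw.sum(axis=1)
        biome_nep[cover] = tot * 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            biome_per_area[cover] = np.where(area_j > 0, tot / np.maximum(area_j, 1), 0.0)
        biome_area[cover] = area_j
    return RegionalSummary(years=archive.years, national_nep=out["nep"],
                           national_npp=out["npp"], national_rh=out["rh"],
                           national_gpp=out["gpp"], soil_pool=soil_pool,
                           veg_pool=veg_pool, biome_nep=biome_nep,
                           biome_nep_per_area=biome_per_area,
                           biome_area=biome_area)


# ---------------------------------------------------------------------------
# Time-series diagnostics
# ---------------------------------------------------------------------------

def decadal_means(series: np.ndarray) -> np.ndarray:
    """Means over the ten clean decades 1900-1909 ... 1990-1999 of a
    101-value annual series (year 2000 is left out of the bins)."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] != 101:
        raise ValueError("expected 101 annual values (1900-2000)")
    return series[:100].reshape(10, 10).mean(axis=1)


def linear_trend(series: np.ndarray, years: np.ndarray | None = None,
                 window: tuple[int, int] | None = None):
    """OLS trend of an annual series, reported per decade.

    Returns (slope_per_decade, r_squared, p_value).  ``window`` selects an
    inclusive year range of ``years`` (default: the whole series).
    """
    series = np.asarray(series, dtype=float)
    if years is None:
        years = np.arange(len(series))
    years = np.asarray(years, dtype=float)
    if window is not None:
        sel = (years >= window[0]) & (years <= window[1])
        series, years = series[sel], years[sel]
    if len(series) < 3:
        raise ValueError("need at least 3 points for a trend")
    if np.ptp(years) == 0:
        raise ValueError("degenerate (constant) year axis")
    if np.ptp(series) == 0:
        return 0.0, 0.0, 1.0
    res = stats.linregress(years, series)
    return res.slope * 10.0, res.rvalue ** 2, res.pvalue


def count_source_years(national_nep: np.ndarray) -> int:
    """Number of years the region was a net carbon source (NEP strictly
    negative; zero counts as neutral)."""
    return int(np.sum(np.asarray(national_nep) < 0.0))


def strip_anomalies(field: np.ndarray, grid: GridSpec, axis: str,
                    years: np.ndarray, baseline: tuple[int, int],
                    areas: np.ndarray | None = None) -> np.ndarray:
    """Strip-by-year anomaly matrix of an annual per-cell field.

    A strip is all cells sharing one latitude (axis='latitude') or
    longitude (axis='longitude') index; each strip's area-weighted annual
    mean has that strip's baseline-period mean removed.  Returns
    (n_strips, n_years).
    """
    field = np.asarray(field, dtype=float)      # (n_years, n_cells)
    if areas is None:
        areas = grid_cell_areas(grid)
    if axis == "latitude":
        idx = np.repeat(np.arange(grid.n_lat), grid.n_lon)
        n_strips = grid.n_lat
    elif axis == "longitude":
        idx = np.tile(np.arange(grid.n_lon), grid.n_lat)
        n_strips = grid.n_lon
    else:
        raise ValueError("axis must be 'latitude' or 'longitude'")
    years = np.asarray(years)
    bsel = (years >= baseline[0]) & (years <= baseline[1])
    if not bsel.any():
        raise ValueError("baseline outside the series")
    out = np.empty((n_strips, field.shape[0]))
    for s in range(n_strips):
        cells = idx == s
        if not cells.any():
            raise ValueError(f"empty strip {s}")
        w = areas[cells] / areas[cells].sum()
        series = field[:, cells] @ w
        out[s] = series - series[bsel].mean()
    return out


# ---------------------------------------------------------------------------
# Hu Huanyong line
# ---------------------------------------------------------------------------

def hu_line_side(lat, lon) -> np.ndarray:
    """'southeast' or 'northwest' of the Heihe-Tengchong line, by the sign
    of the cross product in (lon, lat) space; points on the line count as
    southeast."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    ax, ay = HU_HEIHE
    bx, by = HU_TENGCHONG
    cross = (bx - ax) * (lat - ay) - (by - ay) * (lon - ax)
    # the line runs NE->SW; its left side (cross >= 0) is the southeast
    return np.where(cross >= 0, "southeast", "northwest")


# ---------------------------------------------------------------------------
# Correlation statistics
# ---------------------------------------------------------------------------

def spearman(x, y):
    """Spearman rank correlation with average ranks for ties; p-value from
    the t approximation with n-2 degrees of freedom.

    Raises on zero-variance input (rho is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) >= 1.0:
        return rho_c, 0.0
    t = rho_c * np.sqrt((n - 2) / (1.0 - rho_c ** 2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho_c, float(p)


def partial_correlation(x, y, controls=()):
    """Partial Spearman correlation of x and y given control variables.

    All variables are rank-transformed; x and y ranks are each regressed
    on the control ranks (OLS with intercept) and the correlation of the
    residuals is returned with a t-test p-value on n - 2 - k degrees of
    freedom.  With no controls this reduces exactly to
    :func:`spearman`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    controls = [np.asarray(c, dtype=float) for c in controls]
    n = len(x)
    k = len(controls)
    if n <= k + 2:
        raise ValueError("need n > number_of_controls + 2")
    if not controls:
        return spearman(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack([np.ones(n)] + [stats.rankdata(c) for c in controls])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear control variables")
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    sx, sy = res_x.std(), res_y.std()
    if sx == 0 or sy == 0:
        raise ValueError("residual variance is zero")
    rho = float(np.dot(res_x, res_y) / (n * sx * sy))
    rho = min(max(rho, -1.0), 1.0)
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


def correlation_table(drivers: dict[str, np.ndarray],
                      fluxes: dict[str, np.ndarray],
                      method: str = "spearman") -> dict[tuple[str, str], tuple[float, float]]:
    """Driver x flux correlation table (rho, p) over matching vectors.

    Used both spatially (century means across cells) and temporally
    (annual series within one cell); the caller chooses which vectors to
    pass.  ``method='partial'`` computes each driver's correlation
    controlling for the remaining drivers.
    """
    out = {}
    names = list(drivers)
    for dname in names:
        for fname, f in fluxes.items():
            if method == "spearman":
                out[(dname, fname)] = spearman(drivers[dname], f)
            elif method == "partial":
                others = [drivers[o] for o in names if o != dname]
                out[(dname, fname)] = partial_correlation(drivers[dname], f, others)
            else:
                raise ValueError(f"unknown method {method!r}")
    return out
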