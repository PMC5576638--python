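"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything the analysis consumes can be generated here: a calibration
curve with a pre-bomb plateau and an asymmetric bomb spike (fast rise,
exponential decay — so one Fm value maps to a rising-limb and a
falling-limb calendar year), daily weather with seasonal cycle + linear
trend + missing days, a lapse-rate temperature raster, talus polygons, and
sites whose occupancy is drawn from a logistic model with known
coefficients.  All randomness flows through one seeded
``numpy.random.Generator`` so identical seeds give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import Point, box, mapping

from .calibration import POST_BOMB, PRE_BOMB, CalibrationCurve
from .grids import ClimateGrid
from .occupancy import refugial_mst

__all__ = [
    "CurveSpec",
    "GridSpec",
    "OccupancySpec",
    "SyntheticScenario",
    "make_calibration_curve",
    "make_daily_weather",
    "make_temperature_grid",
    "make_sites_with_occupancy",
    "write_talus_geojson",
]


@dataclass(frozen=True)
class CurveSpec:
    """Pre-bomb plateau plus an asymmetric post-bomb pulse."""

    plateau_fm: float = 0.98
    spike_year: float = 1955.0
    amplitude: float = 0.8
    rise_years: float = 9.0
    decay_years: float = 16.0
    year_start: float = 1700.0
    year_end: float = 2010.0
    sigma: float = 0.003
    wiggle_amplitude: float = 0.0  # optional slow pre-bomb variation
    tabulation_step: float = 1.0


@dataclass(frozen=True)
class GridSpec:
    nrows: int = 60
    ncols: int = 60
    cell_size: float = 270.0
    base_temp: float = 18.0
    lapse_rate: float = 6.5e-3  # °C per m of elevation
    relief_m: float = 1200.0  # peak synthetic elevation above base
    n_bumps: int = 6
    bump_width_frac: tuple[float, float] = (0.1, 0.3)  # of max grid dimension
    noise_sd: float = 0.0
    x_origin: float = 0.0
    y_origin: float = 0.0  # 0 → derived from nrows so yllcorner = 0


@dataclass(frozen=True)
class OccupancySpec:
    n_sites: int = 200
    beta0: float = 20.0
    beta1: float = -1.4  # slope on refugial MST → 0.5 threshold at ≈14.3 °C
    true_radius_km: float = 4.0
    talus_mean_log_area: float = 9.0
    talus_sd_log_area: float = 1.0
    margin_km: float | None = None  # keep sites this far from grid edge
    #: when True, the intercept actually used is β0 − β1·median(MST_min), so
    #: β0 becomes the log-odds of occupancy at the median site and classes
    #: stay balanced whatever the grid's absolute temperature level
    auto_center_beta0: bool = False


@dataclass(frozen=True)
class SyntheticScenario:
    """One bundle of generation parameters for the full pipeline."""

    seed: int = 0
    year_start: int = 1910
    year_end: int = 2015
    warming_rate: float = 1.9  # °C per century
    mean_temp: float = 6.0
    seasonal_amplitude: float = 10.0
    diurnal_range: float = 10.0
    noise_sd: float = 0.0
    missing_day_rate: float = 0.0
    #: station outages cluster in time: this fraction of years is "bad" and
    #: loses ``bad_year_missing`` of its days (on top of the background
    #: ``missing_day_rate``), which is what the <15/<10 missing-day QC rules
    #: are designed to catch.  0 → plain i.i.d. missingness.
    bad_year_rate: float = 0.0
    bad_year_missing: float = 0.5
    snow_winter_depth: float = 100.0  # cm, mid-winter peak
    snow_decline_rate: float = 0.0  # fraction of peak lost per century
    curve_spec: CurveSpec = field(default_factory=CurveSpec)
    grid_spec: GridSpec = field(default_factory=GridSpec)
    occupancy_spec: OccupancySpec = field(default_factory=OccupancySpec)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Calibration curve


def make_calibration_curve(spec: CurveSpec) -> CalibrationCurve:
    """Tabulate a plateau + bomb-pulse curve.

    Post-spike the pulse rises linearly over ``rise_years`` to
    ``amplitude`` above the plateau, then decays exponentially with
    e-folding time ``decay_years``, giving a single-valued curve whose
    non-monotone spike yields two-branch calibration solutions.
    """
    if not (spec.year_start < spec.spike_year < spec.year_end):
        raise ValueError(
            f"spike year {spec.spike_year} outside tabulated range "
            f"[{spec.year_start}, {spec.year_end}]"
        )
    years = np.arange(spec.year_start, spec.year_end + 0.5 * spec.tabulation_step, spec.tabulation_step)
    fm = np.full_like(years, float(spec.plateau_fm))
    if spec.wiggle_amplitude:
        fm = fm + spec.wiggle_amplitude * np.sin(2 * np.pi * (years - spec.year_start) / 200.0)
    t = years - spec.spike_year
    peak = spec.spike_year + spec.rise_years
    rising = (t > 0) & (years <= peak)
    falling = years > peak
    pulse = np.zeros_like(years)
    pulse[rising] = spec.amplitude * t[rising] / spec.rise_years
    pulse[falling] = spec.amplitude * np.exp(-(years[falling] - peak) / spec.decay_years)
    fm = fm + pulse
    labels = np.where(years < spec.spike_year, PRE_BOMB, POST_BOMB).astype(object)
    return CalibrationCurve(years, fm, np.full_like(years, spec.sigma), labels)


# ---------------------------------------------------------------------------
# Daily weather


def make_daily_weather(scenario: SyntheticScenario, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily tmax/tmin/snow series with trend, seasonality, noise, and gaps.

    The daily mean is ``mean_temp + warming_rate/100 × (years since start)
    + seasonal cosine + N(0, noise_sd)``; tmax/tmin sit half the diurnal
    range above/below it, so tmin ≤ tmax by construction.  A seeded
    Bernoulli fraction of days is blanked per temperature variable; snow
    depth is a nonnegative winter sinusoid with optional declining trend.
    """
    if scenario.year_end < scenario.year_start:
        raise ValueError("empty year range")
    if scenario.missing_day_rate < 0:
        raise ValueError(f"missing_day_rate must be ≥ 0, got {scenario.missing_day_rate}")
    rng = rng or scenario.rng()
    dates = pd.date_range(f"{scenario.year_start}-01-01", f"{scenario.year_end}-12-31", freq="D")
    frac_year = (dates.dayofyear - 1) / np.where(dates.is_leap_year, 366, 365)
    t_years = (dates - dates[0]).days / 365.25
    trend = scenario.warming_rate / 100.0 * t_years
    # coldest around Jan 15 (fraction ≈ 0.04)
    season = -scenario.seasonal_amplitude * np.cos(2 * np.pi * (frac_year - 0.04))
    noise = rng.normal(0.0, scenario.noise_sd, len(dates)) if scenario.noise_sd > 0 else 0.0
    daily_mean = scenario.mean_temp + trend + season + noise
    tmax = daily_mean + scenario.diurnal_range / 2.0
    tmin = daily_mean - scenario.diurnal_range / 2.0

    winter = np.maximum(-np.cos(2 * np.pi * (frac_year - 0.04)), 0.0)
    decline = np.maximum(1.0 - scenario.snow_decline_rate * t_years / 100.0, 0.0)
    snow = scenario.snow_winter_depth * winter * decline
    if scenario.noise_sd > 0:
        snow = np.maximum(snow + rng.normal(0.0, scenario.noise_sd * 5.0, len(dates)), 0.0)

    df = pd.DataFrame({"date": dates, "tmax": tmax, "tmin": tmin, "snow_depth": snow})
    if scenario.missing_day_rate > 0 or scenario.bad_year_rate > 0:
        years = np.arange(scenario.year_start, scenario.year_end + 1)
        bad = rng.random(len(years)) < scenario.bad_year_rate
        day_rate = np.where(bad[dates.year - scenario.year_start],
                            scenario.bad_year_missing, scenario.missing_day_rate)
        gaps = rng.random(len(dates)) < day_rate
        df.loc[gaps, ["tmax", "tmin"]] = np.nan
        snow_gaps = rng.random(len(dates)) < day_rate
        df.loc[snow_gaps, "snow_depth"] = np.nan
    return df


# ---------------------------------------------------------------------------
# Temperature raster


def _synthetic_elevation(spec: GridSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth random topography from a few seeded Gaussian bumps."""
    rows, cols = np.mgrid[0 : spec.nrows, 0 : spec.ncols]
    elev = np.zeros((spec.nrows, spec.ncols))
    if spec.relief_m <= 0 or spec.n_bumps == 0:
        return elev
    for _ in range(spec.n_bumps):
        r0 = rng.uniform(0, spec.nrows)
        c0 = rng.uniform(0, spec.ncols)
        width = rng.uniform(*spec.bump_width_frac) * max(spec.nrows, spec.ncols)
        height = rng.uniform(0.3, 1.0)
        elev += height * np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * width**2))
    elev *= spec.relief_m / elev.max()
    return elev


def make_temperature_grid(
    spec: GridSpec,
    rng: np.random.Generator | None = None,
    elevation: np.ndarray | None = None,
) -> tuple[ClimateGrid, np.ndarray]:
    """MST raster = base − lapse_rate × elevation (+ smooth noise).

    Returns the grid and the elevation surface used.  Pass ``elevation``
    explicitly (e.g. zeros) for deterministic layouts.
    """
    if spec.nrows <= 0 or spec.ncols <= 0:
        raise ValueError("grid extent must be positive")
    if spec.cell_size <= 0:
        raise ValueError("cell size must be positive")
    rng = rng or np.random.default_rng(0)
    if elevation is None:
        elevation = _synthetic_elevation(spec, rng)
    elevation = np.asarray(elevation, dtype=float)
    if elevation.shape != (spec.nrows, spec.ncols):
        raise ValueError("elevation shape does not match grid spec")
    values = spec.base_temp - spec.lapse_rate * elevation
    if spec.noise_sd > 0:
        rough = rng.normal(0.0, 1.0, values.shape)
        # crude smoothing keeps the noise field spatially coherent
        kernel = np.ones((3, 3)) / 9.0
        from scipy.signal import convolve2d

        rough = convolve2d(rough, kernel, mode="same", boundary="symm")
        values = values + spec.noise_sd * rough
    y_origin = spec.y_origin if spec.y_origin else spec.nrows * spec.cell_size
    grid = ClimateGrid(values, x_origin=spec.x_origin, y_origin=y_origin, cell_size=spec.cell_size)
    return grid, elevation


# ---------------------------------------------------------------------------
# Sites, talus, occupancy


def make_sites_with_occupancy(
    spec: OccupancySpec,
    grid: ClimateGrid,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list]:
    """Sites with occupancy drawn from logistic(β0 + β1·refugial MST).

    Refugial MST is evaluated on ``grid`` at the spec's true dispersal
    radius.  Returns the site table and a list of talus polygons (squares
    of known lognormal area centred on each site).
    """
    rng = rng or np.random.default_rng(0)
    xmin, ymin, xmax, ymax = grid.bounds
    margin = (spec.margin_km if spec.margin_km is not None else spec.true_radius_km) * 1000.0
    if xmax - xmin <= 2 * margin or ymax - ymin <= 2 * margin:
        margin = min(xmax - xmin, ymax - ymin) / 4.0
    xs = rng.uniform(xmin + margin, xmax - margin, spec.n_sites)
    ys = rng.uniform(ymin + margin, ymax - margin, spec.n_sites)

    mst = np.array([refugial_mst(grid, (x, y), spec.true_radius_km) for x, y in zip(xs, ys)])
    beta0 = spec.beta0
    if spec.auto_center_beta0:
        beta0 = spec.beta0 - spec.beta1 * float(np.median(mst))
    p = expit(beta0 + spec.beta1 * mst)
    occupied = rng.random(spec.n_sites) < p

    areas = np.exp(rng.normal(spec.talus_mean_log_area, spec.talus_sd_log_area, spec.n_sites))
    polygons = []
    for x, y, a in zip(xs, ys, areas):
        half = np.sqrt(a) / 2.0
        polygons.append(box(x - half, y - half, x + half, y + half))

    sites = pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(spec.n_sites)],
            "x": xs,
            "y": ys,
            "occupancy": np.where(occupied, "extant", "extirpated"),
            "true_p": p,
            "true_mst_min": mst,
            "talus_area_true": areas,
        }
    )
    sites.attrs["beta0_effective"] = float(beta0)
    sites.attrs["beta1"] = float(spec.beta1)
    return sites, polygons


def write_talus_geojson(polygons, path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"id": i}, "geometry": mapping(p)}
            for i, p in enumerate(polygons)
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_talus_geojson(path) -> list:
    from shapely.geometry import shape

    with open(path) as fh:
        fc = json.load(fh)
    return [shape(f["geometry"]) for f in fc["features"]]
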