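"""Bomb-spike radiocarbon calibration of Fraction-Modern measurements.

A measurement (Fm ± 1σ) is converted to a normalised probability density
over calendar years by evaluating, at each year of a tabulated calibration
curve, the Gaussian likelihood of the measured Fm given the curve's
expected Fm and the combined (analytical + curve) uncertainty.  Credible
ranges are highest-density regions, which may split into several intervals
where the curve is non-monotone (the post-bomb spike maps one Fm value to
a rising-limb and a falling-limb solution).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "RadiocarbonMeasurement",
    "CalendarAgeDensity",
    "OutOfCurveRangeWarning",
    "read_curve",
    "write_curve",
    "append_curves",
    "calibrate",
    "hpd_intervals",
]

#: Conventional radiocarbon ages use the Libby mean life (5568 / ln 2 years).
LIBBY_MEAN_LIFE = 8033.0

PRE_BOMB = "pre-bomb"
POST_BOMB = "post-bomb"


class OutOfCurveRangeWarning(UserWarning):
    """Measurement Fm is > 5σ from the curve everywhere on its support."""


@dataclass
class CalibrationCurve:
    """Tabulated mapping from calendar year AD to expected Fm with 1σ."""

    calendar_year: np.ndarray
    curve_fm: np.ndarray
    curve_sigma: np.ndarray
    segment_label: np.ndarray  # "pre-bomb" | "post-bomb" per row

    def __post_init__(self) -> None:
        self.calendar_year = np.asarray(self.calendar_year, dtype=float)
        self.curve_fm = np.asarray(self.curve_fm, dtype=float)
        self.curve_sigma = np.asarray(self.curve_sigma, dtype=float)
        self.segment_label = np.asarray(self.segment_label, dtype=object)
        n = len(self.calendar_year)
        if not (len(self.curve_fm) == len(self.curve_sigma) == len(self.segment_label) == n):
            raise ValueError("curve columns have unequal lengths")
        if n < 2:
            raise ValueError("curve needs at least two rows")
        if not np.all(np.diff(self.calendar_year) > 0):
            raise ValueError("calendar_year must be strictly increasing with no duplicates")
        if not np.all(self.curve_sigma > 0):
            raise ValueError("curve_sigma must be positive everywhere")

    def __len__(self) -> int:
        return len(self.calendar_year)

    @property
    def year_range(self) -> tuple[float, float]:
        return float(self.calendar_year[0]), float(self.calendar_year[-1])

    def interpolate(self, years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (curve_fm, curve_sigma) at ``years``."""
        fm = np.interp(years, self.calendar_year, self.curve_fm)
        sig = np.interp(years, self.calendar_year, self.curve_sigma)
        return fm, sig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "calendar_year": self.calendar_year,
                "curve_fm": self.curve_fm,
                "curve_sigma": self.curve_sigma,
                "segment_label": self.segment_label,
            }
        )


@dataclass(frozen=True)
class RadiocarbonMeasurement:
    sample_id: str
    fm: float
    fm_sigma: float
    site_id: str = ""
    composited: bool = False

    def __post_init__(self) -> None:
        if not self.fm > 0:
            raise ValueError(f"fm must be positive, got {self.fm}")
        if not self.fm_sigma > 0:
            raise ValueError(f"fm_sigma must be positive, got {self.fm_sigma}")


@dataclass
class CalendarAgeDensity:
    """Normalised posterior over a uniform calendar-year grid."""

    year_grid: np.ndarray
    density: np.ndarray  # probability mass per grid point; sums to 1
    ranges95: list[tuple[float, float, float]] = field(default_factory=list)
    out_of_range: bool = False
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.year_grid = np.asarray(self.year_grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.year_grid.shape != self.density.shape:
            raise ValueError("year_grid and density shapes differ")

    @property
    def step(self) -> float:
        return float(self.year_grid[1] - self.year_grid[0])

    def mode_year(self) -> float:
        return float(self.year_grid[int(np.argmax(self.density))])

    def total_range_width(self) -> float:
        return sum(hi - lo for lo, hi, _ in self.ranges95)


def _fm_columns(df: pd.DataFrame, unit_convention: str) -> tuple[np.ndarray, np.ndarray]:
    value = df["value"].to_numpy(dtype=float)
    sigma = df["sigma"].to_numpy(dtype=float)
    if unit_convention == "fm":
        return value, sigma
    if unit_convention == "c14_age":
        # Fm = exp(-age/8033); 1σ propagated by the delta method.
        fm = np.exp(-value / LIBBY_MEAN_LIFE)
        return fm, fm * sigma / LIBBY_MEAN_LIFE
    raise ValueError(f"unknown unit_convention {unit_convention!r}; expected 'fm' or 'c14_age'")


def read_curve(path, unit_convention: str = "fm", segment_label: str | None = None) -> CalibrationCurve:
    """Read a calibration-curve CSV.

    Expected columns: ``calendar_year, value, sigma`` and optionally
    ``segment_label``.  ``unit_convention`` declares whether ``value`` is
    Fraction Modern or a conventional ¹⁴C age (years BP), in which case it
    is converted via ``Fm = exp(-age / 8033)``.
    """
    df = pd.read_csv(path)
    required = {"calendar_year", "value", "sigma"}
    if not required.issubset(df.columns):
        raise ValueError(f"curve file must have columns {sorted(required)}, got {list(df.columns)}")
    df = df.sort_values("calendar_year", kind="stable").reset_index(drop=True)
    years = df["calendar_year"].to_numpy(dtype=float)
    if np.any(np.diff(years) <= 0):
        raise ValueError("curve has duplicate or non-monotone calendar years")
    fm, sigma = _fm_columns(df, unit_convention)
    if segment_label is not None:
        labels = np.full(len(df), segment_label, dtype=object)
    elif "segment_label" in df.columns:
        labels = df["segment_label"].to_numpy(dtype=object)
    else:
        labels = np.full(len(df), PRE_BOMB, dtype=object)
    return CalibrationCurve(years, fm, sigma, labels)


def write_curve(curve: CalibrationCurve, path) -> None:
    df = curve.to_frame().rename(columns={"curve_fm": "value", "curve_sigma": "sigma"})
    df.to_csv(path, index=False)


def append_curves(pre_bomb: CalibrationCurve, post_bomb: CalibrationCurve) -> CalibrationCurve:
    """Concatenate a pre-bomb curve with a post-bomb extension.

    Where the two tabulations overlap in calendar year the post-bomb
    segment takes precedence.
    """
    cutoff = post_bomb.calendar_year[0]
    keep = pre_bomb.calendar_year < cutoff
    if not keep.any():
        raise ValueError("post-bomb segment covers the entire pre-bomb curve")
    years = np.concatenate([pre_bomb.calendar_year[keep], post_bomb.calendar_year])
    fm = np.concatenate([pre_bomb.curve_fm[keep], post_bomb.curve_fm])
    sigma = np.concatenate([pre_bomb.curve_sigma[keep], post_bomb.curve_sigma])
    labels = np.concatenate([pre_bomb.segment_label[keep], post_bomb.segment_label])
    return CalibrationCurve(years, fm, sigma, labels)


def _year_grid(curve: CalibrationCurve, step: float) -> np.ndarray:
    lo, hi = curve.year_range
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def calibrate(
    measurement: RadiocarbonMeasurement,
    curve: CalibrationCurve,
    step: float = 0.5,
    mass: float = 0.95,
) -> CalendarAgeDensity:
    """Calibrate one Fm measurement against ``curve``.

    The unnormalised density at year t is
    ``Normal(fm | curve_fm(t), sqrt(fm_sigma² + curve_sigma(t)²))`` with the
    curve linearly interpolated onto a uniform year grid of spacing
    ``step``; it is normalised over the curve's calendar support (i.e.
    truncated at the curve ends).  If the measurement is more than 5σ from
    the curve everywhere an :class:`OutOfCurveRangeWarning` is issued and
    the result is flagged.
    """
    years = _year_grid(curve, step)

    # The likelihood can be much narrower (in years) than the output grid
    # where the curve is steep: its width is ~ total_sigma / |dFm/dt|.
    # Evaluate on an oversampled internal grid fine enough to resolve that
    # width, then aggregate mass into the output grid's bins.
    slopes = np.abs(np.diff(curve.curve_fm) / np.diff(curve.calendar_year))
    min_sig = float(np.hypot(measurement.fm_sigma, curve.curve_sigma.min()))
    max_slope = float(slopes.max())
    width = min_sig / max_slope if max_slope > 0 else np.inf
    oversample = int(np.clip(np.ceil(step / max(width / 4.0, 1e-6)), 1, 2000))
    fine = _year_grid(curve, step / oversample)
    mu, curve_sig = curve.interpolate(fine)
    total_sig = np.hypot(measurement.fm_sigma, curve_sig)
    z = (measurement.fm - mu) / total_sig
    out_of_range = bool(np.min(np.abs(z)) > 5.0)
    if out_of_range:
        warnings.warn(
            f"measurement {measurement.sample_id!r} (Fm={measurement.fm}) is >5σ from the "
            "calibration curve everywhere; density is near-zero and unreliable",
            OutOfCurveRangeWarning,
            stacklevel=2,
        )
    # log-space for numerical stability far into the tails
    loglik = -0.5 * z**2 - np.log(total_sig)
    loglik -= loglik.max()
    fine_dens = np.exp(loglik)
    # bin each fine point to the nearest output grid point
    # half-up (not banker's) rounding: boundary points must bin consistently
    idx = np.clip(np.floor((fine - years[0]) / step + 0.5).astype(int), 0, len(years) - 1)
    dens = np.bincount(idx, weights=fine_dens, minlength=len(years))
    dens /= dens.sum()
    result = CalendarAgeDensity(
        year_grid=years, density=dens, out_of_range=out_of_range, sample_id=measurement.sample_id
    )
    result.ranges95 = hpd_intervals(result, mass=mass)
    return result


def hpd_intervals(density: CalendarAgeDensity, mass: float = 0.95) -> list[tuple[float, float, float]]:
    """Highest-density region of a gridded density, as contiguous intervals.

    Grid points are accumulated in decreasing density order until the
    target ``mass`` is reached, then merged into runs of consecutive grid
    points.  Returns ``[(start_year, end_year, interval_mass), ...]``
    sorted by start year.
    """
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    d = density.density
    total = d.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("density is degenerate")
    order = np.argsort(d, kind="stable")[::-1]
    csum = np.cumsum(d[order]) / total
    k = int(np.searchsorted(csum, mass)) + 1
    k = min(k, len(d))
    selected = np.zeros(len(d), dtype=bool)
    selected[order[:k]] = True
    # tie handling: include any point with density equal to the cut-off
    cutoff = d[order[k - 1]]
    selected |= d >= cutoff

    intervals: list[tuple[float, float, float]] = []
    idx = np.flatnonzero(selected)
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        lo, hi = run[0], run[-1]
        intervals.append(
            (
                float(density.year_grid[lo]),
                float(density.year_grid[hi]),
                float(d[lo : hi + 1].sum() / total),
            )
        )
    return intervals


def calibrate_table(
    measurements: pd.DataFrame, curve: CalibrationCurve, step: float = 0.5, mass: float = 0.95
) -> list[CalendarAgeDensity]:
    """Calibrate a measurement table (columns sample_id, site_id, fm, fm_sigma)."""
    out = []
    for row in measurements.itertuples(index=False):
        m = RadiocarbonMeasurement(
            sample_id=str(row.sample_id),
            site_id=str(getattr(row, "site_id", "")),
            fm=float(row.fm),
            fm_sigma=float(row.fm_sigma),
            composited=bool(getattr(row, "composited", False)),
        )
        out.append(calibrate(m, curve, step=step, mass=mass))
    return out


def ranges_report(densities: list[CalendarAgeDensity], mass: float = 0.95) -> dict:
    return {
        d.sample_id: {
            "mode_year": d.mode_year(),
            "out_of_range": d.out_of_range,
            "ranges": [
                {"start_year": lo, "end_year": hi, "mass": m} for lo, hi, m in d.ranges95
            ],
            "target_mass": mass,
        }
        for d in densities
    }


def write_ranges_json(densities: list[CalendarAgeDensity], path, mass: float = 0.95) -> None:
    with open(path, "w") as fh:
        json.dump(ranges_report(densities, mass=mass), fh, indent=2)
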