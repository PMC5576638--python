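"""Refugial-temperature occupancy modelling and AICc model selection.

Site-level predictors are the minimum ("refugial") mean summer temperature
within 1–5 km of each site centroid and log talus area within 1 km.  Ten
candidate logistic models (each radius alone, and each radius plus talus
area) are ranked by small-sample AICc; the best single-covariate model
yields a 0.5-probability threshold, and observed extirpations are compared
to an external model's predictions with an exact binomial test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from shapely.geometry import Point
from shapely.ops import unary_union

from .grids import ClimateGrid

__all__ = [
    "OccupancyModel",
    "refugial_mst",
    "talus_area_within",
    "log_talus_area",
    "spatial_thin",
    "fit_logistic",
    "rank_models",
    "occupancy_threshold",
    "binomial_extirpation_test",
    "classification_rates",
    "build_site_predictors",
]

DEFAULT_RADII_KM = (1, 2, 3, 4, 5)
#: floor added before the log transform so zero talus area stays finite
TALUS_LOG_FLOOR_M2 = 1.0
SEPARATION_PROB_TOL = 1e-4


@dataclass
class OccupancyModel:
    name: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]  # "intercept" + one entry per predictor
    log_likelihood: float
    k: int
    n: int
    aicc: float
    separation: bool = False
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def delta_from(self) -> float:  # populated by rank_models
        return getattr(self, "_delta", float("nan"))


def aicc_from_llf(llf: float, k: int, n: int) -> float:
    """AICc = −2·logL + 2k + 2k(k+1)/(n−k−1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# Predictors


def refugial_mst(grid: ClimateGrid, site_xy: tuple[float, float], radius_km: float) -> float:
    """Minimum grid value among cells whose center lies within the radius.

    Distances are Euclidean in the projected plane, centre-to-centre from
    the site coordinate.
    """
    if radius_km <= 0:
        raise ValueError(f"radius must be positive, got {radius_km}")
    x0, y0 = site_xy
    if not grid.contains_point(x0, y0):
        raise ValueError(f"site {site_xy} lies outside the grid bounds {grid.bounds}")
    X, Y = grid.cell_centers()
    within = (X - x0) ** 2 + (Y - y0) ** 2 <= (radius_km * 1000.0) ** 2
    vals = grid.values[within]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no valid grid cells within {radius_km} km of site {site_xy}")
    return float(vals.min())


def talus_area_within(polygons, site_xy: tuple[float, float], radius_km: float = 1.0,
                      repair: bool = True) -> float:
    """Total talus area (m²) inside a disk of ``radius_km`` around the site."""
    disk = Point(*site_xy).buffer(radius_km * 1000.0, quad_segs=256)
    total = 0.0
    for poly in polygons:
        if not poly.is_valid:
            if not repair:
                raise ValueError("invalid talus geometry")
            poly = poly.buffer(0)
        total += poly.intersection(disk).area
    return float(total)


def log_talus_area(area_m2: float, floor_m2: float = TALUS_LOG_FLOOR_M2) -> float:
    return float(np.log(area_m2 + floor_m2))


def spatial_thin(sites: pd.DataFrame, min_dist_m: float = 250.0, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Reduce clustered records: no two retained sites closer than ``min_dist_m``.

    A random-permutation greedy pass: visit sites in seeded random order
    and keep each one that is at least ``min_dist_m`` from every site
    already kept.  The retained set is a maximal independent set of the
    proximity graph and is deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xy = sites[["x", "y"]].to_numpy(dtype=float)
    order = rng.permutation(len(sites))
    kept: list[int] = []
    for i in order:
        if all(np.hypot(*(xy[i] - xy[j])) >= min_dist_m for j in kept):
            kept.append(i)
    kept_sorted = sorted(kept)
    return sites.iloc[kept_sorted].reset_index(drop=True)


def build_site_predictors(
    sites: pd.DataFrame,
    grid: ClimateGrid,
    talus_polygons=None,
    radii_km=DEFAULT_RADII_KM,
) -> pd.DataFrame:
    """Attach ``mst_min_{r}km`` columns (and log talus area if polygons given)."""
    out = sites.copy()
    for r in radii_km:
        out[f"mst_min_{r}km"] = [
            refugial_mst(grid, (row.x, row.y), r) for row in out.itertuples(index=False)
        ]
    if talus_polygons is not None:
        areas = [
            talus_area_within(talus_polygons, (row.x, row.y), 1.0)
            for row in out.itertuples(index=False)
        ]
        out["talus_area_1km"] = areas
        out["log_talus_area"] = [log_talus_area(a) for a in areas]
    return out


# ---------------------------------------------------------------------------
# Logistic fitting


def _neg_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> float:
    eta = X @ beta
    # log(1+exp) via logaddexp for stability
    ll = y @ eta - np.logaddexp(0.0, eta).sum()
    return -ll + 0.5 * ridge * (beta @ beta)


def fit_logistic(
    sites: pd.DataFrame,
    predictor_set,
    response: str = "occupancy",
    name: str | None = None,
    separation_fallback: str = "flag",
    ridge: float = 1e-4,
) -> OccupancyModel:
    """Maximum-likelihood logistic regression of occupancy on predictors.

    ``occupancy`` may be 0/1 or the strings extant/extirpated (extant = 1).
    Complete separation is detected (all fitted probabilities within
    ``SEPARATION_PROB_TOL`` of the observed classes) and flagged; with
    ``separation_fallback="ridge"`` the reported coefficients come from a
    weakly ridge-penalised refit instead of the diverging MLE path.
    """
    predictors = tuple(predictor_set)
    y_raw = sites[response]
    if y_raw.dtype == object:
        y = (y_raw == "extant").to_numpy(dtype=float)
    else:
        y = y_raw.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sites))] + [sites[p].to_numpy(dtype=float) for p in predictors])
    n, k = X.shape
    if not (0 < y.sum() < n):
        raise ValueError("both occupancy classes must be present")

    def solve(pen: float) -> optimize.OptimizeResult:
        return optimize.minimize(
            _neg_loglik, np.zeros(k), args=(X, y, pen), method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # BFGS line-search noise under separation
        res = solve(0.0)
    beta = res.x
    p_hat = expit(X @ beta)
    separated = bool(np.all(np.abs(p_hat - y) < SEPARATION_PROB_TOL))
    if separated and separation_fallback == "ridge":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = solve(ridge)
        beta = res.x
    llf = -_neg_loglik(beta, X, y, 0.0)

    cov = None
    p_hat = expit(X @ beta)
    W = p_hat * (1 - p_hat)
    info = (X * W[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = None

    coef = {"intercept": float(beta[0])}
    coef.update({p: float(b) for p, b in zip(predictors, beta[1:])})
    return OccupancyModel(
        name=name or "+".join(predictors),
        predictors=predictors,
        coefficients=coef,
        log_likelihood=float(llf),
        k=k,
        n=n,
        aicc=aicc_from_llf(float(llf), k, n),
        separation=separated,
        cov=cov,
    )


def rank_models(
    sites: pd.DataFrame,
    radii_km=DEFAULT_RADII_KM,
    talus_column: str | None = "log_talus_area",
    response: str = "occupancy",
    separation_fallback: str = "flag",
) -> pd.DataFrame:
    """Fit the candidate model set and rank by AICc (ascending).

    Candidates: one single-covariate model per radius, plus (if a talus
    column is available) each radius combined with talus area.  Ties are
    broken by fewer parameters, then model name.  Failed fits are recorded
    with NaN AICc and excluded from the ranking order.
    """
    specs: list[tuple[str, tuple[str, ...]]] = []
    for r in radii_km:
        col = f"mst_min_{r}km"
        specs.append((col, (col,)))
        if talus_column is not None and talus_column in sites.columns:
            specs.append((f"{col}+{talus_column}", (col, talus_column)))

    rows, models = [], {}
    for name, preds in specs:
        try:
            m = fit_logistic(sites, preds, response=response, name=name,
                             separation_fallback=separation_fallback)
            models[name] = m
            rows.append({
                "model": name, "k": m.k, "n": m.n,
                "log_likelihood": m.log_likelihood, "aicc": m.aicc,
                "separation": m.separation, "ok": True,
            })
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            warnings.warn(f"model {name!r} failed to fit: {exc}", stacklevel=2)
            rows.append({"model": name, "k": 1 + len(preds), "n": len(sites),
                         "log_likelihood": np.nan, "aicc": np.nan,
                         "separation": False, "ok": False})
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["ok", "aicc", "k", "model"], ascending=[False, True, True, True], kind="stable"
    ).reset_index(drop=True)
    best = table.loc[table["ok"], "aicc"].min()
    table["delta_aicc"] = table["aicc"] - best
    table.attrs["models"] = models
    return table


def occupancy_threshold(model: OccupancyModel) -> float:
    """Covariate value where the fitted occupancy probability crosses 0.5."""
    if len(model.predictors) != 1:
        raise ValueError("threshold defined only for single-covariate models")
    b0 = model.coefficients["intercept"]
    b1 = model.coefficients[model.predictors[0]]
    if b1 == 0:
        raise ZeroDivisionError("slope is zero; threshold undefined")
    return -b0 / b1


# ---------------------------------------------------------------------------
# Comparison against an external model's predictions


def _poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """PMF of a sum of independent Bernoulli(p_i), by dynamic programming."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def binomial_extirpation_test(
    extirpated: np.ndarray,
    prior_occupancy_probs: np.ndarray,
    null: str = "pooled_mean",
) -> float:
    """Exact two-sided test of the observed extirpation count.

    ``extirpated`` is boolean per site; ``prior_occupancy_probs`` are the
    external model's occupancy probabilities.  The null extirpation
    probability is their complement.  ``null`` selects the reference
    distribution: ``pooled_mean`` (binomial with p = mean extirpation
    probability), ``point_five`` (binomial, p = 0.5), or
    ``poisson_binomial`` (heterogeneous per-site probabilities).  Two-sided
    p sums the probabilities of all outcomes no more likely than the
    observed one.
    """
    extirpated = np.asarray(extirpated, dtype=bool)
    probs = np.asarray(prior_occupancy_probs, dtype=float)
    if extirpated.size == 0:
        raise ValueError("empty site set")
    if extirpated.shape != probs.shape:
        raise ValueError("sites and probabilities must align")
    n = extirpated.size
    x = int(extirpated.sum())
    p_ext = 1.0 - probs
    if null == "pooled_mean":
        return float(stats.binomtest(x, n, float(p_ext.mean())).pvalue)
    if null == "point_five":
        return float(stats.binomtest(x, n, 0.5).pvalue)
    if null == "poisson_binomial":
        pmf = _poisson_binomial_pmf(p_ext)
        obs = pmf[x]
        return float(pmf[pmf <= obs * (1 + 1e-12)].sum())
    raise ValueError(f"unknown null {null!r}")


def classification_rates(
    extant: np.ndarray, prior_occupancy_probs: np.ndarray, threshold: float = 0.5
) -> dict[str, float | None]:
    """Fraction of extant sites predicted occupied (p ≥ threshold) and of
    extirpated sites predicted extirpated (p < threshold)."""
    extant = np.asarray(extant, dtype=bool)
    probs = np.asarray(prior_occupancy_probs, dtype=float)
    out: dict[str, float | None] = {}
    n_ext = int(extant.sum())
    n_gone = int((~extant).sum())
    out["extant_correct"] = float((probs[extant] >= threshold).mean()) if n_ext else None
    out["extirpated_correct"] = float((probs[~extant] < threshold).mean()) if n_gone else None
    out["n_extant"] = n_ext
    out["n_extirpated"] = n_gone
    return out
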