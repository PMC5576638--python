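"""Tests for predictors, thinning, logistic fitting and model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import binom
from shapely.geometry import box

from taluscape.grids import ClimateGrid
from taluscape.occupancy import (
    aicc_from_llf,
    binomial_extirpation_test,
    build_site_predictors,
    classification_rates,
    fit_logistic,
    log_talus_area,
    occupancy_threshold,
    rank_models,
    refugial_mst,
    spatial_thin,
    talus_area_within,
)
from taluscape.synthetic import OccupancySpec, make_sites_with_occupancy, make_temperature_grid

from conftest import rough_grid_spec


def grid_from(values, cell=270.0):
    values = np.asarray(values, dtype=float)
    return ClimateGrid(values, 0.0, values.shape[0] * cell, cell)


class TestRefugialMst:
    def test_constant_grid(self, flat_grid):
        assert refugial_mst(flat_grid, (2700.0, 2700.0), 2.0) == 12.0

    def test_single_cool_cell_geometry(self):
        """Cool cell at 3.9 km: inside r=4 km, outside r=3 km."""
        v = np.full((70, 70), 16.0)
        site = (1450.0, 3450.0)  # exactly on the centre of cell (35, 14)
        # cell centres at (col + 0.5)·100 → col 53 is 3900 m east of x=1450
        col = int((site[0] + 3900.0) / 100.0 - 0.5)
        row = int((70 * 100.0 - site[1]) / 100.0 - 0.5)
        v[row, col] = 5.0
        grid = grid_from(v, cell=100.0)
        x_c = (col + 0.5) * 100.0
        assert abs(x_c - site[0]) == pytest.approx(3900.0)
        assert refugial_mst(grid, site, 4.0) == 5.0
        assert refugial_mst(grid, site, 3.0) == 16.0

    def test_matches_brute_force_scan(self, rng):
        v = rng.normal(14.0, 2.0, (50, 50))
        grid = grid_from(v, cell=100.0)
        site = (2500.0, 2500.0)
        r = 2.0
        result = refugial_mst(grid, site, r)
        best = np.inf
        for i in range(50):
            for j in range(50):
                xc, yc = (j + 0.5) * 100.0, grid.y_origin - (i + 0.5) * 100.0
                if (xc - site[0]) ** 2 + (yc - site[1]) ** 2 <= (r * 1000.0) ** 2:
                    best = min(best, v[i, j])
        assert result == best

    def test_nonincreasing_in_radius(self, rng):
        v = rng.normal(14.0, 2.0, (60, 60))
        grid = grid_from(v, cell=200.0)
        site = (6000.0, 6000.0)
        vals = [refugial_mst(grid, site, r) for r in (1, 2, 3, 4, 5)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_site_outside_grid_rejected(self, flat_grid):
        with pytest.raises(ValueError, match="outside"):
            refugial_mst(flat_grid, (-500.0, 100.0), 1.0)

    def test_nonpositive_radius_rejected(self, flat_grid):
        with pytest.raises(ValueError, match="radius"):
            refugial_mst(flat_grid, (2700.0, 2700.0), 0.0)


class TestTalusArea:
    def test_square_fully_inside(self):
        sq = box(-50, -50, 50, 50)
        assert talus_area_within([sq], (0.0, 0.0), 1.0) == pytest.approx(10_000.0, rel=1e-6)

    def test_square_fully_outside(self):
        sq = box(5000, 5000, 5100, 5100)
        assert talus_area_within([sq], (0.0, 0.0), 1.0) == 0.0

    def test_half_overlap_matches_monte_carlo(self, rng):
        """Large square straddling the disk edge vs 10⁶-point MC oracle."""
        sq = box(500, -800, 1800, 800)
        area = talus_area_within([sq], (0.0, 0.0), 1.0)
        n = 1_000_000
        xs = rng.uniform(500, 1800, n)
        ys = rng.uniform(-800, 800, n)
        inside = (xs**2 + ys**2) <= 1000.0**2
        mc = inside.mean() * (1300.0 * 1600.0)
        assert area == pytest.approx(mc, rel=0.01)

    def test_log_floor_for_zero_area(self):
        assert log_talus_area(0.0) == pytest.approx(0.0)
        assert log_talus_area(np.e - 1.0) == pytest.approx(1.0)


class TestSpatialThin:
    def _sites(self, coords):
        return pd.DataFrame({"site_id": [f"s{i}" for i in range(len(coords))],
                             "x": [c[0] for c in coords], "y": [c[1] for c in coords]})

    def test_all_far_apart_identity(self):
        sites = self._sites([(0, 0), (1000, 0), (0, 1000), (1000, 1000)])
        out = spatial_thin(sites, 250.0, seed=0)
        assert len(out) == 4

    def test_close_pair_one_retained(self):
        sites = self._sites([(0, 0), (100, 0)])
        out = spatial_thin(sites, 250.0, seed=3)
        assert len(out) == 1

    def test_chain_outcomes_exhaustive(self):
        """A–B 200 m, B–C 200 m, A–C 400 m: retained set ∈ {{A,C}, {B}} only,
        and both outcomes occur across seeds."""
        sites = self._sites([(0, 0), (200, 0), (400, 0)])
        seen = set()
        for seed in range(40):
            out = spatial_thin(sites, 250.0, seed=seed)
            seen.add(tuple(sorted(out["site_id"])))
        assert seen == {("s0", "s2"), ("s1",)}

    def test_min_distance_invariant(self, rng):
        xy = rng.uniform(0, 2000, (60, 2))
        sites = self._sites([tuple(p) for p in xy])
        out = spatial_thin(sites, 250.0, seed=7)
        pts = out[["x", "y"]].to_numpy()
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 250.0

    def test_deterministic_given_seed(self, rng):
        xy = rng.uniform(0, 1500, (40, 2))
        sites = self._sites([tuple(p) for p in xy])
        pd.testing.assert_frame_equal(spatial_thin(sites, 250.0, 11), spatial_thin(sites, 250.0, 11))


class TestFitLogistic:
    def test_parameter_recovery_within_wald_ci(self, rng):
        n = 1000
        x = rng.normal(14.0, 2.0, n)
        b0, b1 = 20.0, -1.4
        y = rng.random(n) < expit(b0 + b1 * x)
        df = pd.DataFrame({"occupancy": y.astype(int), "mst": x})
        m = fit_logistic(df, ("mst",))
        se = np.sqrt(np.diag(m.cov))
        assert abs(m.coefficients["intercept"] - b0) < 1.96 * se[0]
        assert abs(m.coefficients["mst"] - b1) < 1.96 * se[1]
        assert not m.separation

    def test_constant_predictor_balanced_classes(self):
        df = pd.DataFrame({"occupancy": [0, 1] * 25, "c": np.zeros(50)})
        m = fit_logistic(df, ("c",))
        assert m.coefficients["intercept"] == pytest.approx(0.0, abs=1e-5)

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.linspace(10, 13, 20), np.linspace(15, 18, 20)])
        y = np.concatenate([np.ones(20), np.zeros(20)]).astype(int)
        df = pd.DataFrame({"occupancy": y, "mst": x})
        m = fit_logistic(df, ("mst",))
        assert m.separation
        assert np.isfinite(m.aicc)

    def test_single_class_rejected(self):
        df = pd.DataFrame({"occupancy": np.ones(10, dtype=int), "x": np.arange(10.0)})
        with pytest.raises(ValueError, match="classes"):
            fit_logistic(df, ("x",))

    def test_string_labels_accepted(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.random(200) < expit(1.0 - x)
        df = pd.DataFrame({"occupancy": np.where(y, "extant", "extirpated"), "x": x})
        m = fit_logistic(df, ("x",))
        assert m.coefficients["x"] < 0

    def test_matches_independent_optimizer(self, rng):
        """Dual route: our BFGS-on-written-likelihood vs statsmodels IRLS."""
        import statsmodels.api as sm

        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 150
            x1 = r.normal(0, 1, n)
            x2 = r.normal(0, 1, n)
            y = (r.random(n) < expit(0.3 + 0.8 * x1 - 1.1 * x2)).astype(int)
            df = pd.DataFrame({"occupancy": y, "x1": x1, "x2": x2})
            m = fit_logistic(df, ("x1", "x2"))
            ref = sm.Logit(y, sm.add_constant(np.column_stack([x1, x2]))).fit(disp=0)
            assert m.log_likelihood == pytest.approx(ref.llf, abs=1e-6)


class TestAicc:
    def test_formula(self):
        assert aicc_from_llf(-10.0, 2, 30) == pytest.approx(20 + 4 + 2 * 2 * 3 / 27)

    def test_reduces_to_aic_for_large_n(self):
        aic = -2 * (-50.0) + 2 * 3
        assert aicc_from_llf(-50.0, 3, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc_from_llf(-1.0, 3, 4)


class TestRankModels:
    def _sites(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        grid, _ = make_temperature_grid(rough_grid_spec(), rng)
        spec = OccupancySpec(n_sites=n, beta0=0.0, beta1=-4.0, true_radius_km=4,
                             margin_km=5, auto_center_beta0=True)
        sites, _ = make_sites_with_occupancy(spec, grid, rng)
        return build_site_predictors(sites, grid, radii_km=(1, 2, 3, 4, 5))

    def test_generated_radius_ranks_first(self):
        wins = 0
        for seed in range(10):
            table = rank_models(self._sites(seed), talus_column=None)
            wins += table.iloc[0]["model"] == "mst_min_4km"
        assert wins >= 8

    def test_sorted_with_delta_column(self):
        table = rank_models(self._sites(3), talus_column=None)
        assert table["aicc"].is_monotonic_increasing
        assert table["delta_aicc"].iloc[0] == 0.0

    def test_duplicate_predictors_tie_break_by_k(self):
        sites = self._sites(4)
        sites["log_talus_area"] = 0.0  # degenerate extra predictor
        table = rank_models(sites, radii_km=(4,), talus_column="log_talus_area")
        assert len(table) == 2
        # constant extra covariate cannot improve the likelihood, and AICc
        # strictly penalises the extra parameter
        assert table.iloc[0]["model"] == "mst_min_4km"

    def test_invariant_to_site_ordering(self):
        sites = self._sites(5)
        shuffled = sites.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = rank_models(sites, talus_column=None)
        b = rank_models(shuffled, talus_column=None)
        assert list(a["model"]) == list(b["model"])
        np.testing.assert_allclose(a["aicc"], b["aicc"], atol=1e-6)


class TestThresholdAndComparison:
    def test_threshold_arithmetic(self):
        from taluscape.occupancy import OccupancyModel

        m = OccupancyModel("m", ("mst",), {"intercept": 28.4, "mst": -2.0}, -1.0, 2, 30, 0.0)
        assert occupancy_threshold(m) == pytest.approx(14.2)
        m0 = OccupancyModel("m", ("mst",), {"intercept": 0.0, "mst": -2.0}, -1.0, 2, 30, 0.0)
        assert occupancy_threshold(m0) == 0.0

    def test_threshold_zero_slope_rejected(self):
        from taluscape.occupancy import OccupancyModel

        m = OccupancyModel("m", ("mst",), {"intercept": 1.0, "mst": 0.0}, -1.0, 2, 30, 0.0)
        with pytest.raises(ZeroDivisionError):
            occupancy_threshold(m)

    def test_threshold_recovery_on_synthetic(self, rng):
        n = 2000
        x = rng.normal(14.2, 1.5, n)
        y = rng.random(n) < expit(-3.0 * (x - 14.2))
        df = pd.DataFrame({"occupancy": y.astype(int), "mst": x})
        m = fit_logistic(df, ("mst",))
        assert occupancy_threshold(m) == pytest.approx(14.2, abs=0.15)

    def test_binomial_14_of_14(self):
        extirpated = np.ones(14, dtype=bool)
        probs = np.full(14, 0.5)  # occupancy probability 0.5 → extirpation 0.5
        p = binomial_extirpation_test(extirpated, probs)
        assert p == pytest.approx(2 * 0.5**14)
        assert p < 0.001

    def test_binomial_observed_equals_expected(self):
        extirpated = np.concatenate([np.ones(5, dtype=bool), np.zeros(5, dtype=bool)])
        probs = np.full(10, 0.5)
        assert binomial_extirpation_test(extirpated, probs) == pytest.approx(1.0)

    def test_binomial_n1_enumeration(self):
        p0 = 0.3  # extirpation probability when occupancy prob is 0.7
        p_hit = binomial_extirpation_test(np.array([True]), np.array([0.7]))
        p_miss = binomial_extirpation_test(np.array([False]), np.array([0.7]))
        # with one trial the two-sided pmf-summing rule gives either the
        # smaller outcome probability or 1
        assert p_hit == pytest.approx(min(p0, 1 - p0) if p0 != 0.5 else 1.0)
        assert p_miss == pytest.approx(1.0)

    def test_poisson_binomial_matches_binomial_when_homogeneous(self):
        extirpated = np.concatenate([np.ones(9, dtype=bool), np.zeros(3, dtype=bool)])
        probs = np.full(12, 0.6)
        a = binomial_extirpation_test(extirpated, probs, null="pooled_mean")
        b = binomial_extirpation_test(extirpated, probs, null="poisson_binomial")
        assert a == pytest.approx(b, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binomial_extirpation_test(np.array([], dtype=bool), np.array([]))

    def test_classification_rates(self):
        extant = np.concatenate([np.ones(21, dtype=bool), np.zeros(16, dtype=bool)])
        probs = np.concatenate([
            np.full(18, 0.9), np.full(3, 0.2),   # 18/21 extant predicted occupied
            np.full(8, 0.1), np.full(8, 0.8),    # 8/16 extirpated predicted gone
        ])
        rates = classification_rates(extant, probs)
        assert rates["extant_correct"] == pytest.approx(18 / 21)
        assert rates["extirpated_correct"] == pytest.approx(8 / 16)

    def test_classification_single_class_flagged(self):
        rates = classification_rates(np.ones(5, dtype=bool), np.ones(5))
        assert rates["extant_correct"] == 1.0
        assert rates["extirpated_correct"] is None
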