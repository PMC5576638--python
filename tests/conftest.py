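import numpy as np
import pytest

from taluscape.calibration import POST_BOMB, PRE_BOMB, CalibrationCurve
from taluscape.grids import ClimateGrid
from taluscape.synthetic import CurveSpec, GridSpec, OccupancySpec, SyntheticScenario, make_calibration_curve


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bomb_curve():
    """Plateau + spike curve whose post-1955 limb is two-branched."""
    return make_calibration_curve(CurveSpec(plateau_fm=0.98, spike_year=1955, amplitude=0.8,
                                            year_start=1700, year_end=2010))


@pytest.fixture
def monotone_curve():
    """Strictly increasing Fm over 1800–1950 (unique inversion)."""
    years = np.arange(1800.0, 1951.0)
    fm = 0.90 + 0.0005 * (years - 1800.0)
    return CalibrationCurve(years, fm, np.full_like(years, 0.002),
                            np.full(len(years), PRE_BOMB, dtype=object))


@pytest.fixture
def flat_grid():
    """Constant 12 °C, 20×20 cells of 270 m."""
    return ClimateGrid(np.full((20, 20), 12.0), x_origin=0.0, y_origin=20 * 270.0, cell_size=270.0)


def rough_grid_spec(nrows=90, ncols=90):
    """Terrain rough enough that 1–5 km refugial minima decorrelate."""
    return GridSpec(nrows=nrows, ncols=ncols, base_temp=16.5, relief_m=900,
                    n_bumps=60, bump_width_frac=(0.02, 0.06))
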