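"""Scenario projection of refugial and climatically suitable habitat area.

A scenario is a uniform °C offset added to the current temperature grid.
Refugial cells are those strictly below the occupancy threshold; suitable
cells are those within the dispersal radius of any refugial cell
(centre-to-centre Euclidean distance).  Areas are cell counts × cell area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ClimateGrid

__all__ = [
    "ScenarioSpec",
    "AreaSummary",
    "apply_scenario",
    "refugial_mask",
    "suitable_mask",
    "area_summary",
    "project_scenarios",
]

DEFAULT_THRESHOLD_C = 14.2
DEFAULT_DISPERSAL_KM = 4.0


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    delta: float  # uniform °C offset relative to the current grid


@dataclass(frozen=True)
class AreaSummary:
    scenario: str
    refugial_km2: float
    suitable_km2: float
    refugial_pct_decline: float | None  # vs current baseline; None for baseline itself
    suitable_pct_decline: float | None


def apply_scenario(grid: ClimateGrid, scenario: ScenarioSpec) -> ClimateGrid:
    """Add the scenario's uniform offset cellwise; nodata preserved."""
    if not np.isfinite(scenario.delta):
        raise ValueError(f"scenario delta must be finite, got {scenario.delta}")
    return grid.copy_with(grid.values + scenario.delta)


def refugial_mask(grid: ClimateGrid, threshold: float = DEFAULT_THRESHOLD_C) -> np.ndarray:
    """Boolean raster: temperature strictly below threshold, nodata excluded."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    with np.errstate(invalid="ignore"):
        return (grid.values < threshold) & np.isfinite(grid.values)


def suitable_mask(refugia: np.ndarray, cell_size: float, dispersal_km: float = DEFAULT_DISPERSAL_KM) -> np.ndarray:
    """Cells whose centre is within the dispersal radius of a refugial cell centre.

    Uses an exact Euclidean distance transform in cell units; refugial
    cells are at distance 0 and hence always suitable.
    """
    refugia = np.asarray(refugia, dtype=bool)
    if not refugia.any():
        return np.zeros_like(refugia)
    dist = ndimage.distance_transform_edt(~refugia) * cell_size
    return dist <= dispersal_km * 1000.0


def area_summary(
    masks_by_scenario: dict[str, tuple[np.ndarray, np.ndarray]],
    cell_size: float,
    baseline: str = "current",
) -> list[AreaSummary]:
    """km² accounting per scenario with percent declines vs the baseline.

    ``masks_by_scenario`` maps name → (refugial_mask, suitable_mask); all
    masks must share one geometry.  Declines are unrounded fractions × 100.
    """
    shapes = {m[0].shape for m in masks_by_scenario.values()} | {
        m[1].shape for m in masks_by_scenario.values()
    }
    if len(shapes) > 1:
        raise ValueError("masks have inconsistent geometry")
    km2 = cell_size * cell_size / 1e6

    def areas(name: str) -> tuple[float, float]:
        ref, suit = masks_by_scenario[name]
        return float(ref.sum() * km2), float(suit.sum() * km2)

    if baseline not in masks_by_scenario:
        raise ValueError(f"baseline scenario {baseline!r} missing")
    ref0, suit0 = areas(baseline)

    out = []
    for name in masks_by_scenario:
        ref, suit = areas(name)
        if name == baseline:
            rd = sd = None
        else:
            rd = 100.0 * (1.0 - ref / ref0) if ref0 > 0 else None
            sd = 100.0 * (1.0 - suit / suit0) if suit0 > 0 else None
        out.append(AreaSummary(name, ref, suit, rd, sd))
    return out


def project_scenarios(
    grid: ClimateGrid,
    scenarios: list[ScenarioSpec],
    threshold: float = DEFAULT_THRESHOLD_C,
    dispersal_km: float = DEFAULT_DISPERSAL_KM,
    baseline: str = "current",
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], list[AreaSummary]]:
    """Apply each scenario, build refugial/suitable masks, and summarise areas."""
    masks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sc in scenarios:
        shifted = apply_scenario(grid, sc)
        ref = refugial_mask(shifted, threshold)
        masks[sc.name] = (ref, suitable_mask(ref, grid.cell_size, dispersal_km))
    return masks, area_summary(masks, grid.cell_size, baseline=baseline)
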