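"""Thresholding suitability maps and stacking species into richness.

Binarization uses the "10-percentile training presence" rule: the cut-off is
the smallest training-presence suitability value such that at least 90% of
training presences score at or above it; cells at or above the threshold are
classed present. This keeps training omission at or below 10% (plus
discreteness slack 1/m) by construction, without any interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rangeshift.grid import GridSpec


@dataclass
class BinaryMap:
    """Per-cell presence (1) / absence (0) with NaN on masked cells."""

    grid: GridSpec
    data: np.ndarray  # float array: 0.0, 1.0 or NaN
    species: str
    period: str = "current"
    scenario: str = ""
    threshold: float = np.nan

    def __post_init__(self) -> None:
        if self.data.shape != self.grid.shape:
            raise ValueError("binary map shape does not match grid")
        vals = self.data[np.isfinite(self.data)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("binary map must contain only 0, 1 and NaN")

    @property
    def presence_count(self) -> int:
        return int(np.nansum(self.data))

    def presence_cells(self) -> np.ndarray:
        return np.argwhere(self.data == 1.0)


@dataclass
class RichnessMap:
    """Per-cell count of species predicted present."""

    grid: GridSpec
    data: np.ndarray
    species: list[str]
    period: str = "current"
    scenario: str = ""


def ten_percentile_threshold(training_values: Sequence[float]) -> float:
    """The 10-percentile training presence threshold (lower-value convention).

    Returns the smallest training value v with at least 90% of training
    presences at or above v; under >= binarization, at most
    floor(0.1 m) training presences fall in predicted-absent cells.
    """
    vals = np.sort(np.asarray(training_values, dtype=float))
    m = len(vals)
    if m == 0:
        raise ValueError("need at least one training presence value")
    n_keep = (9 * m + 9) // 10  # ceil(0.9 m), integer-exact
    return float(vals[m - n_keep])


def binarize(
    suitability: np.ndarray,
    threshold: float,
    grid: GridSpec,
    species: str,
    period: str = "current",
    scenario: str = "",
) -> BinaryMap:
    """Cells at or above the threshold become 1, below 0; NaN preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    data = np.where(np.isnan(suitability), np.nan, (suitability >= threshold).astype(float))
    return BinaryMap(grid, data, species, period, scenario, threshold)


def stack_richness(binaries: Sequence[BinaryMap]) -> RichnessMap:
    """Cellwise sum of per-species binary maps (one map per species)."""
    if not binaries:
        raise ValueError("no binary maps to stack")
    species = [b.species for b in binaries]
    if len(set(species)) != len(species):
        raise ValueError("duplicate species in richness stack")
    grid = binaries[0].grid
    if any(b.grid != grid for b in binaries):
        raise ValueError("binary maps are on different grids")
    total = np.sum([b.data for b in binaries], axis=0)
    return RichnessMap(grid, total, species, binaries[0].period, binaries[0].scenario)


def richness_change(current: RichnessMap, future: RichnessMap) -> np.ndarray:
    """Signed per-cell species change, future minus current.

    Negative cells lose species, positive cells gain species.
    """
    if current.grid != future.grid:
        raise ValueError("richness maps are on different grids")
    if set(current.species) != set(future.species):
        raise ValueError("richness maps cover different species sets")
    return future.data - current.data
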