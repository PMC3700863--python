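"""The 19 bioclimatic variables (BIO1-BIO19) from monthly climate grids.

The layers follow the WorldClim dialect: BIO4 is 100 x the (population)
standard deviation of monthly mean temperature, and BIO15 is
100 x sd(precip) / (1 + mean(precip)). Temperatures are in degrees C
throughout (not the integer C x 10 storage convention). "Quarters" are any
three consecutive months, wrapping December-January; ties between equally
wet/dry/warm/cold quarters resolve to the earliest starting month.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from rangeshift.climate import ClimateStack
from rangeshift.grid import GridSpec, read_ascii_grid, write_ascii_grid

BIOCLIM_NAMES: tuple[str, ...] = tuple(f"BIO{i}" for i in range(1, 20))

#: Human-readable layer descriptions, WorldClim numbering.
BIOCLIM_LONG_NAMES = {
    "BIO1": "Annual Mean Temperature",
    "BIO2": "Mean Diurnal Range",
    "BIO3": "Isothermality (BIO2/BIO7 x 100)",
    "BIO4": "Temperature Seasonality (sd x 100)",
    "BIO5": "Max Temperature of Warmest Month",
    "BIO6": "Min Temperature of Coldest Month",
    "BIO7": "Temperature Annual Range",
    "BIO8": "Mean Temperature of Wettest Quarter",
    "BIO9": "Mean Temperature of Driest Quarter",
    "BIO10": "Mean Temperature of Warmest Quarter",
    "BIO11": "Mean Temperature of Coldest Quarter",
    "BIO12": "Annual Precipitation",
    "BIO13": "Precipitation of Wettest Month",
    "BIO14": "Precipitation of Driest Month",
    "BIO15": "Precipitation Seasonality (CV)",
    "BIO16": "Precipitation of Wettest Quarter",
    "BIO17": "Precipitation of Driest Quarter",
    "BIO18": "Precipitation of Warmest Quarter",
    "BIO19": "Precipitation of Coldest Quarter",
}


@dataclass
class BioclimStack:
    """The 19 derived bioclimatic layers on a shared grid."""

    grid: GridSpec
    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(BIOCLIM_NAMES) - set(self.layers)
        if missing:
            raise ValueError(f"missing bioclim layers: {sorted(missing)}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells with finite values in every layer."""
        return np.all([np.isfinite(self.layers[n]) for n in BIOCLIM_NAMES], axis=0)

    def write(self, directory: str | Path) -> None:
        for name in BIOCLIM_NAMES:
            write_ascii_grid(Path(directory) / f"{name.lower()}.asc", self.grid, self.layers[name])

    @classmethod
    def read(cls, directory: str | Path) -> "BioclimStack":
        layers = {}
        grid = None
        for name in BIOCLIM_NAMES:
            spec, data = read_ascii_grid(Path(directory) / f"{name.lower()}.asc")
            grid = grid or spec
            layers[name] = data
        return cls(grid, layers)


def _quarter_windows(monthly: np.ndarray, reduce: str) -> np.ndarray:
    """All 12 wrap-around 3-month windows of a (12, R, C) stack.

    Returns shape (12, R, C): window w covers months w, w+1, w+2 (mod 12),
    reduced by mean (temperature) or sum (precipitation).
    """
    wrapped = np.concatenate([monthly, monthly[:2]], axis=0)
    windows = np.stack([wrapped[w : w + 3] for w in range(12)])
    return windows.mean(axis=1) if reduce == "mean" else windows.sum(axis=1)


def _pick(values: np.ndarray, index: np.ndarray) -> np.ndarray:
    """Cellwise selection values[index[r, c], r, c]."""
    return np.take_along_axis(values, index[None], axis=0)[0]


def derive_bioclim(climate: ClimateStack) -> BioclimStack:
    """Compute BIO1-BIO19 cellwise from 12 months of tmin/tmax/precipitation.

    NaN in any input month propagates to NaN in all 19 output layers for
    that cell.
    """
    tmin, tmax, prec = climate.tmin, climate.tmax, climate.prec
    with np.errstate(invalid="ignore", divide="ignore"):
        tmean = (tmin + tmax) / 2.0

        bio = {}
        bio["BIO1"] = tmean.mean(axis=0)
        bio["BIO2"] = (tmax - tmin).mean(axis=0)
        bio["BIO4"] = 100.0 * tmean.std(axis=0)  # population sd
        bio["BIO5"] = tmax.max(axis=0)
        bio["BIO6"] = tmin.min(axis=0)
        bio["BIO7"] = bio["BIO5"] - bio["BIO6"]
        # 0/0 -> 0: a zero annual range forces a zero diurnal range
        bio["BIO3"] = np.where(
            bio["BIO7"] > 0, 100.0 * bio["BIO2"] / np.where(bio["BIO7"] > 0, bio["BIO7"], 1.0), 0.0
        )

        tmean_q = _quarter_windows(tmean, "mean")
        prec_q = _quarter_windows(prec, "sum")
        # argmax/argmin return the first (earliest-starting) extreme window
        wet = prec_q.argmax(axis=0)
        dry = prec_q.argmin(axis=0)
        warm = tmean_q.argmax(axis=0)
        cold = tmean_q.argmin(axis=0)
        bio["BIO8"] = _pick(tmean_q, wet)
        bio["BIO9"] = _pick(tmean_q, dry)
        bio["BIO10"] = _pick(tmean_q, warm)
        bio["BIO11"] = _pick(tmean_q, cold)
        bio["BIO16"] = _pick(prec_q, wet)
        bio["BIO17"] = _pick(prec_q, dry)
        bio["BIO18"] = _pick(prec_q, warm)
        bio["BIO19"] = _pick(prec_q, cold)

        bio["BIO12"] = prec.sum(axis=0)
        bio["BIO13"] = prec.max(axis=0)
        bio["BIO14"] = prec.min(axis=0)
        prec_mean = prec.mean(axis=0)
        bio["BIO15"] = 100.0 * prec.std(axis=0) / (1.0 + prec_mean)

    invalid = ~(
        np.all(np.isfinite(tmin), axis=0)
        & np.all(np.isfinite(tmax), axis=0)
        & np.all(np.isfinite(prec), axis=0)
    )
    for name in BIOCLIM_NAMES:
        layer = np.asarray(bio[name], dtype=float)
        layer[invalid] = np.nan
        bio[name] = layer
    return BioclimStack(climate.grid, bio)


def mask_to_box(
    stack: BioclimStack, lon_min: float, lon_max: float, lat_min: float, lat_max: float
) -> BioclimStack:
    """Set cells whose centers fall outside the lon/lat box to NaN.

    Grid shape is preserved. Raises if no cell center lies inside the box.
    """
    lon = stack.grid.lon_centers()[None, :]
    lat = stack.grid.lat_centers()[:, None]
    inside = (lon >= lon_min) & (lon <= lon_max) & (lat >= lat_min) & (lat <= lat_max)
    inside = np.broadcast_to(inside, stack.grid.shape)
    if not inside.any():
        raise ValueError("mask box does not intersect the grid")
    layers = {}
    for name in BIOCLIM_NAMES:
        layer = stack.layers[name].copy()
        layer[~inside] = np.nan
        layers[name] = layer
    return BioclimStack(stack.grid, layers)
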