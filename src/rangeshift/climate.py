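"""Monthly climate stacks: 12 layers each of tmin, tmax and precipitation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from rangeshift.grid import GridSpec, read_ascii_grid, write_ascii_grid


@dataclass
class ClimateStack:
    """Gridded monthly climate for one period/scenario.

    ``tmin``/``tmax`` are in degrees C, ``prec`` in mm, each with shape
    ``(12, n_rows, n_cols)`` on ``grid``.
    """

    grid: GridSpec
    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray

    def __post_init__(self) -> None:
        expected = (12, *self.grid.shape)
        for name in ("tmin", "tmax", "prec"):
            arr = getattr(self, name)
            if arr.shape != expected:
                raise ValueError(f"{name} has shape {arr.shape}, expected {expected}")

    def write(self, directory: str | Path) -> None:
        """Write 36 per-month ESRI ASCII grids (tmin_01.asc ... prec_12.asc)."""
        directory = Path(directory)
        for name in ("tmin", "tmax", "prec"):
            arr = getattr(self, name)
            for month in range(12):
                write_ascii_grid(directory / f"{name}_{month + 1:02d}.asc", self.grid, arr[month])

    @classmethod
    def read(cls, directory: str | Path) -> "ClimateStack":
        directory = Path(directory)
        layers: dict[str, list[np.ndarray]] = {}
        grid: GridSpec | None = None
        for name in ("tmin", "tmax", "prec"):
            stack = []
            for month in range(12):
                path = directory / f"{name}_{month + 1:02d}.asc"
                if not path.exists():
                    raise FileNotFoundError(f"missing monthly layer {path}")
                spec, data = read_ascii_grid(path)
                if grid is None:
                    grid = spec
                elif spec != grid:
                    raise ValueError(f"layer {path} is on a different grid")
                stack.append(data)
            layers[name] = stack
        assert grid is not None
        return cls(grid, *(np.stack(layers[n]) for n in ("tmin", "tmax", "prec")))
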