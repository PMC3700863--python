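"""Synthetic climate grids and occurrence records with known ground truth.

Real studies of this kind start from a volunteer occurrence database and
monthly climate normals plus GCM scenario layers; neither is redistributable
here, so this module fabricates both with controlled, documented structure:

* monthly climate = latitudinal gradient + seasonal cycle + spatially
  autocorrelated noise (Gaussian-smoothed white noise);
* future scenarios = additive warming and multiplicative precipitation change;
* occurrences = cells drawn from a log-linear (Gibbs) suitability over the
  derived bioclim layers, optionally multiplied by an observer-bias kernel
  around "popular birding sites", with in-cell jitter, a seasonal date, and a
  source flag.

Because the generating suitability is known, parameter recovery and
range-shift direction are testable downstream.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from rangeshift.bioclim import BioclimStack
from rangeshift.climate import ClimateStack
from rangeshift.grid import GridSpec
from rangeshift.records import OccurrenceRecord


@dataclass(frozen=True)
class TruthModel:
    """Ground-truth log-linear suitability over standardized bioclim layers.

    Suitability is ``exp(intercept + sum_v linear[v] * z_v + quadratic[v] * z_v**2)``
    where ``z_v`` is the layer standardized (mean 0, sd 1) over unmasked cells.
    A negative quadratic weight paired with a linear term encodes a climatic
    optimum, which is what makes ranges track isotherms under warming.
    """

    linear: dict[str, float]
    quadratic: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0

    def log_suitability(self, bioclim: BioclimStack) -> np.ndarray:
        """Per-cell log suitability; NaN on masked cells."""
        valid = bioclim.valid_mask
        out = np.full(bioclim.grid.shape, self.intercept, dtype=float)
        for name in set(self.linear) | set(self.quadratic):
            layer = bioclim[name]
            vals = layer[valid]
            sd = vals.std()
            z = (layer - vals.mean()) / (sd if sd > 0 else 1.0)
            out += self.linear.get(name, 0.0) * z
            out += self.quadratic.get(name, 0.0) * z**2
        out[~valid] = np.nan
        return out

    def suitability(self, bioclim: BioclimStack) -> np.ndarray:
        return np.exp(self.log_suitability(bioclim))


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Unit-variance Gaussian-smoothed white noise; infinite smoothness -> flat 0."""
    if not np.isfinite(smoothness):
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    if smoothness > 0:
        noise = gaussian_filter(noise, sigma=smoothness, mode="nearest")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return noise


def make_climate(
    spec: GridSpec,
    seed: int,
    smoothness: float = 3.0,
    mean_temp: float = 12.0,
    lat_gradient: float = -1.0,
    seasonal_amplitude: float = 10.0,
    temp_noise_sd: float = 2.0,
    diurnal_range: float = 10.0,
    annual_precip: float = 600.0,
    precip_winter_fraction: float = 0.5,
    precip_noise_sd: float = 0.4,
) -> ClimateStack:
    """Generate 12 months each of tmin/tmax/precipitation on ``spec``.

    Parameters
    ----------
    smoothness
        Gaussian length scale of the noise fields, in cells. ``np.inf``
        removes the noise entirely (spatially constant anomaly).
    mean_temp, lat_gradient
        Annual mean temperature (deg C) at the mid-latitude of the grid and
        its change per degree of northward latitude (negative in the
        northern hemisphere).
    seasonal_amplitude
        Half peak-to-trough amplitude of the annual temperature cycle (deg C),
        warmest in July.
    diurnal_range
        Mean tmax - tmin (deg C); spatial noise never drives it below 0.5.
    annual_precip, precip_winter_fraction
        Total annual precipitation (mm) at an average cell, and the strength
        of the winter-wet (Mediterranean) seasonal modulation in [0, 1).
    """
    if spec.n_cells == 0:
        raise ValueError("degenerate grid with zero cells")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    lat = spec.lat_centers()[:, None]
    lat_mid = 0.5 * (spec.lat_min + spec.lat_max)

    annual = mean_temp + lat_gradient * (lat - lat_mid)
    annual = annual + temp_noise_sd * _smooth_noise(rng, spec.shape, smoothness)
    dr = diurnal_range + 2.0 * _smooth_noise(rng, spec.shape, smoothness)
    dr = np.clip(dr, 0.5, None)
    precip_field = (annual_precip / 12.0) * np.exp(
        precip_noise_sd * _smooth_noise(rng, spec.shape, smoothness)
    )
    # winter-wet (Mediterranean) strength varies smoothly in space, as it
    # does between coastal and continental climates
    winter_frac = np.clip(
        precip_winter_fraction + 0.3 * _smooth_noise(rng, spec.shape, smoothness), 0.0, 0.95
    )

    months = np.arange(12)
    # month 6 (July) warmest; month 0 (January) wettest
    season_t = -np.cos(2.0 * np.pi * (months - 0.5) / 12.0)
    season_p = np.cos(2.0 * np.pi * (months + 0.5) / 12.0)

    tmean = annual[None] + seasonal_amplitude * season_t[:, None, None]
    tmin = tmean - dr[None] / 2.0
    tmax = tmean + dr[None] / 2.0
    prec = precip_field[None] * (1.0 + winter_frac[None] * season_p[:, None, None])
    return ClimateStack(spec, tmin, tmax, np.clip(prec, 0.0, None))


def perturb_climate(base: ClimateStack, delta_t: float, precip_factor: float) -> ClimateStack:
    """Scenario perturbation: shift temperatures, scale precipitation."""
    if precip_factor <= 0:
        raise ValueError("precip_factor must be positive")
    return ClimateStack(
        base.grid,
        base.tmin + delta_t,
        base.tmax + delta_t,
        base.prec * precip_factor,
    )


def sample_occurrences(
    truth: TruthModel,
    bioclim: BioclimStack,
    n: int,
    seed: int,
    species: str = "species",
    bias_centers: list[tuple[int, int]] | None = None,
    bias_strength: float = 0.0,
    bias_sigma: float = 2.0,
    date_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2005, 4, 15),
        datetime.date(2005, 7, 30),
    ),
    source: str = "casual",
) -> list[OccurrenceRecord]:
    """Draw ``n`` records from the truth suitability over unmasked cells.

    Cells are drawn with probability proportional to
    ``suitability * (1 + bias_strength * K)`` where ``K`` is a Gaussian kernel
    (scale ``bias_sigma`` cells) around each bias center — emulating records
    piling up near frequently visited sites. Coordinates are jittered
    uniformly within the cell; dates are uniform in ``date_window``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    grid = bioclim.grid
    weight = truth.suitability(bioclim)
    valid = np.isfinite(weight)
    if bias_centers and bias_strength > 0:
        rows, cols = np.indices(grid.shape)
        kernel = np.zeros(grid.shape)
        for r0, c0 in bias_centers:
            d2 = (rows - r0) ** 2 + (cols - c0) ** 2
            kernel += np.exp(-d2 / (2.0 * bias_sigma**2))
        weight = weight * (1.0 + bias_strength * kernel)
    weight = np.where(valid, weight, 0.0)
    total = weight.sum()
    if n > 0 and (not np.isfinite(total) or total <= 0):
        raise ValueError("suitability is zero or non-finite everywhere")
    if n == 0:
        return []

    rng = np.random.default_rng(seed)
    flat_p = (weight / total).ravel()
    draws = rng.choice(grid.n_cells, size=n, p=flat_p)
    rows, cols = np.unravel_index(draws, grid.shape)

    day0 = date_window[0].toordinal()
    n_days = date_window[1].toordinal() - day0 + 1
    if n_days <= 0:
        raise ValueError("date_window end precedes start")
    days = rng.integers(0, n_days, size=n)
    jitter = rng.random(size=(n, 2))

    records = []
    for i in range(n):
        lon = grid.lon_min + (cols[i] + jitter[i, 0]) * grid.cell_size
        lat = grid.lat_min + (rows[i] + jitter[i, 1]) * grid.cell_size
        records.append(
            OccurrenceRecord(
                species=species,
                lon=float(lon),
                lat=float(lat),
                date=datetime.date.fromordinal(day0 + int(days[i])),
                source=source,
            )
        )
    return records
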