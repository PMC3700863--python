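"""Per-species range change between periods.

Overlap maps are the cellwise product of current and future binary maps, and
overlap percentage is the share of currently occupied cells still occupied in
the future. Areas and centroids weight cells by cos(latitude), since on a
geographic grid cell area shrinks poleward. Centroid displacement is the
great-circle (haversine) distance on a sphere of radius 6371 km, and the
zonal ellipse is the eigendecomposition of the presence cells' coordinate
covariance on a km-scaled local plane.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rangeshift.postprocess import BinaryMap

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0  # 111.19 km per degree of arc


@dataclass
class RangeChange:
    """Summary of one species' range change between two periods."""

    species: str
    scenario: str
    period_from: str
    period_to: str
    overlap_percent: float
    area_change_percent: float
    centroid_from: tuple[float, float]
    centroid_to: tuple[float, float]
    displacement_km: float


def _check_same_grid(a: BinaryMap, b: BinaryMap) -> None:
    if a.grid != b.grid:
        raise ValueError("binary maps are on different grids")


def overlap_map(current: BinaryMap, future: BinaryMap) -> BinaryMap:
    """Cellwise product: 1 exactly where present in both periods."""
    _check_same_grid(current, future)
    return BinaryMap(
        current.grid,
        current.data * future.data,
        current.species,
        period=f"{current.period}*{future.period}",
        scenario=future.scenario,
    )


def overlap_percent(current: BinaryMap, future: BinaryMap) -> float:
    """100 x (cells present in both periods) / (current presence cells).

    NaN (with a warning) when the current range is empty.
    """
    _check_same_grid(current, future)
    n_current = current.presence_count
    if n_current == 0:
        warnings.warn(f"{current.species}: empty current range, overlap undefined")
        return float("nan")
    n_overlap = int(np.nansum(current.data * future.data))
    return 100.0 * n_overlap / n_current


def _weighted_area(binary: BinaryMap) -> float:
    """Occupied area in cos(latitude)-weighted cell units."""
    weights = binary.grid.cos_lat_weights()[:, None]
    return float(np.nansum(binary.data * weights))


def area_change_percent(current: BinaryMap, future: BinaryMap) -> float:
    """100 x (area_future - area_current) / area_current, cos-lat weighted."""
    _check_same_grid(current, future)
    a_cur = _weighted_area(current)
    if a_cur == 0:
        warnings.warn(f"{current.species}: empty current range, area change undefined")
        return float("nan")
    return 100.0 * (_weighted_area(future) - a_cur) / a_cur


def zonal_centroid(binary: BinaryMap) -> tuple[float, float]:
    """Area-weighted mean (lon, lat) of presence-cell centers."""
    cells = binary.presence_cells()
    if len(cells) == 0:
        raise ValueError(f"{binary.species}: empty map has no centroid")
    lon = binary.grid.lon_centers()[cells[:, 1]]
    lat = binary.grid.lat_centers()[cells[:, 0]]
    w = np.cos(np.deg2rad(lat))
    return (float(np.average(lon, weights=w)), float(np.average(lat, weights=w)))


def centroid_displacement_km(c1: tuple[float, float], c2: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lon, lat) points."""
    lon1, lat1, lon2, lat2 = np.deg2rad([c1[0], c1[1], c2[0], c2[1]])
    a = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def zonal_ellipse(binary: BinaryMap) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues/eigenvectors of the presence-cell coordinate covariance.

    Coordinates are projected to a km-scaled plane about the centroid
    (dlon * cos(centroid lat) * km/deg, dlat * km/deg) and weighted by cell
    area. Eigenvalues are returned in descending order (km^2), eigenvectors
    as columns. A single presence cell yields a zero matrix with a warning.
    """
    cells = binary.presence_cells()
    if len(cells) == 0:
        raise ValueError(f"{binary.species}: empty map has no ellipse")
    lon_c, lat_c = zonal_centroid(binary)
    if len(cells) == 1:
        warnings.warn(f"{binary.species}: single presence cell, degenerate ellipse")
        return np.zeros(2), np.eye(2)
    lon = binary.grid.lon_centers()[cells[:, 1]]
    lat = binary.grid.lat_centers()[cells[:, 0]]
    x = (lon - lon_c) * np.cos(np.deg2rad(lat_c)) * KM_PER_DEGREE
    y = (lat - lat_c) * KM_PER_DEGREE
    w = np.cos(np.deg2rad(lat))
    w = w / w.sum()
    cov = np.cov(np.vstack([x, y]), aweights=w, ddof=0)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def range_change(current: BinaryMap, future: BinaryMap) -> RangeChange:
    """All between-period metrics for one species in one record."""
    c_from = zonal_centroid(current)
    c_to = zonal_centroid(future) if future.presence_count else c_from
    return RangeChange(
        species=current.species,
        scenario=future.scenario,
        period_from=current.period,
        period_to=future.period,
        overlap_percent=overlap_percent(current, future),
        area_change_percent=area_change_percent(current, future),
        centroid_from=c_from,
        centroid_to=c_to,
        displacement_km=centroid_displacement_km(c_from, c_to),
    )


def turnover_same_species(timeline: Sequence[BinaryMap]) -> dict[str, object]:
    """Persistence of one species' range across an ordered timeline.

    Returns the consecutive-pair overlap percentages (each period compared
    with the previous one) and the all-timeline persistence: the percentage
    of currently occupied cells predicted present in *every* period.
    """
    if len(timeline) < 2:
        raise ValueError("need at least two periods")
    for later in timeline[1:]:
        _check_same_grid(timeline[0], later)
    pairwise = [overlap_percent(a, b) for a, b in zip(timeline[:-1], timeline[1:])]
    n_current = timeline[0].presence_count
    if n_current == 0:
        persistence = float("nan")
    else:
        stack = np.array([b.data for b in timeline])
        in_all = int(np.nansum(np.prod(stack, axis=0)))
        persistence = 100.0 * in_all / n_current
    return {"pairwise_percent": pairwise, "all_timeline_percent": persistence}


def turnover_table(timelines: Mapping[str, Sequence[BinaryMap]]) -> tuple[pd.DataFrame, dict]:
    """Turnover per species plus the group mean +/- population sd.

    Species with an empty current range are excluded from the averages with
    a log entry.
    """
    rows = []
    for species, timeline in timelines.items():
        result = turnover_same_species(timeline)
        row = {"species": species, "all_timeline_percent": result["all_timeline_percent"]}
        for i, pct in enumerate(result["pairwise_percent"]):
            row[f"overlap_{timeline[i].period}_to_{timeline[i + 1].period}"] = pct
        rows.append(row)
    table = pd.DataFrame(rows).set_index("species")
    excluded = table.index[table["all_timeline_percent"].isna()].tolist()
    if excluded:
        logger.info("excluded from turnover averages (empty current range): %s", excluded)
    valid = table.dropna()
    summary = {
        "mean": valid.mean().to_dict(),
        "sd": valid.std(ddof=0).to_dict(),
        "n_species": int(len(valid)),
        "excluded": excluded,
    }
    return table, summary
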