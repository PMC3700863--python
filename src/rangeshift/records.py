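"""Occurrence ingestion and the record/species selection rules.

Cleaning mirrors how presence-only volunteer datasets are prepared for
climate-envelope modelling:

* drop systematic-survey and ringing-station records (they oversample a few
  sites relative to casual observations);
* keep migrants only within the breeding season (April 15 - July 30,
  inclusive) so that passage records do not contaminate the breeding range;
* drop resident records from the deep winter window (December 1 - January 31,
  inclusive, wrapping the year boundary) when cold-weather nomadism moves
  birds off their breeding ranges;
* model only species with more than 25 retained records (strict inequality).

Both date windows are inclusive at both endpoints.
"""

from __future__ import annotations

import csv
import datetime
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rangeshift.grid import GridSpec

logger = logging.getLogger(__name__)

SOURCES = frozenset({"casual", "bbs", "ringing"})
SURVEY_SOURCES = frozenset({"bbs", "ringing"})
GROUPS = frozenset({"resident", "migratory"})

#: Breeding-season window for migrants (month, day), inclusive.
BREEDING_WINDOW = ((4, 15), (7, 30))
#: Winter exclusion window for residents (month, day), inclusive; wraps Dec->Jan.
WINTER_WINDOW = ((12, 1), (1, 31))

MIN_RECORDS = 25


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced, dated observation of a species."""

    species: str
    lon: float
    lat: float
    date: datetime.date
    source: str


@dataclass
class PresenceSet:
    """Presence cells of one species on the analysis grid."""

    species: str
    cells: list[tuple[int, int]]
    n_records: int  # raw records retained inside the grid
    n_outside: int  # records dropped for falling outside the grid

    def __post_init__(self) -> None:
        if self.n_records < len(set(self.cells)):
            raise ValueError("record count below distinct presence-cell count")


def read_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Parse an occurrence CSV (species, lon, lat, date, source).

    Malformed rows (unparseable coordinates/dates, unknown source flag) are
    skipped and counted in a log message; missing columns are a hard error.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["species", "lon", "lat", "date", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file {path} lacks required columns: {missing}")
    records: list[OccurrenceRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            lon, lat = float(row.lon), float(row.lat)
            if not (np.isfinite(lon) and np.isfinite(lat)):
                raise ValueError
            date = datetime.date.fromisoformat(str(row.date))
            source = str(row.source).strip().lower()
            if source not in SOURCES or not str(row.species).strip():
                raise ValueError
        except (ValueError, TypeError):
            skipped += 1
            continue
        records.append(OccurrenceRecord(str(row.species).strip(), lon, lat, date, source))
    if skipped:
        logger.warning("skipped %d malformed rows while reading %s", skipped, path)
    return records


def write_occurrences(path: str | Path, records: Iterable[OccurrenceRecord]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "lon", "lat", "date", "source"])
        for rec in records:
            writer.writerow([rec.species, repr(rec.lon), repr(rec.lat), rec.date.isoformat(), rec.source])


def filter_sources(records: Sequence[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Remove systematic-survey (bbs) and ringing-station records."""
    kept = [r for r in records if r.source not in SURVEY_SOURCES]
    logger.info("source filter: %d -> %d records", len(records), len(kept))
    return kept


def _in_window(date: datetime.date, window: tuple[tuple[int, int], tuple[int, int]]) -> bool:
    """Whether (month, day) falls in an inclusive window, wrapping the year."""
    md = (date.month, date.day)
    start, end = window
    if start <= end:
        return start <= md <= end
    return md >= start or md <= end


def filter_season(
    records: Sequence[OccurrenceRecord], groups: Mapping[str, str]
) -> list[OccurrenceRecord]:
    """Apply the seasonal windows per species group.

    Migratory species keep only breeding-season dates; resident species drop
    the winter window. A species absent from ``groups`` is an error.
    """
    kept = []
    for rec in records:
        group = groups.get(rec.species)
        if group is None:
            raise KeyError(f"species {rec.species!r} has no resident/migratory assignment")
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r} for species {rec.species!r}")
        if group == "migratory":
            if _in_window(rec.date, BREEDING_WINDOW):
                kept.append(rec)
        else:
            if not _in_window(rec.date, WINTER_WINDOW):
                kept.append(rec)
    logger.info("season filter: %d -> %d records", len(records), len(kept))
    return kept


def filter_min_records(
    records: Sequence[OccurrenceRecord], minimum: int = MIN_RECORDS
) -> dict[str, list[OccurrenceRecord]]:
    """Keep species with strictly more than ``minimum`` records.

    Returns a species -> records mapping; dropped species are logged.
    """
    by_species: dict[str, list[OccurrenceRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)
    dropped = sorted(s for s, recs in by_species.items() if len(recs) <= minimum)
    if dropped:
        logger.info("min-records filter dropped %d species: %s", len(dropped), dropped)
    return {s: recs for s, recs in by_species.items() if len(recs) > minimum}


def rasterize_presences(
    records: Sequence[OccurrenceRecord],
    spec: GridSpec,
    thin_to_cell: bool = True,
    valid_mask: np.ndarray | None = None,
) -> PresenceSet:
    """Map one species' records to grid cells.

    Records outside the grid (or on cells masked out by ``valid_mask``) are
    dropped and counted. With ``thin_to_cell`` (the default, standard
    duplicate handling for grid-based presence-only models) repeated hits on
    a cell collapse to a single presence cell; order of first appearance is
    preserved either way.
    """
    species = {r.species for r in records}
    if len(species) > 1:
        raise ValueError(f"records span multiple species: {sorted(species)}")
    cells: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    n_outside = 0
    for rec in records:
        cell = spec.cell_of(rec.lon, rec.lat)
        if cell is None or (valid_mask is not None and not valid_mask[cell]):
            n_outside += 1
            continue
        if thin_to_cell:
            if cell not in seen:
                seen.add(cell)
                cells.append(cell)
        else:
            cells.append(cell)
    name = species.pop() if species else ""
    return PresenceSet(name, cells, n_records=len(records) - n_outside, n_outside=n_outside)


def coverage_fraction(
    records: Sequence[OccurrenceRecord],
    lon_min: float,
    lon_max: float,
    lat_min: float,
    lat_max: float,
    block: float = 1.0,
) -> float:
    """Fraction of ``block``-degree blocks of the study box holding a record.

    A measurable proxy for "records spread evenly across the study area";
    reported, not enforced, by the pipeline.
    """
    n_lon = max(1, int(np.ceil((lon_max - lon_min) / block)))
    n_lat = max(1, int(np.ceil((lat_max - lat_min) / block)))
    occupied = {
        (int((r.lon - lon_min) // block), int((r.lat - lat_min) // block))
        for r in records
        if lon_min <= r.lon < lon_max and lat_min <= r.lat < lat_max
    }
    return len(occupied) / (n_lon * n_lat)


def species_counts(records: Sequence[OccurrenceRecord]) -> Counter:
    return Counter(r.species for r in records)
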