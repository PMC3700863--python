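"""Configuration-driven orchestration of the full modelling chain.

One run goes: occurrence cleaning -> bioclim derivation and masking ->
correlation-based variable selection (per group) -> per-species
maximum-entropy fit with train/test AUC -> logistic projection to every
scenario x period -> 10-percentile binarization -> richness, gain/loss,
overlap/centroid/turnover tables -> JSON manifest with checksums.

A master seed spawns independent per-species child streams (background
sampling and the train/test split), recorded in the manifest, so reruns are
bit-reproducible and species do not share randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from rangeshift import bioclim as bc
from rangeshift import change_metrics as cm
from rangeshift import maxent as mx
from rangeshift import postprocess as pp
from rangeshift import records as rec
from rangeshift import varselect as vs
from rangeshift.climate import ClimateStack
from rangeshift.grid import GridSpec, write_ascii_grid

logger = logging.getLogger(__name__)

PERIODS = ("2020", "2050", "2080")
SCENARIOS = ("A2a", "B2a")


@dataclass
class MaxentSettings:
    beta: float = 1.0
    max_iter: int = 1000
    tol: float = 5e-5
    background: int = 10_000
    test_fraction: float = 0.25
    knots: int = 10


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    grid: GridSpec
    occurrences: Path
    climate_current: Path
    climate_future: dict[tuple[str, str], Path]  # (scenario, period) -> dir
    groups: dict[str, str]
    out_dir: Path
    mask_box: tuple[float, float, float, float] | None = None  # lon_min, lon_max, lat_min, lat_max
    min_records: int = rec.MIN_RECORDS
    thin_to_cell: bool = True
    correlation_threshold: float = vs.CORRELATION_THRESHOLD
    priority: tuple[str, ...] | None = None
    maxent: MaxentSettings = field(default_factory=MaxentSettings)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        g = raw["grid"]
        grid = GridSpec.from_bounds(g["lon_min"], g["lon_max"], g["lat_min"], g["lat_max"], g["cell_size"])
        future = {
            (scenario, str(period)): base / p
            for scenario, periods in raw["climate"]["future"].items()
            for period, p in periods.items()
        }
        mask_box = tuple(raw["mask_box"]) if "mask_box" in raw else None
        settings = MaxentSettings(**raw.get("maxent", {}))
        return cls(
            grid=grid,
            occurrences=base / raw["occurrences"],
            climate_current=base / raw["climate"]["current"],
            climate_future=future,
            groups=dict(raw["groups"]),
            out_dir=base / raw.get("out_dir", "outputs"),
            mask_box=mask_box,
            min_records=raw.get("min_records", rec.MIN_RECORDS),
            thin_to_cell=raw.get("thin_to_cell", True),
            correlation_threshold=raw.get("correlation_threshold", vs.CORRELATION_THRESHOLD),
            priority=tuple(raw["priority"]) if "priority" in raw else None,
            maxent=settings,
            seed=int(raw.get("seed", 0)),
        )


def summarize_records(
    counts: Mapping[str, int], groups: Mapping[str, str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-species record counts and per-group totals.

    Mirrors the usual presentation of a cleaned occurrence dataset: one row
    per species with its retained record count, plus resident/migratory
    totals and a grand total.
    """
    rows = [
        {"species": s, "group": groups.get(s, "unassigned"), "n_records": int(n)}
        for s, n in counts.items()
    ]
    table = pd.DataFrame(rows, columns=["species", "group", "n_records"])
    totals = {g: int(table.loc[table["group"] == g, "n_records"].sum()) for g in sorted(set(table["group"]))} if len(table) else {}
    totals["total"] = int(table["n_records"].sum()) if len(table) else 0
    return table, totals


def _load_bioclim(climate_dir: Path, grid: GridSpec, mask_box) -> bc.BioclimStack:
    stack = ClimateStack.read(climate_dir)
    if stack.grid != grid:
        raise ValueError(f"climate in {climate_dir} is not on the configured grid")
    derived = bc.derive_bioclim(stack)
    if mask_box is not None:
        lon_min, lon_max, lat_min, lat_max = mask_box
        derived = bc.mask_to_box(derived, lon_min, lon_max, lat_min, lat_max)
    return derived


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain; returns the output manifest (also written).

    Any stage failure raises with the species and stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.grid

    # --- climate -> bioclim for every period/scenario ---
    bioclim_by_key: dict[str, bc.BioclimStack] = {
        "current": _load_bioclim(config.climate_current, grid, config.mask_box)
    }
    for (scenario, period), path in config.climate_future.items():
        bioclim_by_key[f"{scenario}:{period}"] = _load_bioclim(path, grid, config.mask_box)
    current = bioclim_by_key["current"]

    # --- occurrence cleaning ---
    raw_records = rec.read_occurrences(config.occurrences)
    cleaned = rec.filter_season(rec.filter_sources(raw_records), config.groups)
    by_species = rec.filter_min_records(cleaned, config.min_records)
    counts = {s: len(r) for s, r in by_species.items()}
    summary_table, totals = summarize_records(counts, config.groups)
    summary_table.to_csv(out / "record_summary.csv", index=False)

    # --- variable selection (current period) ---
    matrix = vs.pearson_matrix(current)
    matrix.to_csv(out / "correlation_matrix.csv")
    resident_sel = vs.eliminate_correlated(
        matrix, config.correlation_threshold, config.priority
    )
    migrant_sel = vs.migrant_substitution(resident_sel)
    selections = {"resident": resident_sel, "migratory": migrant_sel}
    (out / "variable_selection.json").write_text(
        json.dumps({g: s.variables for g, s in selections.items()}, indent=2)
    )

    # --- per-species modelling ---
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(by_species))
    species_order = sorted(by_species)
    model_rows = []
    binaries: dict[tuple[str, str, str], pp.BinaryMap] = {}  # (species, scenario, period)
    seeds_used = {}
    for child, species in zip(children, species_order):
        stage = "presences"
        try:
            group = config.groups[species]
            presences = rec.rasterize_presences(
                by_species[species], grid, config.thin_to_cell, valid_mask=current.valid_mask
            )
            cells = np.asarray(presences.cells)
            rng = np.random.default_rng(child)
            seed_bg, seed_split = (int(s) for s in rng.integers(0, 2**31, size=2))
            seeds_used[species] = {"background": seed_bg, "split": seed_split}

            stage = "features"
            background = mx.sample_background(current, config.maxent.background, seed_bg)
            train, test = mx.split_train_test(cells, config.maxent.test_fraction, seed_split)
            features = mx.build_features(
                current, selections[group], background,
                n_presences=len(train), knots=config.maxent.knots,
            )

            stage = "fit"
            model = mx.fit(
                features, train, background,
                beta=config.maxent.beta, max_iter=config.maxent.max_iter, tol=config.maxent.tol,
            )
            (out / "models").mkdir(exist_ok=True)
            (out / "models" / f"{species}.json").write_text(json.dumps(model.to_dict(), indent=2))

            stage = "evaluation"
            back_scores = features.matrix(background) @ model.lam
            auc_train = mx.auc(features.matrix(train) @ model.lam, back_scores)
            auc_test = (
                mx.auc(features.matrix(test) @ model.lam, back_scores) if len(test) else np.nan
            )

            stage = "projection"
            suit_current = mx.logistic_output(model)
            train_values = suit_current[train[:, 0], train[:, 1]]
            threshold = pp.ten_percentile_threshold(train_values)
            model_rows.append(
                {
                    "species": species, "group": group,
                    "n_presence_cells": len(cells), "n_train": len(train), "n_test": len(test),
                    "auc_train": auc_train, "auc_test": auc_test,
                    "threshold": threshold, "converged": model.converged,
                }
            )
            maps = {"current": suit_current}
            for key, stack in bioclim_by_key.items():
                if key != "current":
                    maps[key] = mx.logistic_output(model, stack)
            for key, suit in maps.items():
                scenario, _, period = key.partition(":")
                if not period:
                    scenario, period = "", "current"
                bmap = pp.binarize(suit, threshold, grid, species, period, scenario)
                binaries[(species, scenario, period)] = bmap
                write_ascii_grid(
                    out / "suitability" / f"{species}_{key.replace(':', '_')}.asc", grid, suit
                )
                write_ascii_grid(
                    out / "binary" / f"{species}_{key.replace(':', '_')}.asc", grid, bmap.data
                )
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"pipeline failed for species {species!r} at stage {stage}") from exc

    models_table = pd.DataFrame(model_rows)
    models_table.to_csv(out / "model_summary.csv", index=False)

    # --- richness and change per group/scenario ---
    groups_present = sorted({config.groups[s] for s in species_order})
    change_rows = []
    turnover_summaries = {}
    for group in groups_present:
        members = [s for s in species_order if config.groups[s] == group]
        rich_current = pp.stack_richness([binaries[(s, "", "current")] for s in members])
        write_ascii_grid(out / "richness" / f"{group}_current.asc", grid, rich_current.data)
        for scenario in sorted({sc for sc, _ in config.climate_future}):
            periods = sorted({p for sc, p in config.climate_future if sc == scenario})
            for period in periods:
                rich = pp.stack_richness([binaries[(s, scenario, period)] for s in members])
                write_ascii_grid(out / "richness" / f"{group}_{scenario}_{period}.asc", grid, rich.data)
                change = pp.richness_change(rich_current, rich)
                write_ascii_grid(out / "richness" / f"{group}_{scenario}_{period}_change.asc", grid, change)
                for s in members:
                    r = cm.range_change(binaries[(s, "", "current")], binaries[(s, scenario, period)])
                    change_rows.append(
                        {
                            "species": s, "group": group, "scenario": scenario,
                            "period": period,
                            "overlap_percent": r.overlap_percent,
                            "area_change_percent": r.area_change_percent,
                            "centroid_lon_current": r.centroid_from[0],
                            "centroid_lat_current": r.centroid_from[1],
                            "centroid_lon_future": r.centroid_to[0],
                            "centroid_lat_future": r.centroid_to[1],
                            "displacement_km": r.displacement_km,
                        }
                    )
            timelines = {
                s: [binaries[(s, "", "current")]] + [binaries[(s, scenario, p)] for p in periods]
                for s in members
            }
            table, summary = cm.turnover_table(timelines)
            table.to_csv(out / f"turnover_{group}_{scenario}.csv")
            turnover_summaries[f"{group}:{scenario}"] = summary

    pd.DataFrame(change_rows).to_csv(out / "range_change.csv", index=False)

    # --- manifest ---
    artifacts = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "child_seeds": seeds_used,
        "grid": {
            "lon_min": grid.lon_min, "lat_min": grid.lat_min,
            "cell_size": grid.cell_size, "n_rows": grid.n_rows, "n_cols": grid.n_cols,
        },
        "record_totals": totals,
        "species": species_order,
        "selections": {g: s.variables for g, s in selections.items()},
        "turnover": turnover_summaries,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
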