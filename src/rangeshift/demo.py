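"""A self-contained synthetic study system for the full pipeline.

Emulates, at desk scale, the shape of a national songbird range-shift study:
a 0.25-degree grid over western Anatolia (26-33.5 E, 36-41 N, 20 x 30
cells), a "current" monthly climate plus two emission scenarios (a stronger
A2a and a milder B2a) at three horizons (2020/2050/2080), and four species
with known climatic optima:

* ``northern_warbler`` (resident) — cool optimum; its suitable band sits in
  the north and is the designated probe for northward displacement under
  warming;
* ``steppe_lark`` (resident) — warm, dry optimum in the south;
* ``masked_shrike`` (migratory) — intermediate optimum, records only in
  spring-summer;
* ``rare_bunting`` (resident) — deliberately too few records, so the
  minimum-record rule removes it.

Records mix casual, survey (bbs) and ringing sources and spread dates beyond
the seasonal windows, so every cleaning rule has work to do. Observer bias
concentrates records around two "popular sites".
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import yaml

from rangeshift.bioclim import derive_bioclim
from rangeshift.grid import GridSpec
from rangeshift.records import write_occurrences
from rangeshift.synth import TruthModel, make_climate, perturb_climate, sample_occurrences

DEMO_GRID = GridSpec.from_bounds(26.0, 33.5, 36.0, 41.0, 0.25)

#: (delta_t in deg C, precipitation factor) per scenario and horizon.
SCENARIO_DELTAS: dict[str, dict[str, tuple[float, float]]] = {
    "A2a": {"2020": (1.2, 0.95), "2050": (2.4, 0.90), "2080": (3.6, 0.85)},
    "B2a": {"2020": (0.9, 0.97), "2050": (1.8, 0.94), "2080": (2.7, 0.91)},
}

#: Ground-truth suitability per species (on standardized bioclim layers).
#: quadratic -a*(z - z0)^2 is written as linear 2*a*z0 plus quadratic -a.
TRUTHS: dict[str, TruthModel] = {
    "northern_warbler": TruthModel(linear={"BIO1": 2 * 1.5 * -0.8}, quadratic={"BIO1": -1.5}),
    "steppe_lark": TruthModel(
        linear={"BIO1": 2 * 1.2 * 0.8, "BIO12": -0.6}, quadratic={"BIO1": -1.2}
    ),
    "masked_shrike": TruthModel(
        linear={"BIO1": 2 * 1.0 * 0.3, "BIO12": 0.4}, quadratic={"BIO1": -1.0}
    ),
    "rare_bunting": TruthModel(linear={"BIO12": 0.5}),
}

GROUPS = {
    "northern_warbler": "resident",
    "steppe_lark": "resident",
    "masked_shrike": "migratory",
    "rare_bunting": "resident",
}

#: Casual/bbs/ringing record counts drawn per species (before cleaning).
SAMPLE_SIZES = {
    "northern_warbler": (260, 25, 12),
    "steppe_lark": (300, 30, 15),
    "masked_shrike": (200, 18, 8),
    "rare_bunting": (20, 3, 2),
}

RESIDENT_WINDOW = (datetime.date(2005, 1, 1), datetime.date(2005, 12, 31))
MIGRANT_WINDOW = (datetime.date(2005, 3, 15), datetime.date(2005, 9, 15))
BIAS_CENTERS = [(4, 5), (15, 24)]


def make_demo_inputs(out_dir: str | Path, seed: int = 0) -> Path:
    """Write climate grids, occurrences and a config; returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    current = make_climate(DEMO_GRID, seed=int(rng.integers(2**31)))
    current.write(out / "climate" / "current")
    future_paths: dict[str, dict[str, str]] = {}
    for scenario, horizons in SCENARIO_DELTAS.items():
        future_paths[scenario] = {}
        for period, (delta_t, pfac) in horizons.items():
            stack = perturb_climate(current, delta_t, pfac)
            rel = f"climate/{scenario}_{period}"
            stack.write(out / rel)
            future_paths[scenario][period] = rel

    bioclim = derive_bioclim(current)
    all_records = []
    for species, truth in TRUTHS.items():
        window = MIGRANT_WINDOW if GROUPS[species] == "migratory" else RESIDENT_WINDOW
        n_casual, n_bbs, n_ring = SAMPLE_SIZES[species]
        for n, source in ((n_casual, "casual"), (n_bbs, "bbs"), (n_ring, "ringing")):
            all_records.extend(
                sample_occurrences(
                    truth, bioclim, n, seed=int(rng.integers(2**31)), species=species,
                    bias_centers=BIAS_CENTERS, bias_strength=1.0,
                    date_window=window, source=source,
                )
            )
    write_occurrences(out / "occurrences.csv", all_records)

    config = {
        "grid": {
            "lon_min": DEMO_GRID.lon_min, "lon_max": DEMO_GRID.lon_max,
            "lat_min": DEMO_GRID.lat_min, "lat_max": DEMO_GRID.lat_max,
            "cell_size": DEMO_GRID.cell_size,
        },
        "occurrences": "occurrences.csv",
        "climate": {"current": "climate/current", "future": future_paths},
        "groups": GROUPS,
        "out_dir": "outputs",
        "seed": int(seed),
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
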