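"""Generate the synthetic study system: climate grids and occurrence records.

Writes a 20 x 30-cell (0.25 degree) study region with a current monthly
climate, two warming scenarios (A2a stronger, B2a milder) at three horizons,
and occurrence records for four species with known climatic optima —
including survey/ringing records and out-of-season dates for the cleaning
stage to remove, and one species too rare to model.
"""

from collections import Counter
from pathlib import Path

from rangeshift.demo import SCENARIO_DELTAS, make_demo_inputs
from rangeshift.records import read_occurrences

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "results" / "study"
SEED = 0


def main() -> None:
    config_path = make_demo_inputs(STUDY, seed=SEED)
    records = read_occurrences(STUDY / "occurrences.csv")
    print(f"wrote study inputs under {STUDY} (config: {config_path})")
    print(f"scenarios: {[f'{s} {p}' for s in SCENARIO_DELTAS for p in SCENARIO_DELTAS[s]]}")
    print(f"\nraw records: {len(records)}")
    by = Counter((r.species, r.source) for r in records)
    for species in sorted({r.species for r in records}):
        counts = {src: by.get((species, src), 0) for src in ("casual", "bbs", "ringing")}
        print(f"  {species:18s} {counts}")


if __name__ == "__main__":
    main()
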