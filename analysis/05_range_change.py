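"""Summarize projected range changes: overlap, displacement and turnover.

Reads the pipeline outputs and reports, per scenario, the median range-size
change of each group, every species' centroid displacement by 2080, and the
share of currently occupied cells expected to keep the same species across
all timelines.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "study" / "outputs"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    rc = pd.read_csv(OUT / "range_change.csv")
    manifest = json.loads((OUT / "manifest.json").read_text())

    print("median range-size change (%) by group, scenario and horizon:")
    medians = rc.groupby(["group", "scenario", "period"])["area_change_percent"].median()
    print(medians.unstack("period").round(1).to_string())

    end = rc[rc.period == 2080].copy()
    end["direction"] = (end.centroid_lat_future > end.centroid_lat_current).map(
        {True: "north", False: "south"}
    )
    print("\ncentroid displacement by 2080 (km):")
    cols = ["species", "scenario", "displacement_km", "direction", "overlap_percent"]
    print(end[cols].sort_values(["species", "scenario"]).round(1).to_string(index=False))

    print("\nshare of current cells keeping the same species across all timelines (%):")
    rows = []
    for key, summary in manifest["turnover"].items():
        group, scenario = key.split(":")
        rows.append(
            {
                "group": group, "scenario": scenario,
                "all_timeline_mean": round(summary["mean"]["all_timeline_percent"], 1),
                "all_timeline_sd": round(summary["sd"]["all_timeline_percent"], 1),
                "n_species": summary["n_species"],
            }
        )
    turnover = pd.DataFrame(rows)
    TABLES.mkdir(parents=True, exist_ok=True)
    turnover.to_csv(TABLES / "turnover_summary.csv", index=False)
    print(turnover.to_string(index=False))


if __name__ == "__main__":
    main()
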