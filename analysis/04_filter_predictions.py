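"""Mask the probability rasters and apply the area and elevation filters.

Per region: zero out pixels outside broadleaved stands, rank the rest by
probability, then (i) accumulate ranked pixels up to the regional
stocked-oak area and (ii) fill each 10 m elevation class up to the survey
histogram quota. Also computes the manual-adjustment diagnostic and the
Kolmogorov-Smirnov comparison of the two selections' probability values.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, make_config

from oakmap.pipeline import run_stage

cfg = make_config()
state = run_stage("filter", cfg)

report = state["selection_report"]
rows = []
for region, info in sorted(report["regions"].items(), key=lambda kv: int(kv[0])):
    rows.append(
        {
            "region": int(region),
            "target_area_ha": info["target_area_ha"],
            "area_filter_min_prob": info["area_filter"]["min_selected_probability"],
            "elev_filter_min_prob": info["elevation_filter"]["min_selected_probability"],
            "elev_shortfall_classes": info["elevation_filter"]["n_shortfall_classes"],
            "manual_adjust_mean_diff": info["manual_adjustment_mean_difference"],
        }
    )
summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "filter_summary.csv", index=False)
print(summary.round(4).to_string(index=False))

ks = report["ks"]
print(f"\nKS comparison of the two selections: D = {ks['D']:.3f}, p = {ks['p_value']:.3g}.")
print(
    "Forcing pixels into the surveyed elevation distribution admits a "
    "low-probability tail the area-only filter never reaches — the lowest "
    "selected probabilities drop by an order of magnitude — which is the "
    "signature of the filter correcting the suitability ranking toward "
    "where managed oak woodland actually sits."
)
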