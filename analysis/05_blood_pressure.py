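#!/usr/bin/env python
"""Descriptive summary of the five-group blood-pressure time courses.

Summarizes the packaged antihypertensive study table: minimum mean BP
and its time, maximum drop from the pre-dose value, and contiguous
hours below 140 mmHg, per treatment group.  Finding: the oil-entrapped
bead group reaches its nadir of 88 mmHg at 7 h and stays below
threshold for most of the 12-h window, while the pure-drug group's
effect peaks at 2 h and wears off — the sustained-release formulation
trades peak speed for duration.
"""

from pathlib import Path

import pandas as pd

from beadopt import datasets
from beadopt.pk import bp_summary

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

table = datasets.load_bp_timecourse()
rows = []
for group in table["group"].unique():
    s = bp_summary(datasets.bp_series(group, table), threshold=140.0)
    rows.append(
        {
            "group": group,
            "min_bp_mmhg": s.min_bp,
            "time_of_min_h": s.time_of_min,
            "max_drop_vs_initial_mmhg": s.max_drop_vs_initial,
            "hours_below_140": s.duration_below_threshold,
        }
    )
    print(
        f"{group}: nadir {s.min_bp:g} mmHg at {s.time_of_min:g} h, "
        f"drop {s.max_drop_vs_initial:g} mmHg, "
        f"{s.duration_below_threshold:g} h below 140 mmHg"
    )

pd.DataFrame(rows).to_csv(OUT / "bp_summary.csv", index=False)
print(f"wrote {OUT/'bp_summary.csv'}")
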