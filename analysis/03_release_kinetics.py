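#!/usr/bin/env python
"""Dissolution-kinetics battery on synthetic optimized-bead profiles.

The raw release curves behind the study's kinetic table exist only as
figures, so this script generates 12-h profiles from the package's
calibrated presets (the reported Korsmeyer-Peppas exponents, Km set to
reach the reported 12-h cumulative release) at 2% multiplicative noise,
fits all five release laws to each, and classifies the mechanism from
the power-law exponent.  Finding: the power law ranks first on its own
data and the fitted exponents recover the generating values (0.836 oil
beads, 0.7297 oil-free beads), both classifying as anomalous transport
under the exponent rule.  (Both presets are calibrated to the same 12-h
endpoint, so their release AUCs are similar by construction; the
study's large AUC gap between formulations reflects curve shapes that
were published only as figures.)
"""

from pathlib import Path

import pandas as pd

from beadopt import datasets
from beadopt.kinetics import classify_release_mechanism, dissolution_auc, select_best_model
from beadopt.synthetic import gen_dissolution

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for idx, (preset_name, preset) in enumerate(datasets.DISSOLUTION_PRESETS.items()):
    prof, _ = gen_dissolution(
        preset["model"],
        preset["params"],
        datasets.DISSOLUTION_SCHEDULE,
        cv_pct=2.0,
        seed=100 + idx,
        formulation_id=preset_name,
    )
    fits, excluded = select_best_model(prof)
    auc = dissolution_auc(prof)
    kp = next(f for f in fits if f.model == "korsmeyer_peppas")
    mech = classify_release_mechanism(kp.n)
    print(
        f"{preset_name}: best model {fits[0].model} (R^2 = {fits[0].R2:.4f}); "
        f"n = {kp.n:.3f} -> {mech}; release AUC = {auc:.1f} %.h"
    )
    for rank, f in enumerate(fits, 1):
        rows.append(
            {
                "formulation": preset_name,
                "rank": rank,
                "model": f.model,
                "K": f.K,
                "n": f.n,
                "R2": f.R2,
                "mechanism": mech if f.model == "korsmeyer_peppas" else None,
                "dissolution_auc": auc,
            }
        )

pd.DataFrame(rows).round(6).to_csv(OUT / "release_kinetics.csv", index=False)
print(f"wrote {OUT/'release_kinetics.csv'}")
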