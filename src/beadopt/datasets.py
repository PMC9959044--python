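"""Packaged study data for the telmisartan floating-bead formulation.

This module carries the published experimental record of the study the
pipeline reproduces: the three-factor central-composite design with its
measured responses, the reported quadratic-surface coefficients (used as
ground truth by the synthetic generators), the located optimum, the
group-mean pharmacokinetic summary, and the blood-pressure time
courses.  Everything here is an *input* to the pipeline; nothing is a
computed result.

Factors (all percent w/v): X1 sodium alginate 2-6%, X2 calcium chloride
cross-linker 5-15%, X3 sesame oil 4-8%.  Responses: Y1 entrapment
efficiency (%), Y2 in vitro buoyancy duration (h), Y3 cumulative release
at 6 h (%).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .doe import FactorSpec
from .pk import BPTimeSeries

__all__ = [
    "FACTORS",
    "RESPONSE_NAMES",
    "REFERENCE_COEFFICIENTS",
    "REFERENCE_CV_PCT",
    "OPTIMUM_ACTUAL",
    "PK_GROUP_SUMMARY",
    "PLASMA_PRESETS",
    "DISSOLUTION_PRESETS",
    "SWELLING_RATIOS",
    "load_design",
    "load_bp_timecourse",
    "bp_series",
]

#: The three formulation factors with their coded -1/+1 actual levels.
FACTORS = [
    FactorSpec("alginate_pct", "% w/v", 2.0, 6.0),
    FactorSpec("cacl2_pct", "% w/v", 5.0, 15.0),
    FactorSpec("oil_pct", "% w/v", 4.0, 8.0),
]

RESPONSE_NAMES = ("y1_ee_pct", "y2_buoyancy_h", "y3_q6h_pct")

#: Reported quadratic-surface coefficients in coded units, used as the
#: default "truth" by the synthetic CCD-response generator.
REFERENCE_COEFFICIENTS = {
    "y1_ee_pct": {
        "b0": 90.0032, "b1": 11.3928, "b2": 1.7407, "b3": 10.0215,
        "b12": 4.25, "b13": -1.0, "b23": 0.25,
        "b11": -6.90525, "b22": -10.7943, "b33": -4.78393,
    },
    "y2_buoyancy_h": {
        "b0": 8.99569, "b1": 0.909626, "b2": 0.0282884, "b3": 2.7808,
        "b12": -0.1, "b13": 0.625, "b23": 0.625,
        "b11": -1.34635, "b22": -0.745306, "b33": -0.780662,
    },
    "y3_q6h_pct": {
        "b0": 69.0418, "b1": -0.935248, "b2": -13.8458, "b3": 0.65901,
        "b12": 3.875, "b13": -0.375, "b23": 2.125,
        "b11": -6.33132, "b22": -6.86165, "b33": -7.2152,
    },
}

#: Reported run-to-run coefficient of variation per response (%),
#: the realistic noise scale for the synthetic generator.
REFERENCE_CV_PCT = {"y1_ee_pct": 2.40, "y2_buoyancy_h": 7.20, "y3_q6h_pct": 3.82}

#: Located optimum of the desirability optimization (actual units, %).
OPTIMUM_ACTUAL = np.array([4.56, 8.72, 7.68])

#: Reported group-mean PK summary (n = 6 rats per group, 1 mg/kg oral).
#: AUC in ug*h/mL, Kel in 1/h, Cmax in ug/mL, Tmax and MRT in h.
PK_GROUP_SUMMARY = pd.DataFrame(
    {
        "group": ["pure_tel", "op1_beads", "op2_beads"],
        "dose_mg_kg": [1.0, 1.0, 1.0],
        "cmax_ug_ml": [1.16, 1.13, 1.06],
        "tmax_h": [3.0, 5.0, 5.0],
        "auc_0_inf": [5.615, 12.495, 8.25],
        "kel_per_h": [0.114, 0.0585, 0.093],
    }
).set_index("group")

#: Bateman-curve presets emulating the three PK groups: ke matches the
#: reported elimination rate, ka is solved so the analytic Tmax matches
#: the reported Tmax, and dose_scale so the peak matches the reported
#: Cmax.  (Individual-animal profiles were never published; these are
#: synthetic stand-ins with the reported summary statistics.)
PLASMA_PRESETS = {
    "pure_tel_like": {"ka": 0.74, "ke": 0.114, "dose_scale": 1.631},
    "op1_like": {"ka": 0.48, "ke": 0.0585, "dose_scale": 1.513},
    "op2_like": {"ka": 0.37, "ke": 0.093, "dose_scale": 1.685},
}

#: Reported sampling schedule for the rat PK study (hours post dose).
PLASMA_SCHEDULE = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 10.0, 12.0, 20.0, 24.0])

#: Dissolution sampling schedule (hours).
DISSOLUTION_SCHEDULE = np.arange(1.0, 13.0)

#: Release-law presets emulating the two optimized formulations: the
#: reported Korsmeyer-Peppas exponents n, with Km (fraction basis,
#: h^-n) calibrated so the power law reaches the reported 12-h
#: cumulative release (92.68% and 91.88%).  The reported kinetic
#: constants themselves are not mutually consistent with the observed
#: release magnitudes, so they cannot serve as generator truth directly.
DISSOLUTION_PRESETS = {
    "op1_like": {
        "model": "korsmeyer_peppas",
        "params": {"Km": 0.9268 / 12.0**0.836, "n": 0.836},
    },
    "op2_like": {
        "model": "korsmeyer_peppas",
        "params": {"Km": 0.9188 / 12.0**0.7297, "n": 0.7297},
    },
}

#: Reported swelling ratios (wet/dry weight) of the optimized beads at
#: 1..6 h in simulated gastric fluid.
SWELLING_RATIOS = pd.DataFrame(
    {
        "time_h": [1, 2, 3, 4, 5, 6],
        "op1_beads": [1.62, 1.58, 1.53, 1.49, 1.47, 1.41],
        "op2_beads": [1.76, 1.68, 1.64, 1.59, 1.55, 1.52],
    }
).set_index("time_h")


def _data_path(name: str):
    return resources.files("beadopt").joinpath("data", name)


def load_design():
    """The packaged 17-run CCD with its measured responses.

    Returns a validated :class:`beadopt.doe.DesignTable` (8 factorial +
    6 axial + 3 center runs, axial magnitude 8^(1/4)).
    """
    from .io import read_design_csv

    with resources.as_file(_data_path("ccd_design.csv")) as path:
        return read_design_csv(path, FACTORS)


def load_bp_timecourse() -> pd.DataFrame:
    """Blood-pressure time courses of the five pharmacodynamic groups.

    Long-format frame: group, time_label ('initial' for the pre-dose
    row), time_h, bp_mean_mmhg, bp_sd_mmhg.
    """
    with resources.as_file(_data_path("bp_timecourse.csv")) as path:
        return pd.read_csv(path)


def bp_series(group: str, table: pd.DataFrame | None = None) -> BPTimeSeries:
    """One group's BP course as a :class:`beadopt.pk.BPTimeSeries`."""
    if table is None:
        table = load_bp_timecourse()
    sub = table[table["group"] == group].sort_values("time_h")
    if sub.empty:
        raise KeyError(
            f"group {group!r} not in table; have {sorted(table['group'].unique())}"
        )
    return BPTimeSeries(
        times=sub["time_h"].to_numpy(float),
        mean_bp=sub["bp_mean_mmhg"].to_numpy(float),
        sd_bp=sub["bp_sd_mmhg"].to_numpy(float),
        group=group,
    )
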