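"""CSV readers and writers for the pipeline's interchange schemas.

CSV is the single interchange format: UTF-8, mandatory header row,
``.`` decimal separator.  Schemas:

* design: ``std_order, run_order, x1_coded..xk_coded,
  <factor actual columns>, <response columns>``
* dissolution profiles: ``formulation_id, time_h, release_pct``
* plasma: ``subject_id, group, time_h, conc_ug_ml``
* blood pressure: ``group, time_label, time_h, bp_mean_mmhg, bp_sd_mmhg``
  (pre-dose row has ``time_h = 0`` and label ``initial``)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .doe import DesignTable, FactorSpec
from .kinetics import DissolutionProfile
from .pk import PlasmaProfile

__all__ = [
    "read_design_csv",
    "write_design_csv",
    "read_dissolution_csv",
    "write_dissolution_csv",
    "read_plasma_csv",
]

#: tolerance for the coded/actual cross-check when reading designs
CODED_ACTUAL_TOL = 1e-6


def read_design_csv(
    path, factors: list[FactorSpec], expected_runs: int | None = None
) -> DesignTable:
    """Read and validate a design CSV against its factor specs.

    Every row's actual levels are cross-checked against its coded levels
    (``actual = center + coded * half_range`` within 1e-6); columns not
    part of the design schema are taken as responses.

    Raises
    ------
    ValueError
        On missing columns, a coded/actual mismatch, or a run count that
        contradicts ``expected_runs``.
    """
    df = pd.read_csv(path)
    k = len(factors)
    coded_cols = [f"x{j + 1}_coded" for j in range(k)]
    actual_cols = [f.name for f in factors]
    required = ["std_order", "run_order"] + coded_cols + actual_cols
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"design CSV missing columns: {missing}")
    if expected_runs is not None and len(df) != expected_runs:
        raise ValueError(f"expected {expected_runs} runs, file has {len(df)}")

    coded = df[coded_cols].to_numpy(float)
    actual = df[actual_cols].to_numpy(float)
    center = np.array([f.center for f in factors])
    half = np.array([f.half_range for f in factors])
    mismatch = np.abs(actual - (center + coded * half))
    if mismatch.max() > CODED_ACTUAL_TOL:
        i, j = np.unravel_index(np.argmax(mismatch), mismatch.shape)
        raise ValueError(
            f"coded/actual mismatch at row {i}, factor {factors[j].name!r}: "
            f"|delta| = {mismatch[i, j]:.3g} > {CODED_ACTUAL_TOL}"
        )

    responses = {
        c: df[c].to_numpy(float) for c in df.columns if c not in required
    }
    return DesignTable(
        factors=list(factors),
        coded=coded,
        std_order=df["std_order"].to_numpy(int),
        run_order=df["run_order"].to_numpy(int),
        responses=responses,
    )


def write_design_csv(design: DesignTable, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_dissolution_csv(path) -> dict[str, DissolutionProfile]:
    """Read profiles keyed by formulation_id."""
    df = pd.read_csv(path)
    required = {"formulation_id", "time_h", "release_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"dissolution CSV needs columns {sorted(required)}")
    out = {}
    for fid, sub in df.groupby("formulation_id", sort=False):
        sub = sub.sort_values("time_h")
        out[str(fid)] = DissolutionProfile(
            sub["time_h"].to_numpy(float),
            sub["release_pct"].to_numpy(float),
            formulation_id=str(fid),
        )
    return out


def write_dissolution_csv(profiles: dict[str, DissolutionProfile], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "formulation_id": fid,
                "time_h": p.times,
                "release_pct": p.release,
            }
        )
        for fid, p in profiles.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_plasma_csv(path, dose: float = 1.0) -> dict[tuple[str, str], PlasmaProfile]:
    """Read plasma profiles keyed by (group, subject_id)."""
    df = pd.read_csv(path)
    required = {"subject_id", "group", "time_h", "conc_ug_ml"}
    if not required.issubset(df.columns):
        raise ValueError(f"plasma CSV needs columns {sorted(required)}")
    out = {}
    for (grp, subj), sub in df.groupby(["group", "subject_id"], sort=False):
        sub = sub.sort_values("time_h")
        out[(str(grp), str(subj))] = PlasmaProfile(
            sub["time_h"].to_numpy(float),
            sub["conc_ug_ml"].to_numpy(float),
            dose=dose,
            group_id=str(grp),
        )
    return out
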