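"""Scalar formulation-characterization metrics.

Entrapment efficiency (percent of the theoretical drug load recovered
inside the beads), swelling ratio over time (wet weight over dry
weight), and descriptive buoyancy summaries (floating lag time and total
floating duration).  These are bookkeeping operations on measured
quantities; no physics is modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BuoyancyRecord",
    "BuoyancySummary",
    "entrapment_efficiency",
    "swelling_ratio",
    "summarize_buoyancy",
]


@dataclass(frozen=True)
class BuoyancyRecord:
    """One bead batch's floating lag time (s) and float duration (h)."""

    lag_time_s: float
    float_duration_h: float

    def __post_init__(self) -> None:
        if self.lag_time_s < 0 or self.float_duration_h < 0:
            raise ValueError("lag time and float duration must be >= 0")


@dataclass(frozen=True)
class BuoyancySummary:
    lag_mean_s: float
    lag_sd_s: float
    duration_mean_h: float
    duration_sd_h: float
    n: int
    sd_defined: bool


def entrapment_efficiency(actual_mg: float, theoretical_mg: float) -> float:
    """EE% = 100 * actual drug content / theoretical drug content."""
    if theoretical_mg <= 0:
        raise ValueError("theoretical drug content must be positive")
    if actual_mg < 0:
        raise ValueError("actual drug content must be >= 0")
    return 100.0 * actual_mg / theoretical_mg


def swelling_ratio(wet_weights, dry_weight: float) -> np.ndarray:
    """Elementwise swelling ratio: wet bead weight / dry bead weight."""
    if dry_weight <= 0:
        raise ValueError("dry weight must be positive")
    wet = np.asarray(wet_weights, dtype=float)
    if np.any(wet < 0):
        raise ValueError("wet weights must be >= 0")
    return wet / dry_weight


def summarize_buoyancy(records: list[BuoyancyRecord]) -> BuoyancySummary:
    """Mean +/- SD (n-1 denominator) of lag time and float duration.

    With a single record the SD is undefined; it is reported as 0 with
    ``sd_defined=False`` and a warning.
    """
    if not records:
        raise ValueError("need at least one buoyancy record")
    lag = np.array([r.lag_time_s for r in records], dtype=float)
    dur = np.array([r.float_duration_h for r in records], dtype=float)
    n = len(records)
    if n == 1:
        warnings.warn("single record: SD undefined, reported as 0", stacklevel=2)
        return BuoyancySummary(lag[0], 0.0, dur[0], 0.0, 1, sd_defined=False)
    return BuoyancySummary(
        float(lag.mean()),
        float(lag.std(ddof=1)),
        float(dur.mean()),
        float(dur.std(ddof=1)),
        n,
        sd_defined=True,
    )
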