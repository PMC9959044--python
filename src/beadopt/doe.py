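"""Rotatable central composite designs and coded-unit transforms.

A central composite design (CCD) for k factors consists of a full 2^k
factorial core at coded levels +/-1, 2k axial ("star") points at coded
level +/-alpha on one axis at a time, and replicated center points at the
origin.  The design is *rotatable* when alpha = (2^k)^(1/4), which makes
the prediction variance of a second-order model depend only on the
distance from the design center.

Factor levels are handled in two unit systems:

* **actual** units -- the physical concentrations (percent w/v here);
* **coded** units -- rescaled so that the low level maps to -1, the high
  level to +1 and their midpoint to 0.

Coded units are the canonical internal representation; actual units
appear only at I/O boundaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "rotatable_alpha",
    "build_ccd",
    "code_point",
    "decode_point",
]


def rotatable_alpha(k: int) -> float:
    """Axial coded magnitude (2^k)^(1/4) giving a rotatable CCD."""
    if k < 2:
        raise ValueError("a CCD requires at least 2 factors")
    return (2.0**k) ** 0.25


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its coded -1/+1 actual levels.

    Parameters
    ----------
    name :
        Factor label, e.g. ``"alginate_pct"``.
    unit :
        Physical unit of the actual levels (percent w/v for all factors
        in the bead formulation study).
    low, high :
        Actual levels that map to coded -1 and +1.
    """

    name: str
    unit: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"factor {self.name!r}: low must be < high")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


def code_point(actual, factors) -> np.ndarray:
    """Map actual factor levels to coded units.

    ``coded[i] = (actual[i] - center[i]) / half_range[i]``
    """
    actual = np.asarray(actual, dtype=float)
    if actual.shape != (len(factors),):
        raise ValueError(
            f"expected {len(factors)} actual levels, got shape {actual.shape}"
        )
    center = np.array([f.center for f in factors])
    half = np.array([f.half_range for f in factors])
    return (actual - center) / half


def decode_point(coded, factors) -> np.ndarray:
    """Inverse of :func:`code_point`: coded units back to actual levels."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape != (len(factors),):
        raise ValueError(
            f"expected {len(factors)} coded levels, got shape {coded.shape}"
        )
    center = np.array([f.center for f in factors])
    half = np.array([f.half_range for f in factors])
    return center + coded * half


@dataclass
class DesignTable:
    """A designed experiment: factor definitions, runs, and responses.

    Attributes
    ----------
    factors :
        One :class:`FactorSpec` per factor (k of them).
    coded :
        ``(n_runs, k)`` array of coded factor levels, in standard order.
    std_order, run_order :
        1-based standard-order and (possibly randomized) run-order ids.
    responses :
        Mapping from response name to an ``(n_runs,)`` value vector.
    """

    factors: list[FactorSpec]
    coded: np.ndarray
    std_order: np.ndarray = None
    run_order: np.ndarray = None
    responses: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        if self.coded.ndim != 2 or self.coded.shape[1] != len(self.factors):
            raise ValueError("coded must be (n_runs, n_factors)")
        n = self.n_runs
        if self.std_order is None:
            self.std_order = np.arange(1, n + 1)
        if self.run_order is None:
            self.run_order = np.arange(1, n + 1)
        self.std_order = np.asarray(self.std_order, dtype=int)
        self.run_order = np.asarray(self.run_order, dtype=int)
        for name, vals in self.responses.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (n,):
                raise ValueError(f"response {name!r} must have one value per run")
            self.responses[name] = vals

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def actual(self) -> np.ndarray:
        """Actual factor levels, ``(n_runs, k)``."""
        center = np.array([f.center for f in self.factors])
        half = np.array([f.half_range for f in self.factors])
        return center + self.coded * half

    def response(self, name: str) -> np.ndarray:
        try:
            return self.responses[name]
        except KeyError:
            raise KeyError(
                f"response {name!r} not present; have {sorted(self.responses)}"
            ) from None

    def with_responses(self, responses: dict[str, np.ndarray]) -> "DesignTable":
        """Copy of the design with (additional) response columns."""
        merged = dict(self.responses)
        merged.update({k: np.asarray(v, float) for k, v in responses.items()})
        return DesignTable(
            factors=self.factors,
            coded=self.coded.copy(),
            std_order=self.std_order.copy(),
            run_order=self.run_order.copy(),
            responses=merged,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat table: orders, coded levels, actual levels, responses."""
        data = {"std_order": self.std_order, "run_order": self.run_order}
        for j, f in enumerate(self.factors):
            data[f"x{j + 1}_coded"] = self.coded[:, j]
        actual = self.actual
        for j, f in enumerate(self.factors):
            data[f.name] = actual[:, j]
        for name, vals in self.responses.items():
            data[name] = vals
        return pd.DataFrame(data)


def build_ccd(factors, n_center: int = 3) -> DesignTable:
    """Build a rotatable central composite design in standard order.

    Runs are ordered: 2^k factorial points (low level varying fastest in
    the first factor), 2k axial points (-alpha/+alpha per factor), then
    ``n_center`` center replicates.  Axial magnitude is (2^k)^(1/4).

    Parameters
    ----------
    factors :
        Sequence of :class:`FactorSpec`, at least two.
    n_center :
        Number of center-point replicates, at least one.
    """
    factors = list(factors)
    k = len(factors)
    if k < 2:
        raise ValueError("a CCD requires at least 2 factors")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    alpha = rotatable_alpha(k)

    factorial = [
        list(levels) for levels in itertools.product([-1.0, 1.0], repeat=k)
    ]
    axial = []
    for j in range(k):
        for sign in (-1.0, 1.0):
            pt = [0.0] * k
            pt[j] = sign * alpha
            axial.append(pt)
    center = [[0.0] * k for _ in range(n_center)]
    coded = np.array(factorial + axial + center)
    return DesignTable(factors=factors, coded=coded)
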