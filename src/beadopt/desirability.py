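"""Derringer desirability scoring and multi-response optimization.

Each response prediction is mapped to a desirability d in [0, 1] by a
goal-specific ramp (maximize, minimize, hit a target, or stay in range),
and the per-response scores are combined into an overall desirability

    D = (prod_i d_i^{r_i})^(1 / sum_i r_i),

the importance-weighted geometric mean.  D is zero as soon as any single
response is fully undesirable, which is what makes the geometric mean
(rather than an arithmetic one) the right aggregate for formulation
trade-offs.

The optimizer is a deterministic seeded multi-start: Latin-hypercube
starting points over the design region followed by derivative-free
Nelder-Mead polish, with the candidate clipped/projected back into the
region.  The region is either the coded cube [-1, 1]^k or the sphere of
radius alpha that circumscribes the axial points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .rsm import FittedRSM, predict_response

__all__ = [
    "DesirabilityGoal",
    "DesirabilityResult",
    "desirability_component",
    "overall_desirability",
    "optimize_desirability",
]


@dataclass(frozen=True)
class DesirabilityGoal:
    """Goal definition for one response.

    ``kind`` is one of ``maximize``, ``minimize``, ``target``,
    ``in_range``.  ``weight`` is the ramp curvature exponent; ``importance``
    the exponent r_i in the weighted geometric mean.
    """

    response_name: str
    kind: str
    low: float
    high: float
    target: float | None = None
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("maximize", "minimize", "target", "in_range"):
            raise ValueError(f"unknown goal kind {self.kind!r}")
        if not self.low < self.high:
            raise ValueError("goal requires low < high")
        if self.kind == "target":
            if self.target is None or not self.low <= self.target <= self.high:
                raise ValueError("target goal requires low <= target <= high")
        if self.weight <= 0 or self.importance <= 0:
            raise ValueError("weight and importance must be positive")


@dataclass
class DesirabilityResult:
    """Optimized point with component and overall desirability."""

    point_coded: np.ndarray
    point_actual: np.ndarray | None
    per_response_d: dict[str, float]
    overall_D: float
    predicted: dict[str, float]
    feasible: bool = True
    note: str = ""


def desirability_component(value: float, goal: DesirabilityGoal) -> float:
    """Map one response value to its desirability in [0, 1]."""
    lo, hi, w = goal.low, goal.high, goal.weight
    v = float(value)
    if goal.kind == "maximize":
        if v <= lo:
            return 0.0
        if v >= hi:
            return 1.0
        return ((v - lo) / (hi - lo)) ** w
    if goal.kind == "minimize":
        if v >= hi:
            return 0.0
        if v <= lo:
            return 1.0
        return ((hi - v) / (hi - lo)) ** w
    if goal.kind == "target":
        t = goal.target
        if v <= lo or v >= hi:
            # endpoints score 0 except degenerate target-at-bound
            return 1.0 if v == t else 0.0
        if v == t:
            return 1.0
        if v < t:
            return ((v - lo) / (t - lo)) ** w
        return ((hi - v) / (hi - t)) ** w
    # in_range: flat indicator
    return 1.0 if lo <= v <= hi else 0.0


def overall_desirability(
    ds: dict[str, float], importances: dict[str, float] | None = None
) -> float:
    """Importance-weighted geometric mean of component desirabilities."""
    if not ds:
        raise ValueError("no desirability components")
    if importances is None:
        importances = {k: 1.0 for k in ds}
    if set(importances) != set(ds):
        raise ValueError("importances must carry the same keys as ds")
    r_total = sum(importances.values())
    prod = 1.0
    for name, d in ds.items():
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"component {name!r} outside [0, 1]")
        if d == 0.0:
            return 0.0
        prod *= d ** importances[name]
    return prod ** (1.0 / r_total)


def _project(x: np.ndarray, region: str, radius: float) -> np.ndarray:
    if region == "cuboidal":
        return np.clip(x, -1.0, 1.0)
    nrm = np.linalg.norm(x)
    if nrm > radius:
        return x * (radius / nrm)
    return x


def _score(
    x: np.ndarray,
    models: list[FittedRSM],
    goals: list[DesirabilityGoal],
) -> tuple[float, dict[str, float], dict[str, float]]:
    preds = {m.response_name: predict_response(m, x) for m in models}
    ds = {
        g.response_name: desirability_component(preds[g.response_name], g)
        for g in goals
    }
    D = overall_desirability(ds, {g.response_name: g.importance for g in goals})
    return D, ds, preds


def optimize_desirability(
    models: list[FittedRSM],
    goals: list[DesirabilityGoal],
    region: str = "cuboidal",
    radius: float | None = None,
    n_starts: int = 32,
    seed: int = 0,
    tol: float = 1e-8,
    factors=None,
) -> DesirabilityResult:
    """Locate the maximum-desirability point in the design region.

    Parameters
    ----------
    models, goals :
        One fitted surface and one goal per response; goals are matched
        to models by response name.
    region :
        ``"cuboidal"`` for the coded cube [-1, 1]^k, ``"spherical"`` for
        the ball of radius ``radius`` (default: the rotatable axial
        magnitude (2^k)^(1/4)).
    n_starts, seed :
        Latin-hypercube multi-start budget; fully deterministic given
        the seed.
    factors :
        Optional factor specs used to report the optimum in actual units.

    If every start scores D = 0 the goals are infeasible over the
    region; the best-effort point is still returned with
    ``feasible=False``.
    """
    if not models:
        raise ValueError("need at least one model")
    by_name = {g.response_name: g for g in goals}
    if set(by_name) != {m.response_name for m in models}:
        raise ValueError("goals and models must cover the same responses")
    if region not in ("cuboidal", "spherical"):
        raise ValueError("region must be 'cuboidal' or 'spherical'")
    k = models[0].k
    if radius is None:
        radius = (2.0**k) ** 0.25

    sampler = qmc.LatinHypercube(d=k, seed=seed)
    span = 1.0 if region == "cuboidal" else radius
    starts = qmc.scale(sampler.random(n_starts), -span, span)

    neg = lambda x: -_score(_project(x, region, radius), models, goals)[0]
    best_x, best_D = None, -1.0
    for x0 in starts:
        x0 = _project(x0, region, radius)
        res = minimize(
            neg,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": tol, "maxiter": 2000},
        )
        x = _project(res.x, region, radius)
        D = _score(x, models, goals)[0]
        if D > best_D:
            best_D, best_x = D, x

    D, ds, preds = _score(best_x, models, goals)
    actual = None
    if factors is not None:
        from .doe import decode_point

        actual = decode_point(best_x, factors)
    return DesirabilityResult(
        point_coded=best_x,
        point_actual=actual,
        per_response_d=ds,
        overall_D=D,
        predicted=preds,
        feasible=D > 0.0,
        note="" if D > 0.0 else "all starts scored D = 0: goals infeasible over region",
    )
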