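"""Non-compartmental pharmacokinetic analysis and blood-pressure summaries.

Standard model-free PK summary of a plasma concentration-time profile:

* Cmax / Tmax read directly off the observations (ties -> earliest time);
* terminal elimination: linear regression of log10(C) on t over a
  terminal window after Tmax, with ``Kel = -slope * 2.303`` (the 2.303
  converts the base-10 slope to a natural-log rate constant);
* AUC_0-t by the linear trapezoidal rule; exponential tail
  ``AUC_t-inf = C_last / Kel``; ``AUC_0-inf`` their sum;
* AUMC by trapezoid on t*C plus the analytic tail
  ``C_last * (t_last/Kel + 1/Kel^2)``; ``MRT = AUMC_0-inf / AUC_0-inf``;
* relative bioavailability: dose-normalized AUC ratio of test vs
  reference, in percent.

The terminal window is not standardized in the field; the default rule
here considers every suffix window of >= 3 positive-concentration
points strictly after Tmax and picks the one maximizing the adjusted R^2
of the log-linear fit (ties -> more points).  A fixed "last k points"
rule is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PlasmaProfile",
    "NCAResult",
    "BPTimeSeries",
    "BPSummary",
    "cmax_tmax",
    "terminal_slope",
    "auc_trapezoid",
    "nca",
    "relative_bioavailability",
    "bp_summary",
]

LN10 = 2.303  # conventional rounded factor used in PK practice


@dataclass
class PlasmaProfile:
    """Plasma concentration-time series for one subject or group mean."""

    times: np.ndarray  # hours
    concentrations: np.ndarray  # ug/mL
    dose: float = 1.0  # mg/kg
    group_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ValueError("times and concentrations must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("negative concentrations are input errors")


@dataclass(frozen=True)
class NCAResult:
    Cmax: float  # ug/mL
    Tmax: float  # h
    slope: float  # log10-units/h
    Kel: float  # 1/h
    AUC_0_t: float  # ug*h/mL
    AUC_t_inf: float
    AUC_0_inf: float
    AUMC_0_inf: float  # ug*h^2/mL
    MRT: float  # h
    n_terminal_points: int


@dataclass
class BPTimeSeries:
    """Mean systolic blood pressure time course for one treatment group.

    The pre-dose value is ``times[0] == 0`` (the "initial" reading).
    """

    times: np.ndarray  # hours
    mean_bp: np.ndarray  # mmHg
    sd_bp: np.ndarray | None = None
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_bp = np.asarray(self.mean_bp, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty blood-pressure series")
        if self.times.shape != self.mean_bp.shape:
            raise ValueError("times and mean_bp must match")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.mean_bp <= 0):
            raise ValueError("mean BP must be positive")
        if self.sd_bp is not None:
            self.sd_bp = np.asarray(self.sd_bp, dtype=float)


@dataclass(frozen=True)
class BPSummary:
    min_bp: float  # mmHg
    time_of_min: float  # h
    max_drop_vs_initial: float  # mmHg
    duration_below_threshold: float  # h, contiguous from first crossing


def cmax_tmax(profile: PlasmaProfile) -> tuple[float, float]:
    """Peak observed concentration and its time (ties -> earliest)."""
    c = profile.concentrations
    if c.size == 0:
        raise ValueError("empty profile")
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(profile.times[i])


def terminal_slope(
    profile: PlasmaProfile, window_rule: str | tuple[str, int] = "best_adj_r2"
) -> tuple[float, float, int]:
    """Terminal log-linear slope and elimination rate constant.

    Returns ``(slope, Kel, n_points)`` where slope is in log10 units per
    hour and ``Kel = -slope * 2.303`` in 1/h.

    ``window_rule`` is ``"best_adj_r2"`` (default; see module docstring)
    or ``("last", k)`` for the last k points.  Concentrations of exactly
    0 are excluded from the log fit.  Raises if fewer than 3 usable
    points remain after Tmax, or if the selected slope is non-negative
    (no elimination phase).
    """
    _, tmax = cmax_tmax(profile)
    mask = (profile.times > tmax) & (profile.concentrations > 0)
    t, c = profile.times[mask], profile.concentrations[mask]
    if t.size < 3:
        raise ValueError(
            f"only {t.size} positive concentrations strictly after Tmax "
            "(need >= 3 for the terminal fit)"
        )
    logc = np.log10(c)

    if window_rule == "best_adj_r2":
        best = None
        for start in range(t.size - 2):
            m = t.size - start
            res = stats.linregress(t[start:], logc[start:])
            r2 = res.rvalue**2
            adj = 1 - (1 - r2) * (m - 1) / (m - 2) if m > 2 else r2
            key = (adj, m)
            if best is None or key > best[0]:
                best = (key, res.slope, m)
        slope, npts = float(best[1]), int(best[2])
    elif isinstance(window_rule, tuple) and window_rule[0] == "last":
        k = int(window_rule[1])
        if k < 3 or k > t.size:
            raise ValueError(f"'last' window needs 3 <= k <= {t.size}")
        res = stats.linregress(t[-k:], logc[-k:])
        slope, npts = float(res.slope), k
    else:
        raise ValueError(f"unknown window rule {window_rule!r}")

    if slope >= 0:
        raise ValueError(
            f"non-negative terminal slope ({slope:.4g}): no elimination "
            "phase detectable in the selected window"
        )
    return slope, -slope * LN10, npts


def auc_trapezoid(times, values) -> float:
    """Linear trapezoidal area over the observed range."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points to integrate")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def nca(
    profile: PlasmaProfile, window_rule: str | tuple[str, int] = "best_adj_r2"
) -> NCAResult:
    """Full non-compartmental summary of one plasma profile."""
    cmax, tmax = cmax_tmax(profile)
    slope, kel, npts = terminal_slope(profile, window_rule)
    t, c = profile.times, profile.concentrations
    auc_0_t = auc_trapezoid(t, c)
    c_last, t_last = float(c[-1]), float(t[-1])
    auc_tail = c_last / kel
    auc_0_inf = auc_0_t + auc_tail
    aumc_0_t = auc_trapezoid(t, t * c)
    aumc_tail = c_last * (t_last / kel + 1.0 / kel**2)
    aumc_0_inf = aumc_0_t + aumc_tail
    return NCAResult(
        Cmax=cmax,
        Tmax=tmax,
        slope=slope,
        Kel=kel,
        AUC_0_t=auc_0_t,
        AUC_t_inf=auc_tail,
        AUC_0_inf=auc_0_inf,
        AUMC_0_inf=aumc_0_inf,
        MRT=aumc_0_inf / auc_0_inf,
        n_terminal_points=npts,
    )


def relative_bioavailability(
    auc_test: float,
    auc_ref: float,
    dose_test: float = 1.0,
    dose_ref: float = 1.0,
) -> float:
    """Dose-normalized AUC ratio, percent:
    ``100 * (AUC_test/AUC_ref) * (dose_ref/dose_test)``."""
    for name, v in (
        ("auc_test", auc_test),
        ("auc_ref", auc_ref),
        ("dose_test", dose_test),
        ("dose_ref", dose_ref),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return 100.0 * (auc_test / auc_ref) * (dose_ref / dose_test)


def bp_summary(
    series: BPTimeSeries,
    threshold: float | None = None,
) -> BPSummary:
    """Descriptive summary of a blood-pressure time course.

    Reports the minimum mean BP and its time (ties -> earliest), the
    maximum drop relative to the series' initial (pre-dose) value, and
    the total time spent below ``threshold`` (trapezoid on the
    measurement grid: each interval counts if both endpoints are below).
    """
    t, bp = series.times, series.mean_bp
    i = int(np.argmin(bp))
    min_bp, t_min = float(bp[i]), float(t[i])
    drop = float(bp[0] - bp.min())
    below = 0.0
    if threshold is not None:
        under = bp < threshold
        for j in range(t.size - 1):
            if under[j] and under[j + 1]:
                below += t[j + 1] - t[j]
    return BPSummary(
        min_bp=min_bp,
        time_of_min=t_min,
        max_drop_vs_initial=drop,
        duration_below_threshold=float(below),
    )
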