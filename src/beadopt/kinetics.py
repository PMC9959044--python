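"""Dissolution-kinetics model fitting and release-mechanism classification.

Five classical release laws are fitted to cumulative-release profiles by
the conventional linearizations (Q is cumulative percent released at
time t, on a 100% label-claim basis):

========================  =============================================  =====================
model                     linearized regression                          reported constant
========================  =============================================  =====================
zero order                Q vs t                                         K0 = slope  (%/h)
first order               ln(100 - Q) vs t                               K1 = -slope (1/h)
Higuchi                   Q vs sqrt(t)                                   KH = slope  (%/h^0.5)
Korsmeyer-Peppas          log10(Mt/M) vs log10(t), Mt/M <= 0.60 only     Km = 10^intercept,
                                                                         n = slope
Hixson-Crowell            100^(1/3) - (100-Q)^(1/3) vs t                 KHC = slope
========================  =============================================  =====================

All linear fits include an intercept; only the slope-derived constant is
reported, and the quoted R^2 is the regression R^2.  The Korsmeyer-Peppas
exponent n identifies the transport mechanism for swellable matrices:
n <= 0.45 Fickian diffusion, 0.45 < n < 0.89 anomalous (coupled
diffusion/relaxation), 0.89 <= n <= 1 case-II (relaxation-controlled),
n > 1 super case II.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DissolutionProfile",
    "KineticFitResult",
    "MODELS",
    "fit_kinetic_model",
    "select_best_model",
    "classify_release_mechanism",
    "dissolution_auc",
]

MODELS = ("zero", "first", "higuchi", "korsmeyer_peppas", "hixson_crowell")

#: number of fitted parameters per model, used to break R^2 ties
#: (simpler models first)
_N_PARAMS = {
    "zero": 1,
    "first": 1,
    "higuchi": 1,
    "hixson_crowell": 1,
    "korsmeyer_peppas": 2,
}


@dataclass
class DissolutionProfile:
    """Cumulative-release time series for one formulation.

    ``times`` in hours, strictly increasing and positive; ``release`` in
    cumulative percent of label claim.  Decreasing release values are
    physically suspect (sampling noise) -- they are flagged in
    ``monotone_violations`` but kept as measured, never re-sorted.
    """

    times: np.ndarray
    release: np.ndarray
    formulation_id: str = ""
    monotone_violations: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.release = np.asarray(self.release, dtype=float)
        if self.times.shape != self.release.shape or self.times.ndim != 1:
            raise ValueError("times and release must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times <= 0):
            raise ValueError("times must be positive (0 h is implicit)")
        if np.any((self.release < 0) | (self.release > 110)):
            raise ValueError("release must lie in [0, 110] percent")
        viol = np.diff(self.release) < 0
        self.monotone_violations = np.concatenate([[False], viol])
        if viol.any():
            warnings.warn(
                f"profile {self.formulation_id!r}: release decreases at "
                f"{viol.sum()} point(s); kept as measured",
                stacklevel=2,
            )


@dataclass(frozen=True)
class KineticFitResult:
    """One model's linearized least-squares fit to a profile."""

    model: str
    K: float
    R2: float
    n_points_used: int
    n: float | None = None  # Korsmeyer-Peppas release exponent
    intercept: float = 0.0


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_kinetic_model(
    profile: DissolutionProfile,
    model: str,
    kp_release_cutoff: float = 0.60,
) -> KineticFitResult:
    """Fit one release law to a dissolution profile.

    Points with Q >= 100 are dropped (with a warning) from the first-order
    and Hixson-Crowell transforms, whose linearizations require
    100 - Q > 0.  The Korsmeyer-Peppas fit uses only points with
    fractional release Mt/M <= ``kp_release_cutoff`` (default 0.60, the
    conventional validity range of the power law).

    Raises
    ------
    ValueError
        For an unknown model or fewer than 3 usable points.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    t, q = profile.times, profile.release

    if model in ("first", "hixson_crowell"):
        ok = q < 100.0
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} point(s) with Q >= 100% dropped from "
                f"{model} transform",
                stacklevel=2,
            )
        t, q = t[ok], q[ok]
    elif model == "korsmeyer_peppas":
        ok = (q > 0) & (q / 100.0 <= kp_release_cutoff)
        t, q = t[ok], q[ok]

    if t.size < 3:
        raise ValueError(
            f"{model}: only {t.size} usable points (need >= 3)"
        )

    if model == "zero":
        slope, b, r2 = _linfit(t, q)
        return KineticFitResult("zero", slope, r2, t.size, intercept=b)
    if model == "first":
        slope, b, r2 = _linfit(t, np.log(100.0 - q))
        return KineticFitResult("first", -slope, r2, t.size, intercept=b)
    if model == "higuchi":
        slope, b, r2 = _linfit(np.sqrt(t), q)
        return KineticFitResult("higuchi", slope, r2, t.size, intercept=b)
    if model == "hixson_crowell":
        y = 100.0 ** (1.0 / 3.0) - (100.0 - q) ** (1.0 / 3.0)
        slope, b, r2 = _linfit(t, y)
        return KineticFitResult("hixson_crowell", slope, r2, t.size, intercept=b)
    # korsmeyer_peppas: log10(F) = log10(Km) + n*log10(t)
    slope, b, r2 = _linfit(np.log10(t), np.log10(q / 100.0))
    return KineticFitResult(
        "korsmeyer_peppas", 10.0**b, r2, t.size, n=slope, intercept=b
    )


def select_best_model(
    profile: DissolutionProfile, kp_release_cutoff: float = 0.60
) -> tuple[list[KineticFitResult], dict[str, str]]:
    """Fit all five laws and rank by R^2 (descending).

    Ties are broken in favour of the model with fewer parameters.
    Models that cannot be fitted (e.g. too few points after the
    Korsmeyer-Peppas cutoff) are excluded; the reasons are returned in
    the second element.
    """
    fits, excluded = [], {}
    for model in MODELS:
        try:
            fits.append(
                fit_kinetic_model(profile, model, kp_release_cutoff)
            )
        except ValueError as exc:
            excluded[model] = str(exc)
    if len(fits) < 2:
        raise ValueError(f"profile fit-able by < 2 models: {excluded}")
    fits.sort(key=lambda f: (-f.R2, _N_PARAMS[f.model]))
    return fits, excluded


def classify_release_mechanism(n: float) -> str:
    """Transport mechanism implied by the Korsmeyer-Peppas exponent.

    ``n <= 0.45`` -> ``"fickian"``; ``0.45 < n < 0.89`` -> ``"anomalous"``;
    ``0.89 <= n <= 1.0`` -> ``"case_II"``; ``n > 1.0`` -> ``"super_case_II"``.
    """
    if not np.isfinite(n):
        raise ValueError("release exponent must be finite")
    if n <= 0.45:
        return "fickian"
    if n < 0.89:
        return "anomalous"
    if n <= 1.0:
        return "case_II"
    return "super_case_II"


def dissolution_auc(
    profile: DissolutionProfile, prepend_origin: bool = True
) -> float:
    """Trapezoidal area under the cumulative-release curve (%.h).

    By default a (0 h, 0%) point is prepended: release starts at dosing.
    """
    t, q = profile.times, profile.release
    if prepend_origin:
        t = np.concatenate([[0.0], t])
        q = np.concatenate([[0.0], q])
    if t.size < 2:
        raise ValueError("need at least 2 points to integrate")
    return float(np.trapezoid(q, t))
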