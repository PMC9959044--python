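"""Synthetic-data generators for every pipeline stage.

Each generator draws from the statistical model the corresponding
analysis stage assumes, so the full chain can be exercised and
validated without any external data:

* CCD response tables: a known quadratic surface with multiplicative
  Gaussian noise whose standard deviation is a stated coefficient of
  variation (CV%), matching how run-to-run dispersion is reported for
  designed formulation experiments;
* dissolution profiles: one of the five release laws, multiplicative
  noise, clamped to [0, 100] and made non-decreasing by cumulative max;
* plasma profiles: the Bateman one-compartment first-order-absorption
  curve ``C(t) = S*ka/(ka-ke) * (exp(-ke t) - exp(-ka t))`` with
  lognormal multiplicative noise;
* blood-pressure courses: a baseline minus a smooth gamma-shaped effect
  pulse, with additive Gaussian noise (BP dispersion is reported as an
  absolute +/- SD, not a CV).

Every generator is bit-reproducible for a fixed seed, and noiseless
output lies exactly on the generating law.
"""

from __future__ import annotations

import numpy as np

from .doe import DesignTable
from .kinetics import DissolutionProfile
from .pk import BPTimeSeries, PlasmaProfile
from .rsm import model_matrix, term_names

__all__ = [
    "gen_ccd_responses",
    "gen_dissolution",
    "gen_plasma",
    "gen_bp",
    "bateman",
    "bateman_tmax",
]


def gen_ccd_responses(
    design: DesignTable,
    true_coefficients: dict[str, dict[str, float] | np.ndarray],
    cv_pct: float = 0.0,
    seed: int = 0,
) -> DesignTable:
    """Attach responses drawn from known quadratic surfaces to a design.

    ``true_coefficients`` maps response name -> the 10 quadratic-model
    coefficients (dict keyed like :func:`beadopt.rsm.term_names`, or a
    vector in that order).  Each response is
    ``y = surface(x) * (1 + eps)`` with ``eps ~ N(0, cv_pct/100)``;
    ``cv_pct = 0`` returns the exact surface values.
    """
    if cv_pct < 0:
        raise ValueError("cv_pct must be >= 0")
    rng = np.random.default_rng(seed)
    X = model_matrix(design.coded)
    p = X.shape[1]
    names = term_names(design.k)
    responses = {}
    for resp, coeffs in true_coefficients.items():
        if isinstance(coeffs, dict):
            missing = set(names) - set(coeffs)
            if missing:
                raise ValueError(f"{resp}: missing coefficients {sorted(missing)}")
            beta = np.array([coeffs[t] for t in names], dtype=float)
        else:
            beta = np.asarray(coeffs, dtype=float)
            if beta.shape != (p,):
                raise ValueError(f"{resp}: expected {p} coefficients")
        mean = X @ beta
        eps = rng.normal(0.0, cv_pct / 100.0, size=mean.shape)
        responses[resp] = mean * (1.0 + eps)
    return design.with_responses(responses)


def _release_law(model: str, params: dict[str, float], t: np.ndarray) -> np.ndarray:
    if model == "zero":
        return params["K0"] * t
    if model == "first":
        return 100.0 * (1.0 - np.exp(-params["K1"] * t))
    if model == "higuchi":
        return params["KH"] * np.sqrt(t)
    if model == "korsmeyer_peppas":
        return 100.0 * params["Km"] * t ** params["n"]
    if model == "hixson_crowell":
        root = 100.0 ** (1.0 / 3.0) - params["KHC"] * t
        return 100.0 - np.maximum(root, 0.0) ** 3
    raise ValueError(f"unknown release law {model!r}")


def gen_dissolution(
    model: str,
    params: dict[str, float],
    times,
    cv_pct: float = 0.0,
    seed: int = 0,
    formulation_id: str = "synthetic",
) -> tuple[DissolutionProfile, bool]:
    """Cumulative-release profile following one kinetic law plus noise.

    Multiplicative Gaussian noise (sd = cv_pct/100) is applied, the
    series is clamped to [0, 100] and forced non-decreasing by a
    cumulative maximum.  Returns ``(profile, clamped)`` where
    ``clamped`` flags whether the law (before noise) exceeded 100%.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0) or np.any(t <= 0):
        raise ValueError("times must be positive and strictly increasing")
    exact = _release_law(model, params, t)
    clamped = bool(np.any(exact > 100.0))
    rng = np.random.default_rng(seed)
    noisy = exact * (1.0 + rng.normal(0.0, cv_pct / 100.0, size=t.shape))
    q = np.maximum.accumulate(np.clip(noisy, 0.0, 100.0))
    return DissolutionProfile(t, q, formulation_id=formulation_id), clamped


def bateman(t, dose_scale: float, ka: float, ke: float) -> np.ndarray:
    """One-compartment first-order-absorption concentration curve."""
    if ka <= 0 or ke <= 0:
        raise ValueError("ka and ke must be positive")
    if ka == ke:
        raise ValueError("ka = ke is the degenerate Bateman limit")
    t = np.asarray(t, dtype=float)
    return dose_scale * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def bateman_tmax(ka: float, ke: float) -> float:
    """Analytic time of peak, ln(ka/ke)/(ka - ke)."""
    return float(np.log(ka / ke) / (ka - ke))


def gen_plasma(
    dose_scale: float,
    ka: float,
    ke: float,
    times,
    cv_pct: float = 0.0,
    seed: int = 0,
    dose: float = 1.0,
    group_id: str = "synthetic",
) -> PlasmaProfile:
    """Plasma profile from the Bateman curve with lognormal noise.

    Noise is multiplicative lognormal with coefficient of variation
    ``cv_pct``; ``cv_pct = 0`` returns the exact curve.
    """
    t = np.asarray(times, dtype=float)
    c = bateman(t, dose_scale, ka, ke)
    if cv_pct > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p((cv_pct / 100.0) ** 2))
        c = c * rng.lognormal(-0.5 * sigma**2, sigma, size=t.shape)
    return PlasmaProfile(t, c, dose=dose, group_id=group_id)


def gen_bp(
    baseline: float,
    effect_peak: float,
    t_peak: float,
    duration: float,
    times,
    sd: float = 0.0,
    seed: int = 0,
    group: str = "synthetic",
) -> BPTimeSeries:
    """Blood-pressure course: baseline minus a gamma-shaped effect pulse.

    The pulse is ``effect_peak * ((t/t_peak) * exp(1 - t/t_peak))**s``,
    which peaks at ``t_peak`` with height ``effect_peak``; the shape
    exponent s is chosen so the effect has decayed to 10% of its peak at
    ``t = duration`` (which must exceed ``t_peak``).  Additive Gaussian
    noise with standard deviation ``sd``.
    """
    if duration <= t_peak:
        raise ValueError("duration must exceed t_peak")
    t = np.asarray(times, dtype=float)
    g_end = (duration / t_peak) * np.exp(1.0 - duration / t_peak)
    s = np.log(0.1) / np.log(g_end)  # g_end in (0,1) for duration != t_peak
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(t > 0, (t / t_peak) * np.exp(1.0 - t / t_peak), 0.0)
    pulse = effect_peak * g**s
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd, size=t.shape) if sd > 0 else 0.0
    return BPTimeSeries(t, baseline - pulse + noise, group=group)
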