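"""Quadratic response-surface fitting and DoE diagnostics.

The full second-order model on k coded factors,

    y = b0 + sum_i bi*xi + sum_{i<j} bij*xi*xj + sum_i bii*xi^2 + e,

is fitted by ordinary least squares.  With k = 3 this is the 10-term
model used throughout the bead-formulation study; no term pruning is
ever applied, so the reported coefficient vector always carries every
term.  Alongside the fit, the standard Design-of-Experiments diagnostic
suite is computed: R^2, adjusted R^2, PRESS-based predicted R^2, the
coefficient of variation, and the adequate-precision signal-to-noise
ratio.

Conventions (these are required to reproduce Design-Expert output):

* the total sum of squares is corrected (about the mean), with
  df_total = n - 1 and df_error = n - p;
* PRESS uses the hat-diagonal shortcut
  ``PRESS = sum((e_i / (1 - h_i))^2)``, algebraically identical to n
  explicit leave-one-out refits (see :func:`press_by_loo`);
* adequate precision is ``(max(yhat) - min(yhat)) / sqrt(p*MSE/n)``
  over the design points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .doe import DesignTable

__all__ = [
    "FittedRSM",
    "DiagnosticsReport",
    "term_names",
    "model_matrix",
    "fit_quadratic_rsm",
    "predict_response",
    "compute_diagnostics",
    "press_by_loo",
]


def term_names(k: int) -> list[str]:
    """Term labels in fitting order: b0, linear, interactions, quadratic."""
    names = ["b0"] + [f"b{i + 1}" for i in range(k)]
    names += [f"b{i + 1}{j + 1}" for i in range(k) for j in range(i + 1, k)]
    names += [f"b{i + 1}{i + 1}" for i in range(k)]
    return names


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Second-order model matrix for coded points ``(n, k)``."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)]
    cols += [coded[:, i] for i in range(k)]
    cols += [
        coded[:, i] * coded[:, j] for i in range(k) for j in range(i + 1, k)
    ]
    cols += [coded[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass
class FittedRSM:
    """An OLS-fitted quadratic response surface on coded factors."""

    response_name: str
    k: int
    coefficients: dict[str, float]
    n_runs: int
    n_params: int
    mse: float
    hat_diagonal: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    observed: np.ndarray
    f_model: float
    p_model: float

    @property
    def beta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))


@dataclass(frozen=True)
class DiagnosticsReport:
    """R^2 family, precision, and dispersion diagnostics of a fit."""

    R2: float
    adj_R2: float
    pred_R2: float
    PRESS: float
    CV_pct: float
    adeq_precision: float
    F_model: float
    p_model: float


def fit_quadratic_rsm(design: DesignTable, response_name: str) -> FittedRSM:
    """Fit the full quadratic model to one response of a design table.

    Parameters
    ----------
    design :
        Design with coded factor levels and the named response present.
    response_name :
        Key into ``design.responses``.

    Raises
    ------
    ValueError
        If there are fewer runs than model terms, or the model matrix is
        rank deficient (fewer distinct design points than parameters).
    """
    y = design.response(response_name)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"response {response_name!r} contains non-finite values")
    X = model_matrix(design.coded)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need >= {p} runs to fit {p} terms, have {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design: fewer distinct points than terms")

    res = sm.OLS(y, X).fit()
    influence = res.get_influence()
    names = term_names(design.k)
    return FittedRSM(
        response_name=response_name,
        k=design.k,
        coefficients=dict(zip(names, res.params)),
        n_runs=n,
        n_params=p,
        mse=float(res.mse_resid),
        hat_diagonal=np.asarray(influence.hat_matrix_diag),
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        observed=np.asarray(y, dtype=float),
        f_model=float(res.fvalue),
        p_model=float(res.f_pvalue),
    )


def predict_response(model: FittedRSM, point) -> float:
    """Evaluate the fitted polynomial at one coded point."""
    point = np.asarray(point, dtype=float)
    if point.shape != (model.k,):
        raise ValueError(f"point must have {model.k} coded coordinates")
    return float((model_matrix(point[None, :]) @ model.beta)[0])


def compute_diagnostics(model: FittedRSM) -> DiagnosticsReport:
    """Compute the DoE diagnostic suite for a fitted surface.

    Raises
    ------
    ValueError
        If the response mean is zero (CV% undefined) or any leverage is
        >= 1 (the PRESS residual for that point is undefined).
    """
    y = model.observed
    e = model.residuals
    n, p = model.n_runs, model.n_params
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    ybar = y.mean()
    if ybar == 0:
        raise ValueError("zero response mean: CV% undefined")
    h = model.hat_diagonal
    if np.any(h >= 1 - 1e-12):
        raise ValueError("leverage >= 1: PRESS undefined")

    sse = float(e @ e)
    sst = float(((y - ybar) ** 2).sum())
    press = float(((e / (1 - h)) ** 2).sum())
    r2 = 1 - sse / sst
    adj = 1 - (sse / (n - p)) / (sst / (n - 1))
    pred = 1 - press / sst
    cv = 100.0 * np.sqrt(model.mse) / ybar
    adeq = (model.fitted.max() - model.fitted.min()) / np.sqrt(
        p * model.mse / n
    )
    return DiagnosticsReport(
        R2=r2,
        adj_R2=adj,
        pred_R2=pred,
        PRESS=press,
        CV_pct=float(cv),
        adeq_precision=float(adeq),
        F_model=model.f_model,
        p_model=model.p_model,
    )


def press_by_loo(design: DesignTable, response_name: str) -> float:
    """PRESS by n explicit leave-one-out refits.

    Independent of the hat-diagonal shortcut in
    :func:`compute_diagnostics`; the two must agree to numerical
    precision.  Raises if any deleted-point refit is rank deficient
    (e.g. a saturated design).
    """
    y = design.response(response_name)
    X = model_matrix(design.coded)
    n, p = X.shape
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        if np.linalg.matrix_rank(Xi) < p:
            raise ValueError(
                f"rank-deficient refit after deleting run {i}: PRESS undefined"
            )
        beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        press += float((y[i] - X[i] @ beta) ** 2)
    return press
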