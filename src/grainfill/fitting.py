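"""Nonlinear least-squares estimation of the logistic filling curve.

Estimation is deterministic: a linearization-based initial guess followed
by bounded trust-region least squares (scipy ``least_squares``, TRF) with
an analytic Jacobian.  No random restarts are used by default so that a
given series always yields the same fit; a small deterministic multi-start
grid on lnB is available as a fallback for pathological series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataValidationError, FitError
from .model import LogisticParams, logistic_weight

__all__ = ["LogisticFit", "init_params", "fit_logistic", "goodness_of_fit", "fit_units"]

#: default relative tolerance on cost decrease
DEFAULT_TOL = 1e-10
#: default iteration cap for the trust-region solver
DEFAULT_MAX_ITER = 200


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic curve with diagnostics.

    r_squared is computed against the mean-only model on the same points
    (NaN when the observations have zero variance); rmse is the
    root-mean-square residual in grams.
    """

    params: LogisticParams
    r_squared: float
    rmse: float
    n_obs: int
    converged: bool
    n_iter: int


def _as_series(dap, weight) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(dap, dtype=float)
    w = np.asarray(weight, dtype=float)
    if t.shape != w.shape or t.ndim != 1:
        raise DataValidationError("dap and weight must be 1-d and equally long")
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(w)):
        raise DataValidationError("non-finite values in series")
    if np.any(w <= 0):
        raise DataValidationError("weights must be positive")
    return t, w


def init_params(dap, weight) -> LogisticParams:
    """Deterministic starting values from the logit linearization.

    A0 is 1.05x the largest observed weight; B0 and C0 come from ordinary
    least squares on ln(A0/W - 1) = lnB - C t over the points with
    0 < W < A0.  Raises FitError when fewer than 3 points remain or the
    linearized slope is non-negative (no growth signal).
    """
    t, w = _as_series(dap, weight)
    if t.size < 3:
        raise FitError(f"need >= 3 points to initialize, got {t.size}")
    A0 = 1.05 * float(w.max())
    keep = w < A0
    if keep.sum() < 2:
        raise FitError("all points at/above the inflated asymptote guess")
    z = np.log(A0 / w[keep] - 1.0)
    slope, intercept = np.polyfit(t[keep], z, 1)
    C0 = -slope
    if C0 <= 0:
        raise FitError(
            "linearized slope is non-negative: series shows no logistic growth"
        )
    return LogisticParams(A=A0, B=math.exp(intercept), C=C0)


def _residuals(theta: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    A, B, C = theta
    return A / (1.0 + B * np.exp(-C * t)) - w


def _jacobian(theta: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    A, B, C = theta
    e = np.exp(-C * t)
    den = 1.0 + B * e
    J = np.empty((t.size, 3))
    J[:, 0] = 1.0 / den
    J[:, 1] = -A * e / den**2
    J[:, 2] = A * B * t * e / den**2
    return J


def fit_logistic(
    dap,
    weight,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    multistart: bool = False,
) -> LogisticFit:
    """Fit W = A/(1 + B e^{-Ct}) to one observed series.

    Minimizes the sum of squared weight residuals over A, B, C > 0 with a
    trust-region-reflective solver and analytic Jacobian; deterministic
    given the input.  Non-convergence (including unidentifiable series
    such as constant weights) is reported via ``converged=False``, never
    silently and never as an exception.  ``multistart=True`` additionally
    tries a fixed grid of lnB starting values and keeps the best cost.

    Requires at least 4 points (3 parameters + 1 residual df).
    """
    t, w = _as_series(dap, weight)
    if t.size < 4:
        raise FitError(f"need >= 4 points to fit 3 parameters, got {t.size}")

    starts: list[LogisticParams] = []
    init_failed = False
    try:
        starts.append(init_params(t, w))
    except FitError:
        init_failed = True
    if multistart or init_failed:
        A0 = 1.05 * float(w.max())
        span = max(float(t.max() - t.min()), 1.0)
        for lnB in (1.5, 2.5, 3.5, 4.5):
            starts.append(LogisticParams(A=A0, B=math.exp(lnB), C=2.0 * lnB / span))

    best = None
    for p0 in starts:
        res = least_squares(
            _residuals,
            x0=np.array([p0.A, p0.B, p0.C]),
            jac=_jacobian,
            bounds=(np.full(3, 1e-12), np.full(3, np.inf)),
            args=(t, w),
            ftol=tol,
            xtol=tol,
            gtol=tol,
            max_nfev=max_iter * 4,
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None

    A, B, C = (float(v) for v in best.x)
    params = LogisticParams(A=max(A, 1e-12), B=max(B, 1e-12), C=max(C, 1e-12))
    r2, rmse = goodness_of_fit(params, t, w)
    at_boundary = bool(np.any(best.x <= 1e-10))
    converged = bool(best.status > 0) and not init_failed and not at_boundary
    return LogisticFit(
        params=params,
        r_squared=r2,
        rmse=rmse,
        n_obs=int(t.size),
        converged=converged,
        n_iter=int(best.nfev),
    )


def goodness_of_fit(params: LogisticParams, dap, weight) -> tuple[float, float]:
    """(r_squared, rmse) of a fitted curve against its own series.

    r2 = 1 - SS_res/SS_tot with SS_tot about the observed mean; NaN when
    the observations have zero variance (r2 undefined).
    """
    t, w = _as_series(dap, weight)
    resid = logistic_weight(params, t) - w
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((w - w.mean()) ** 2))
    rmse = math.sqrt(ss_res / t.size)
    r2 = math.nan if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return r2, rmse


def fit_units(
    filling: pd.DataFrame,
    per_replicate: bool = True,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> pd.DataFrame:
    """Fit every experimental unit of a long-format filling table.

    ``filling`` needs columns year, tillage, variety, replicate, dap,
    weight.  With ``per_replicate=True`` (default) each
    year x tillage x variety x replicate series is fitted independently;
    otherwise replicate weights are averaged per sampling day and one
    curve is fitted per year x tillage x variety treatment mean.

    Returns one row per fitted unit with columns A, B, C, r_squared, rmse,
    n_obs, converged.
    """
    keys = ["year", "tillage", "variety"] + (["replicate"] if per_replicate else [])
    df = filling
    if not per_replicate:
        df = (
            filling.groupby(keys + ["dap"], sort=True, observed=True)["weight"]
            .mean()
            .reset_index()
        )
    rows = []
    for key, grp in df.groupby(keys, sort=True, observed=True):
        grp = grp.sort_values("dap")
        fit = fit_logistic(grp["dap"], grp["weight"], tol=tol, max_iter=max_iter)
        rows.append(
            dict(zip(keys, key if isinstance(key, tuple) else (key,)))
            | {
                "A": fit.params.A,
                "B": fit.params.B,
                "C": fit.params.C,
                "r_squared": fit.r_squared,
                "rmse": fit.rmse,
                "n_obs": fit.n_obs,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
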