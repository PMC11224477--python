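"""Logistic grain-filling model and its closed-form phase partition.

The 100-grain dry weight of a maize ear follows a sigmoid ("S"-type)
trajectory after pollination, modelled here as the three-parameter logistic

    W(t) = A / (1 + B * exp(-C * t))

with ``t`` days after flowering (t = 0 on the flowering day), ``A`` the
asymptotic 100-grain weight (g), ``B`` a dimensionless shape parameter and
``C`` a rate parameter (1/d).  The filling-rate curve dW/dt is bell-shaped;
its concavity changes (roots of the third derivative of W) delimit a
*gradual* increase phase, a *fast* (peak) phase and a *slow* phase:

    t1 = (ln B - k1) / C      start of the fast phase
    t2 = (ln B + k1) / C      end of the fast phase
    t3 = (ln B + k3) / C      weight reaches 99% of A ("effective filling")

where k1 = ln(2 + sqrt(3)) = 1.31696... and k3 = ln(99) = 4.59512...
Agronomic practice truncates these to 1.317 and 4.59512; both conventions
are supported via the ``constants`` argument (default: the truncated
field-standard values, so printed tables reproduce digit-for-digit).

Per-phase durations T_i, weight gains w_i and mean rates V_i = w_i / T_i
follow in closed form.  Two ratios are parameter-free consequences of the
model: T3/T2 = (k3 - k1)/(2 k1) ~ 1.2446 and V2/V3 ~ 3.569, so relative
treatment effects on V2 and V3 (and on T2 and T3) are always identical
under this model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np

from .errors import (
    DataValidationError,
    DegenerateFitError,
    DegeneratePartitionError,
    InvalidParameterError,
)

__all__ = [
    "K1_EXACT",
    "K3_EXACT",
    "K1_TRUNCATED",
    "K3_TRUNCATED",
    "phase_offsets",
    "LogisticParams",
    "PhaseParameters",
    "RatePoint",
    "logistic_weight",
    "logistic_rate",
    "logistic_acceleration",
    "empirical_rate_series",
    "partition_phases",
    "quadratic_peak",
]

# Offsets delimiting the filling phases, in units of C*t - lnB.
# k1 solves d3W/dt3 = 0 (concavity change of the rate curve);
# k3 solves W(t) = 0.99 A.
K1_EXACT = math.log(2.0 + math.sqrt(3.0))  # 1.3169578969248166
K3_EXACT = math.log(99.0)                  # 4.59511985013459
# Truncated values as printed in agronomic grain-filling tables.
K1_TRUNCATED = 1.317
K3_TRUNCATED = 4.59512


def phase_offsets(constants: str = "truncated") -> tuple[float, float]:
    """Return the (k1, k3) phase offsets for the given convention.

    ``"truncated"`` uses the truncated field-standard constants 1.317 and
    4.59512; ``"exact"`` uses ln(2+sqrt(3)) and ln(99) to full precision.
    """
    if constants == "truncated":
        return K1_TRUNCATED, K3_TRUNCATED
    if constants == "exact":
        return K1_EXACT, K3_EXACT
    raise ValueError(f"constants must be 'truncated' or 'exact', got {constants!r}")


@dataclass(frozen=True)
class LogisticParams:
    """Parameters (A, B, C) of the logistic filling curve.

    A: asymptotic 100-grain weight (g); B: shape (dimensionless);
    C: rate (1/d).  All must be strictly positive; the weight on the
    flowering day is then A/(1+B) < A.
    """

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "C"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(
                    f"logistic parameter {name} must be finite and > 0, got {v!r}"
                )

    @property
    def w0(self) -> float:
        """Model weight on the flowering day, A/(1+B)."""
        return self.A / (1.0 + self.B)

    @property
    def t_max(self) -> float:
        """Time of the maximum instantaneous filling rate, lnB/C (d)."""
        return math.log(self.B) / self.C

    @property
    def g_max(self) -> float:
        """Maximum instantaneous filling rate, A*C/4 (g/d)."""
        return self.A * self.C / 4.0


def logistic_weight(params: LogisticParams, t):
    """100-grain weight W(t) = A / (1 + B e^{-Ct}) in grams.

    ``t`` may be a scalar or array of days after flowering; negative t
    simply evaluates the formula.
    """
    t = np.asarray(t, dtype=float)
    out = params.A / (1.0 + params.B * np.exp(-params.C * t))
    return out if out.ndim else float(out)


def logistic_rate(params: LogisticParams, t):
    """Instantaneous filling rate dW/dt = A B C e^{-Ct} / (1 + B e^{-Ct})^2.

    Positive everywhere; maximal at t = lnB/C where it equals A*C/4.
    """
    t = np.asarray(t, dtype=float)
    s = params.B * np.exp(-params.C * t)
    out = params.A * params.C * s / (1.0 + s) ** 2
    return out if out.ndim else float(out)


def logistic_acceleration(params: LogisticParams, t):
    """Second derivative d2W/dt2 = A C^2 s (s - 1) / (1 + s)^3, s = B e^{-Ct}."""
    t = np.asarray(t, dtype=float)
    s = params.B * np.exp(-params.C * t)
    out = params.A * params.C**2 * s * (s - 1.0) / (1.0 + s) ** 3
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RatePoint:
    """Mean filling rate over one sampling interval (secant slope).

    t_mid is the interval midpoint in days; rate is (W_curr - W_prev)/D in
    g/d.  ``decreasing`` flags an interval whose weight went down (kept,
    never silently dropped).
    """

    t_mid: float
    rate: float
    decreasing: bool = False


def empirical_rate_series(dap, weight) -> list[RatePoint]:
    """Empirical filling rate from consecutive dry-weight samples.

    For each consecutive pair of observations the mean rate over the
    interval is (W_current - W_previous) / D with D the days between
    samples; it is attached to the interval midpoint, which centres the
    secant estimate of the derivative.

    Parameters may be any equal-length sequences of days-after-pollination
    and 100-grain dry weights (g).  dap must be strictly increasing; a
    decreasing weight yields a flagged (negative-rate) point plus a warning.
    """
    dap = np.asarray(dap, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if dap.shape != weight.shape or dap.ndim != 1:
        raise DataValidationError("dap and weight must be 1-d and equally long")
    if dap.size < 2:
        raise DataValidationError("need at least 2 observations to form a rate")
    d = np.diff(dap)
    if np.any(d <= 0):
        bad = int(np.argmax(d <= 0)) + 1
        raise DataValidationError(
            f"dap must be strictly increasing (violation at position {bad})"
        )
    rates = np.diff(weight) / d
    mids = (dap[:-1] + dap[1:]) / 2.0
    points = [
        RatePoint(float(m), float(r), bool(r < 0)) for m, r in zip(mids, rates)
    ]
    n_dec = sum(p.decreasing for p in points)
    if n_dec:
        warnings.warn(
            f"{n_dec} interval(s) with decreasing weight; rates flagged",
            stacklevel=2,
        )
    return points


@dataclass(frozen=True)
class PhaseParameters:
    """Closed-form phase partition of a logistic filling curve.

    Times in days, weights in grams, rates in g/d.  Phase 1 (gradual)
    spans [0, t1], phase 2 (fast) [t1, t2], phase 3 (slow) [t2, t3];
    t3 is where the weight reaches 99% of A.  W0..W3 are model weights at
    the boundaries, w_i the per-phase gains, V_i = w_i / T_i the per-phase
    mean rates; t_max = lnB/C and G_max = A*C/4 locate the rate peak.
    """

    t1: float
    t2: float
    t3: float
    T1: float
    T2: float
    T3: float
    W0: float
    W1: float
    W2: float
    W3: float
    w1: float
    w2: float
    w3: float
    V1: float
    V2: float
    V3: float
    t_max: float
    G_max: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def partition_phases(
    params: LogisticParams, constants: str = "truncated"
) -> PhaseParameters:
    """Partition the filling process into gradual / fast / slow phases.

    The fast-phase boundaries t1, t2 are the roots of the third derivative
    of W (where the rate curve changes concavity) and t3 the 99%-of-A time:

        t1 = (lnB - k1)/C,  t2 = (lnB + k1)/C,  t3 = (lnB + k3)/C.

    Raises DegeneratePartitionError when lnB <= k1, i.e. the gradual phase
    would start at or before flowering.
    """
    k1, k3 = phase_offsets(constants)
    lnB = math.log(params.B)
    if lnB <= k1:
        raise DegeneratePartitionError(
            f"ln(B) = {lnB:.4f} <= {k1}: t1 would be non-positive "
            "(gradual phase starting before flowering)"
        )
    C = params.C
    t1 = (lnB - k1) / C
    t2 = (lnB + k1) / C
    t3 = (lnB + k3) / C
    W0 = params.w0
    W1 = logistic_weight(params, t1)
    W2 = logistic_weight(params, t2)
    W3 = logistic_weight(params, t3)
    T1, T2, T3 = t1, t2 - t1, t3 - t2
    w1, w2, w3 = W1 - W0, W2 - W1, W3 - W2
    return PhaseParameters(
        t1=t1, t2=t2, t3=t3,
        T1=T1, T2=T2, T3=T3,
        W0=W0, W1=W1, W2=W2, W3=W3,
        w1=w1, w2=w2, w3=w3,
        V1=w1 / T1, V2=w2 / T2, V3=w3 / T3,
        t_max=params.t_max, G_max=params.g_max,
    )


def quadratic_peak(points) -> tuple[float, float]:
    """Peak rate and its time from a concave quadratic fit.

    Fits rate = a + b t + c t^2 by ordinary least squares to a sequence of
    RatePoint (or (t, rate) pairs) and returns the vertex
    (x, y) = (-b/(2c), a - b^2/(4c)).  The empirical rate trace of a
    filling series rises then falls, so the fitted parabola must be
    concave (c < 0); otherwise DegenerateFitError is raised.
    """
    pts = list(points)
    if len(pts) < 3:
        raise DataValidationError("need at least 3 rate points for a quadratic")
    if isinstance(pts[0], RatePoint):
        t = np.array([p.t_mid for p in pts])
        r = np.array([p.rate for p in pts])
    else:
        t = np.array([p[0] for p in pts], dtype=float)
        r = np.array([p[1] for p in pts], dtype=float)
    c, b, a = np.polyfit(t, r, 2)
    # concavity must be resolvable above rounding noise of the fit
    c_scale = (np.abs(r).max() + 1e-30) / (np.ptp(t) ** 2 + 1e-30)
    if c >= -1e-9 * c_scale:
        raise DegenerateFitError(
            f"fitted quadratic is not concave (c = {c:.3g}); no interior rate peak"
        )
    x = -b / (2.0 * c)
    y = a - b * b / (4.0 * c)
    return float(x), float(y)
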