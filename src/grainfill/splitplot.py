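"""Designed-experiment statistics for split-plot field trials.

The trial layout is a classical split-plot with replicates as random
blocks: tillage method (M, the hard-to-randomize factor) occupies main
plots, variety (V) occupies subplots.  Two error strata follow:

* Error I  = Block x M interaction, df (r-1)(m-1) — tests M;
* Error II = residual, df m(r-1)(v-1) — tests V and M x V.

Sums of squares are the standard balanced-design quantities computed from
marginal means; unbalanced data are rejected outright (no Type-III
approximation).  Mean separation uses Fisher's LSD at alpha = 0.05 with
compact letter display.  Also provided: the moisture standardization of
air-dry 100-grain weight to 14% moisture, the nitrogen-to-crude-protein
conversion (factor 6.25), and a fertilizer nutrient-total check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, UnbalancedDesignError

__all__ = [
    "moisture_standardize",
    "crude_protein_from_nitrogen",
    "validate_nutrient_totals",
    "splitplot_ss",
    "anova_splitplot",
    "lsd_value",
    "lsd_compare",
    "LsdGrouping",
    "mainplot_within_subplot_se",
]

#: reference moisture content for reporting 100-grain weight
TARGET_MOISTURE = 0.14
#: standard nitrogen-to-protein conversion factor for cereal grain
N_TO_PROTEIN = 6.25

SOURCES = ["Block", "M", "Error I", "V", "M x V", "Error II", "Total"]


def moisture_standardize(air_dry_weight: float, moisture_fraction: float) -> float:
    """Re-express an air-dry 100-grain weight at 14% moisture content.

    Dry matter is preserved: weight_14 = w * (1 - m) / (1 - 0.14).
    """
    if not 0.0 <= moisture_fraction < 1.0:
        raise DataValidationError(
            f"moisture fraction must be in [0, 1), got {moisture_fraction}"
        )
    return air_dry_weight * (1.0 - moisture_fraction) / (1.0 - TARGET_MOISTURE)


def crude_protein_from_nitrogen(total_n_pct: float) -> float:
    """Crude protein % from total (Kjeldahl) nitrogen %, factor 6.25."""
    if total_n_pct < 0:
        raise DataValidationError(f"nitrogen content must be >= 0, got {total_n_pct}")
    return N_TO_PROTEIN * total_n_pct


def validate_nutrient_totals(applications) -> float:
    """Total pure nutrient (kg/ha) from (rate, nutrient fraction) pairs.

    E.g. diammonium phosphate 375 kg/ha at 18% N plus urea 345 kg/ha at
    46% N gives 226.2 kg/ha of pure nitrogen.  Reported to 1 decimal.
    """
    total = 0.0
    for rate, frac in applications:
        if rate < 0:
            raise DataValidationError(f"application rate must be >= 0, got {rate}")
        if not 0.0 <= frac <= 1.0:
            raise DataValidationError(f"nutrient fraction must be in [0,1], got {frac}")
        total += rate * frac
    return round(total, 1)


def splitplot_ss(y: np.ndarray) -> dict[str, float]:
    """Split-plot sums of squares from a (replicate, M, V) response array.

    Pure-numpy core shared by :func:`anova_splitplot` and by power/size
    simulations.  Returns SS for Block, M, Error I, V, M x V, Error II and
    Total; Error II is the residual closing the additivity identity.
    """
    r, m, v = y.shape
    g = y.mean()
    yr = y.mean(axis=(1, 2))
    ym = y.mean(axis=(0, 2))
    yv = y.mean(axis=(0, 1))
    yrm = y.mean(axis=2)
    ymv = y.mean(axis=0)
    ss_block = m * v * float(np.sum((yr - g) ** 2))
    ss_m = r * v * float(np.sum((ym - g) ** 2))
    ss_e1 = v * float(np.sum((yrm - yr[:, None] - ym[None, :] + g) ** 2))
    ss_v = r * m * float(np.sum((yv - g) ** 2))
    ss_mv = r * float(np.sum((ymv - ym[:, None] - yv[None, :] + g) ** 2))
    ss_tot = float(np.sum((y - g) ** 2))
    ss_e2 = ss_tot - (ss_block + ss_m + ss_e1 + ss_v + ss_mv)
    return {
        "Block": ss_block,
        "M": ss_m,
        "Error I": ss_e1,
        "V": ss_v,
        "M x V": ss_mv,
        "Error II": max(ss_e2, 0.0),
        "Total": ss_tot,
    }


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pivot_balanced(records: pd.DataFrame, value_col: str = "value") -> np.ndarray:
    """Arrange long-format records into a (replicate, M, V) array.

    Requires exactly one observation per tillage x variety x replicate
    cell; raises UnbalancedDesignError otherwise.  Factor levels are taken
    in sorted order.
    """
    needed = {"tillage", "variety", "replicate", value_col}
    missing = needed - set(records.columns)
    if missing:
        raise DataValidationError(f"missing columns: {sorted(missing)}")
    piv = records.pivot_table(
        index="replicate",
        columns=["tillage", "variety"],
        values=value_col,
        aggfunc="count",
        fill_value=0,
    )
    if piv.size == 0 or not (piv.to_numpy() == 1).all():
        raise UnbalancedDesignError(
            "split-plot ANOVA needs exactly one observation per "
            "tillage x variety x replicate cell"
        )
    reps = sorted(records["replicate"].unique())
    ms = sorted(records["tillage"].unique())
    vs = sorted(records["variety"].unique())
    idx = records.set_index(["replicate", "tillage", "variety"])[value_col]
    y = np.empty((len(reps), len(ms), len(vs)))
    for i, rr in enumerate(reps):
        for j, mm in enumerate(ms):
            for k, vv in enumerate(vs):
                y[i, j, k] = idx.loc[(rr, mm, vv)]
    return y


def anova_splitplot(records: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Split-plot ANOVA table for one trait in one year.

    ``records`` is long-format with columns tillage, variety, replicate
    and the response; the design must be balanced with r >= 2 replicates.
    Returns a table indexed by source (Block, M, Error I, V, M x V,
    Error II, Total) with df, SS, MS, F, p and a significance mark
    (** p<0.01, * p<0.05, ns).  F(M) uses Error I; F(V) and F(M x V) use
    Error II.  Zero error variance yields NaN F with mark ''.
    """
    y = pivot_balanced(records, value_col)
    r, m, v = y.shape
    if r < 2:
        raise UnbalancedDesignError("need at least 2 replicates")
    ss = splitplot_ss(y)
    df = {
        "Block": r - 1,
        "M": m - 1,
        "Error I": (r - 1) * (m - 1),
        "V": v - 1,
        "M x V": (m - 1) * (v - 1),
        "Error II": m * (r - 1) * (v - 1),
        "Total": r * m * v - 1,
    }
    ms = {s: (ss[s] / df[s] if s != "Total" and df[s] > 0 else np.nan) for s in SOURCES}
    out = pd.DataFrame(index=pd.Index(SOURCES, name="source"))
    out["df"] = [df[s] for s in SOURCES]
    out["SS"] = [ss[s] for s in SOURCES]
    out["MS"] = [ms[s] for s in SOURCES]
    F = {s: np.nan for s in SOURCES}
    p = {s: np.nan for s in SOURCES}
    tests = {"M": "Error I", "V": "Error II", "M x V": "Error II"}
    for src, err in tests.items():
        if ms[err] and np.isfinite(ms[err]) and ms[err] > 0:
            F[src] = ms[src] / ms[err]
            p[src] = float(stats.f.sf(F[src], df[src], df[err]))
    out["F"] = [F[s] for s in SOURCES]
    out["p"] = [p[s] for s in SOURCES]
    out["sig"] = ["" if s not in tests else _stars(p[s]) for s in SOURCES]
    return out


def lsd_value(error_ms: float, error_df: float, r_effective: float,
              alpha: float = 0.05) -> float:
    """Fisher's least significant difference.

    LSD = t_{1-alpha/2, df} * sqrt(2 * MS_error / r_effective) where
    r_effective is the number of observations behind each compared mean.
    """
    if error_ms <= 0:
        raise DataValidationError(f"error MS must be > 0, got {error_ms}")
    if error_df < 1:
        raise DataValidationError(f"error df must be >= 1, got {error_df}")
    if r_effective <= 0:
        raise DataValidationError(f"r_effective must be > 0, got {r_effective}")
    if not 0.0 < alpha < 1.0:
        raise DataValidationError(f"alpha must be in (0,1), got {alpha}")
    t = stats.t.ppf(1.0 - alpha / 2.0, error_df)
    return float(t * math.sqrt(2.0 * error_ms / r_effective))


@dataclass(frozen=True)
class LsdGrouping:
    """Compact-letter display of an LSD mean comparison.

    ``table`` has one row per level (descending mean) with columns level,
    mean, letters; two levels share a letter iff their means differ by at
    most ``lsd``.
    """

    table: pd.DataFrame
    lsd: float
    alpha: float
    error_df: float


def lsd_compare(level_means, error_ms: float, error_df: float,
                r_effective: float, alpha: float = 0.05) -> LsdGrouping:
    """LSD mean separation with letters assigned by a descending sweep.

    ``level_means`` maps level label -> mean (dict or Series).  Starting
    from the largest mean, each letter covers the maximal run of
    consecutive (sorted) means within one LSD of the run's top member;
    runs that add no new level are skipped.
    """
    means = pd.Series(level_means, dtype=float).sort_values(ascending=False)
    lsd = lsd_value(error_ms, error_df, r_effective, alpha)
    n = len(means)
    letters = [""] * n
    vals = means.to_numpy()
    next_letter = 0
    covered_until = -1
    for i in range(n):
        j = i
        while j + 1 < n and vals[i] - vals[j + 1] <= lsd:
            j += 1
        if j > covered_until or i == 0:
            ch = chr(ord("a") + next_letter)
            next_letter += 1
            for k in range(i, j + 1):
                letters[k] += ch
            covered_until = j
        if covered_until == n - 1:
            break
    table = pd.DataFrame(
        {"level": means.index, "mean": vals, "letters": letters}
    ).reset_index(drop=True)
    return LsdGrouping(table=table, lsd=lsd, alpha=alpha, error_df=error_df)


def mainplot_within_subplot_se(
    ms_error1: float,
    df_error1: float,
    ms_error2: float,
    df_error2: float,
    n_subplot_levels: int,
    replicates: int,
) -> tuple[float, float]:
    """Standard error (and Satterthwaite df) for comparing two main-plot
    (tillage) means at a fixed subplot (variety) level.

    Such comparisons mix both error strata:
    se^2 = 2[(v-1) MS_EII + MS_EI] / (r v); the df follow Satterthwaite.
    Used for within-variety tillage letters; pass ``ms_error2`` = Error II
    MS etc.  Returns (se_diff, df).
    """
    v, r = n_subplot_levels, replicates
    num = (v - 1) * ms_error2 + ms_error1
    if num <= 0:
        raise DataValidationError("non-positive combined error")
    se2 = 2.0 * num / (r * v)
    df = num**2 / (
        ((v - 1) * ms_error2) ** 2 / df_error2 + ms_error1**2 / df_error1
    )
    return math.sqrt(se2), float(df)
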