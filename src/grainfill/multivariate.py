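"""Trait multivariate statistics: Pearson correlation, correlation-matrix
PCA, and stepwise multiple regression.

These link the fitted filling-rate parameters (V1-V3, T1-T3) to grain
quality traits (protein, starch, fat, soluble sugar).  Correlation
p-values are unadjusted (no multiple-testing correction).  Stepwise
selection is the classical forward-entry / backward-elimination scheme on
partial-F p-values with entry threshold ``sle`` and stay threshold
``sls``; the defaults sle = sls = 0.15 follow the convention of the
common statistical packages for this procedure (which retains terms with
p around 0.08-0.15 rather than enforcing 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, DegenerateFitError

__all__ = [
    "pearson_matrix",
    "PcaResult",
    "pca_correlation",
    "RegressionModel",
    "stepwise_regression",
]

DEFAULT_SLE = 0.15
DEFAULT_SLS = 0.15


def _check_table(table: pd.DataFrame, min_rows: int = 3) -> pd.DataFrame:
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] != table.shape[1]:
        bad = sorted(set(table.columns) - set(num.columns))
        raise DataValidationError(f"non-numeric columns: {bad}")
    if table.isna().any().any():
        raise DataValidationError("table contains missing cells")
    if len(table) < min_rows:
        raise DataValidationError(f"need >= {min_rows} rows, got {len(table)}")
    sd = table.std(ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise DataValidationError(f"zero-variance column(s): {zero}")
    return table


def pearson_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    Returns (r, p) DataFrames over the table's columns; r is symmetric
    with unit diagonal, p comes from t = r sqrt((n-2)/(1-r^2)) on n-2 df
    (NaN on the diagonal).
    """
    table = _check_table(table)
    cols = table.columns
    n = len(table)
    r = np.corrcoef(table.to_numpy(), rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    np.fill_diagonal(p, np.nan)
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


@dataclass(frozen=True)
class PcaResult:
    """Correlation-matrix PCA.

    ``loadings``: variables x components eigenvectors of the correlation
    matrix, sign-fixed so each component's largest-|loading| entry is
    positive.  ``explained``: eigenvalue fractions lambda_i / p summing
    to 1.  ``scores``: standardized data projected on the components.
    ``eigenvalues``: the eigenvalues themselves (sum = number of
    variables).
    """

    loadings: pd.DataFrame
    explained: np.ndarray
    scores: pd.DataFrame
    eigenvalues: np.ndarray = field(repr=False, default=None)


def pca_correlation(table: pd.DataFrame) -> PcaResult:
    """PCA on the correlation matrix (variables standardized internally)."""
    table = _check_table(table)
    cols = table.columns
    X = table.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):  # sign convention: dominant loading > 0
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    pcs = [f"PC{i + 1}" for i in range(len(cols))]
    return PcaResult(
        loadings=pd.DataFrame(evecs, index=cols, columns=pcs),
        explained=evals / evals.sum(),
        scores=pd.DataFrame(Z @ evecs, index=table.index, columns=pcs),
        eigenvalues=evals,
    )


@dataclass(frozen=True)
class RegressionModel:
    """A fitted (possibly stepwise-selected) linear model.

    ``terms`` has one row per term (Intercept first) with columns variate,
    coef, se, F, p — F is the squared t of the coefficient, i.e. the
    partial F on 1 numerator df, and p its upper tail on (1, n-k) df.
    """

    terms: pd.DataFrame
    selected: list[str]
    r_squared: float
    n_obs: int
    sse: float


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with intercept column included in X.

    Returns (beta, se, sse, df_resid); collinear X raises LinAlgError.
    """
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank-deficient")
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df = n - k
    sigma2 = sse / df if df > 0 else np.nan
    se = np.sqrt(np.diag(np.linalg.inv(xtx)) * sigma2)
    return beta, se, sse, df


def _fit_report(y, X, names) -> RegressionModel:
    beta, se, sse, df = _ols(y, X)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (beta / se) ** 2
    p = stats.f.sf(F, 1, df)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    terms = pd.DataFrame(
        {"variate": ["Intercept"] + names, "coef": beta, "se": se, "F": F, "p": p}
    )
    return RegressionModel(
        terms=terms, selected=list(names), r_squared=r2, n_obs=len(y), sse=sse
    )


def stepwise_regression(
    y,
    X: pd.DataFrame,
    sle: float = DEFAULT_SLE,
    sls: float = DEFAULT_SLS,
    forward_only: bool = False,
) -> RegressionModel:
    """Forward-with-backward-elimination stepwise linear regression.

    At each step the candidate with the smallest partial-F p-value enters
    if p <= ``sle``; then any included variable with p > ``sls`` (largest
    first) is removed; iterate to a fixed point.  Exactly collinear
    candidates are skipped with a warning; revisiting an earlier model
    terminates the loop (cycle guard).  The final model is refitted by
    ordinary least squares and reported with coefficient, SE, partial F
    and p per term.
    """
    y = np.asarray(y, dtype=float).ravel()
    if isinstance(X, pd.DataFrame):
        names_all = list(X.columns)
        Xmat = X.to_numpy(dtype=float)
    else:
        Xmat = np.asarray(X, dtype=float)
        names_all = [f"x{i + 1}" for i in range(Xmat.shape[1])]
    n, p_all = Xmat.shape
    if len(y) != n:
        raise DataValidationError("y and X row counts differ")
    if n < 3:
        raise DataValidationError("need at least 3 observations")

    included: list[str] = []
    seen = {tuple()}
    sst = float(np.sum((y - y.mean()) ** 2))
    # below this residual the fit is exact to rounding noise and partial-F
    # statistics are meaningless: stop entering, drop redundant terms
    exact_sse = 1e-12 * sst

    def design(names):
        cols = [np.ones(n)] + [Xmat[:, names_all.index(nm)] for nm in names]
        return np.column_stack(cols)

    def sse_of(names) -> float:
        beta, *_ = np.linalg.lstsq(design(names), y, rcond=None)
        resid = y - design(names) @ beta
        return float(resid @ resid)

    import warnings as _warnings

    if sst == 0.0:
        return _fit_report(y, design([]), [])

    while True:
        changed = False
        cur_sse = sse_of(included)
        # forward step: best candidate by partial-F p-value
        if cur_sse > exact_sse:
            best_name, best_p = None, np.inf
            for nm in names_all:
                if nm in included:
                    continue
                try:
                    mdl = _fit_report(y, design(included + [nm]), included + [nm])
                except np.linalg.LinAlgError:
                    _warnings.warn(
                        f"candidate {nm!r} is collinear; skipped", stacklevel=2
                    )
                    continue
                pv = mdl.terms.set_index("variate").loc[nm, "p"]
                if np.isfinite(pv) and pv < best_p:
                    best_name, best_p = nm, pv
            if best_name is not None and best_p <= sle:
                included.append(best_name)
                changed = True
        # backward step
        if not forward_only:
            while included:
                if sse_of(included) <= exact_sse:
                    # exact fit: remove any term whose exclusion keeps it exact
                    redundant = next(
                        (
                            nm for nm in included
                            if sse_of([m for m in included if m != nm]) <= exact_sse
                        ),
                        None,
                    )
                    if redundant is None:
                        break
                    included.remove(redundant)
                    changed = True
                    continue
                mdl = _fit_report(y, design(included), included)
                pv = mdl.terms.set_index("variate").loc[included, "p"]
                worst = pv.idxmax()
                if pv[worst] > sls:
                    included.remove(worst)
                    changed = True
                else:
                    break
        key = tuple(sorted(included))
        if not changed:
            break
        if key in seen:  # cycle guard: same model revisited
            break
        seen.add(key)

    return _fit_report(y, design(included), included)
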