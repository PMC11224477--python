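"""End-to-end analysis pipeline: fit -> partition -> ANOVA/LSD -> multivariate.

Chains the package's stages the way the field trial is analyzed: logistic
fits per experimental unit, closed-form phase partition of each fit,
split-plot ANOVA per trait and year with LSD letters for tillage within
each variety, and the multivariate layer (Pearson correlations,
correlation PCA, stepwise regression of quality on filling rates) on the
per-treatment feature table.
"""

from __future__ import annotations

import pandas as pd

from .errors import DataValidationError
from .fitting import fit_units
from .io import RunConfig
from .model import LogisticParams, partition_phases
from .multivariate import pca_correlation, pearson_matrix, stepwise_regression
from .splitplot import anova_splitplot, lsd_compare, mainplot_within_subplot_se

__all__ = [
    "phase_table",
    "anova_by_year",
    "tillage_letters",
    "feature_table",
    "run_report",
]

UNIT_KEYS = ["year", "tillage", "variety", "replicate"]
TREATMENT_KEYS = ["year", "tillage", "variety"]

QUALITY_TRAITS = {
    "crude_protein_pct": "Protein",
    "total_starch_pct": "Starch",
    "crude_fat_pct": "Fat",
    "soluble_sugar_pct": "Sugar",
}


def phase_table(fits: pd.DataFrame, constants: str = "truncated") -> pd.DataFrame:
    """Phase parameters for every fitted unit (adds t1..G_max columns)."""
    rows = []
    for r in fits.itertuples():
        p = partition_phases(LogisticParams(r.A, r.B, r.C), constants=constants)
        rows.append(p.as_dict())
    return pd.concat([fits.reset_index(drop=True), pd.DataFrame(rows)], axis=1)


def anova_by_year(
    records: pd.DataFrame, value_col: str = "value"
) -> dict[int, pd.DataFrame]:
    """Split-plot ANOVA separately per year (years are never pooled)."""
    return {
        int(year): anova_splitplot(grp, value_col=value_col)
        for year, grp in records.groupby("year", sort=True)
    }


def tillage_letters(
    records: pd.DataFrame,
    anova: pd.DataFrame,
    value_col: str = "value",
    alpha: float = 0.05,
    combined_error: bool = True,
) -> dict[str, object]:
    """LSD letter groups for tillage means within each variety.

    Comparing tillage (main-plot) levels at a fixed variety mixes the two
    error strata, so by default the combined standard error with
    Satterthwaite df is used; ``combined_error=False`` falls back to the
    naive Error II-only LSD.
    """
    ms1 = anova.loc["Error I", "MS"]
    df1 = anova.loc["Error I", "df"]
    ms2 = anova.loc["Error II", "MS"]
    df2 = anova.loc["Error II", "df"]
    varieties = sorted(records["variety"].unique())
    reps = records["replicate"].nunique()
    out = {}
    for var in varieties:
        sub = records[records["variety"] == var]
        means = sub.groupby("tillage")[value_col].mean()
        if combined_error:
            se, df = mainplot_within_subplot_se(
                ms1, df1, ms2, df2, len(varieties), reps
            )
            # passing (MS=se^2/2, r=1) makes lsd_compare's sqrt(2*MS/r)
            # equal the combined-stratum se, so LSD = t(df) * se_diff
            grouping = lsd_compare(means, error_ms=se**2 / 2.0,
                                   error_df=df, r_effective=1.0, alpha=alpha)
        else:
            grouping = lsd_compare(means, error_ms=ms2, error_df=df2,
                                   r_effective=reps, alpha=alpha)
        out[var] = grouping
    return out


def feature_table(
    phases: pd.DataFrame, traits: pd.DataFrame, weight_col: str = "A"
) -> pd.DataFrame:
    """Per-treatment feature table for the multivariate layer.

    Rows are year x tillage x variety treatment means; columns are Y (the
    fitted asymptotic 100-grain dry weight), the phase rates/durations
    V1-V3 and T1-T3, and the quality traits Protein, Starch, Fat, Sugar.
    """
    ft = (
        phases.groupby(TREATMENT_KEYS, sort=True)[
            [weight_col, "V1", "V2", "V3", "T1", "T2", "T3"]
        ]
        .mean()
        .rename(columns={weight_col: "Y"})
    )
    qual = traits[traits["trait"].isin(QUALITY_TRAITS)]
    if len(qual):
        wide = (
            qual.groupby(TREATMENT_KEYS + ["trait"], sort=True)["value"]
            .mean()
            .unstack("trait")
            .rename(columns=QUALITY_TRAITS)
        )
        ft = ft.join(wide, how="inner")
    if ft.isna().any().any():
        raise DataValidationError("feature table has missing cells")
    return ft


def run_report(
    filling: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> dict[str, object]:
    """Run the full analysis and return every artifact as an object.

    Returns a dict with fits, phases, per-trait ANOVA tables
    ('anova', keyed (trait, year)), LSD letters keyed (trait, year,
    variety), the feature table, correlation r/p matrices, the PCA result
    and the stepwise regressions of Starch and Fat on (V1, V2, V3).
    """
    config = config or RunConfig()
    fits = fit_units(
        filling,
        per_replicate=config.per_replicate,
        tol=config.fit_tol,
        max_iter=config.fit_max_iter,
    )
    phases = phase_table(fits, constants=config.constants)
    out: dict[str, object] = {"fits": fits, "phases": phases}

    anovas: dict[tuple, pd.DataFrame] = {}
    letters: dict[tuple, object] = {}
    if config.per_replicate:
        for year, tab in anova_by_year(phases, value_col="A").items():
            anovas[("fitted_A", year)] = tab
            sub = phases[phases["year"] == year]
            for var, grp in tillage_letters(
                sub, tab, value_col="A",
                alpha=config.alpha, combined_error=config.lsd_combined_error,
            ).items():
                letters[("fitted_A", year, var)] = grp
    if traits is not None and len(traits):
        for trait, tgrp in traits.groupby("trait", sort=True):
            for year, tab in anova_by_year(tgrp).items():
                anovas[(str(trait), year)] = tab
                sub = tgrp[tgrp["year"] == year]
                for var, grp in tillage_letters(
                    sub, tab,
                    alpha=config.alpha, combined_error=config.lsd_combined_error,
                ).items():
                    letters[(str(trait), year, var)] = grp
    out["anova"] = anovas
    out["lsd"] = letters

    if traits is not None and config.per_replicate:
        ft = feature_table(phases, traits)
        out["features"] = ft
        r, p = pearson_matrix(ft)
        out["pearson_r"], out["pearson_p"] = r, p
        out["pca"] = pca_correlation(ft)
        rates = ft[["V1", "V2", "V3"]]
        regs = {}
        for resp in ("Starch", "Fat"):
            if resp in ft.columns:
                regs[resp] = stepwise_regression(
                    ft[resp], rates, sle=config.sle, sls=config.sls
                )
        out["stepwise"] = regs
    return out
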