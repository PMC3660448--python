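"""Extreme-phenotype study design: covariate adjustment and tail selection.

Three agonist-induced aggregation phenotypes (collagen, epinephrine, ADP;
percent aggregation, 0-100) are adjusted for clinical covariates by
ordinary least squares within each ancestry stratum.  Subjects whose
residuals fall strictly above the stratum's third quartile on *all three*
phenotypes are hyper-aggregators; strictly below the first quartile on all
three, hypo-aggregators; everyone else is unselected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from extremevar.errors import DesignError

logger = logging.getLogger(__name__)

PHENOTYPES = ("pheno_col", "pheno_epi", "pheno_adp")
COVARIATES = ("age", "sex", "diabetes", "hypertension", "bmi", "ldl", "smoking", "fibrinogen")


def adjust_phenotype(
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    covariate_names=COVARIATES,
) -> pd.Series:
    """OLS residuals of one phenotype on the clinical covariates.

    Rows with any missing covariate or phenotype are excluded (their
    residual is NaN) and the exclusion count is logged.  Constant
    (zero-variance) covariates are dropped with a warning; the intercept
    is always included, so in the all-constant limit the residuals are the
    phenotype minus its mean.
    """
    cov = covariates.loc[phenotype.index, list(covariate_names)].astype(float)
    ok = phenotype.notna() & cov.notna().all(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("adjust_phenotype: excluding %d rows with missing values", n_drop)
    y = phenotype[ok].astype(float)
    X = cov[ok]
    if len(y) == 0:
        raise DesignError("no complete-case rows for adjustment")
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = sorted(set(X.columns) - set(keep))
    if dropped:
        logger.warning("adjust_phenotype: dropping constant covariates %s", dropped)
    X = sm.add_constant(X[keep], has_constant="add")
    fit = sm.OLS(y, X).fit()
    res = pd.Series(np.nan, index=phenotype.index, name=f"res_{phenotype.name}")
    res[ok] = fit.resid
    return res


def adjust_cohort(cohort: pd.DataFrame, phenotypes=PHENOTYPES, covariates=COVARIATES) -> pd.DataFrame:
    """Adjust all phenotypes within each stratum; returns the cohort with
    residual columns ``res_<phenotype>`` appended."""
    out = cohort.copy()
    for ph in phenotypes:
        out[f"res_{ph}"] = np.nan
        for label, grp in cohort.groupby("stratum"):
            res = adjust_phenotype(grp[ph], grp, covariates)
            out.loc[grp.index, f"res_{ph}"] = res
    return out


def select_extremes(
    residuals: pd.DataFrame,
    quartile: float = 0.25,
    residual_cols=None,
    stratum_col: str = "stratum",
) -> pd.Series:
    """Label subjects ``hyper`` / ``hypo`` / ``unselected`` from residuals.

    Quartiles are empirical quantiles with linear interpolation, computed
    within stratum over subjects with all residuals present; selection uses
    strict inequalities, so a residual exactly at the quartile is not
    selected.  ``hyper`` and ``hypo`` are disjoint for quartile < 0.5.

    Raises
    ------
    DesignError
        If a stratum has fewer than 8 subjects with complete residuals.
    """
    if not 0 < quartile < 0.5:
        raise ValueError("quartile must lie in (0, 0.5)")
    if residual_cols is None:
        residual_cols = [f"res_{p}" for p in PHENOTYPES]
    group = pd.Series("unselected", index=residuals.index, name="group")
    for label, grp in residuals.groupby(stratum_col):
        complete = grp[residual_cols].notna().all(axis=1)
        sub = grp.loc[complete, residual_cols]
        if len(sub) < 8:
            raise DesignError(f"stratum {label!r} has {len(sub)} complete subjects (<8)")
        lo = sub.quantile(quartile, interpolation="linear")
        hi = sub.quantile(1 - quartile, interpolation="linear")
        hyper = (sub > hi).all(axis=1)
        hypo = (sub < lo).all(axis=1)
        group.loc[sub.index[hyper]] = "hyper"
        group.loc[sub.index[hypo]] = "hypo"
    return group


def read_cohort(path) -> pd.DataFrame:
    """Read the tab-separated phenotype/covariate table."""
    cohort = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "stratum": str})
    required = {"subject_id", "stratum", *PHENOTYPES, *COVARIATES}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return cohort.set_index("subject_id", drop=False)


def write_selection(cohort: pd.DataFrame, path) -> None:
    cols = ["subject_id", "stratum", "group"] + [f"res_{p}" for p in PHENOTYPES]
    cohort[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
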