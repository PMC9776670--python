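"""eGFR-slope prognosis analysis for IgA nephropathy cohorts.

Per patient, kidney-function decline is summarised as the slope of an
ordinary least-squares fit of eGFR over time, restricted to visits within
two years of the biopsy (closed at t = 2).  The slope is then regressed on
six prognostic variables — age at biopsy, sex (male = 1), pre-biopsy
hypertension (present = 1), eGFR at biopsy, UPCR at biopsy, and the
slide-level sclerotic proportion — with every predictor z-scored (sample
SD, ddof = 1), including the binaries, so the coefficients are standardized
partial regression coefficients in eGFR-slope units per predictor SD.  The
outcome is left in its natural units (mL/min/1.73 m²/yr); pass
``standardize_outcome=True`` for the fully-standardized convention.
Multicollinearity is screened with variance inflation factors.

Eligibility mirrors typical IgAN prognosis studies: adults (≥ 18 y at
biopsy), not in end-stage renal failure at biopsy (eGFR ≥ 15, plus any
explicit end-stage flag), and at least one year of eGFR follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    InvalidInputError,
    MulticollinearityError,
    UndefinedResultError,
)
from .synthetic import PREDICTOR_COLUMNS

__all__ = [
    "RegressionReport",
    "filter_eligible",
    "egfr_slope",
    "patient_slopes",
    "fit_prognosis_model",
    "vif",
]

_COHORT_COLUMNS = {"patient_id", "visit_time_yr", "egfr"}


def _per_patient(long_df: pd.DataFrame) -> pd.DataFrame:
    static = [c for c in long_df.columns if c not in ("visit_time_yr", "egfr")]
    return long_df.groupby("patient_id", as_index=False)[static].first()


def filter_eligible(
    long_df: pd.DataFrame,
    min_age: float = 18.0,
    min_egfr: float = 15.0,
    min_followup_years: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop ineligible patients from a visit-level cohort table.

    Exclusions, counted per criterion in the returned log: age at biopsy
    below `min_age`; end-stage renal failure at biopsy (baseline eGFR below
    `min_egfr`, or a truthy ``end_stage`` column if present); eGFR follow-up
    shorter than `min_followup_years`.
    """
    missing = _COHORT_COLUMNS - set(long_df.columns)
    if missing:
        raise InvalidInputError(f"cohort table missing columns {sorted(missing)}")
    g = long_df.groupby("patient_id")
    age = g["age"].first() if "age" in long_df.columns else None
    followup = g["visit_time_yr"].max()
    if "egfr0" in long_df.columns:
        egfr0 = g["egfr0"].first()
    else:  # fall back to the measurement at the earliest visit
        egfr0 = long_df.sort_values("visit_time_yr").groupby("patient_id")["egfr"].first()

    excluded: dict[str, pd.Index] = {}
    excluded["age_lt_min"] = (
        age.index[age < min_age] if age is not None else pd.Index([])
    )
    end_stage = egfr0 < min_egfr
    if "end_stage" in long_df.columns:
        end_stage = end_stage | g["end_stage"].first().astype(bool)
    excluded["end_stage_at_biopsy"] = egfr0.index[end_stage]
    excluded["followup_lt_min"] = followup.index[followup < min_followup_years]

    drop = pd.Index([]).union(excluded["age_lt_min"]).union(
        excluded["end_stage_at_biopsy"]
    ).union(excluded["followup_lt_min"])
    log = {k: int(len(v)) for k, v in excluded.items()}
    log["excluded_total"] = int(len(drop))
    log["eligible"] = int(long_df["patient_id"].nunique() - len(drop))
    return long_df[~long_df["patient_id"].isin(drop)].copy(), log


def egfr_slope(times_yr, egfr, window_years: float = 2.0) -> float:
    """OLS slope of eGFR over time for visits with t ≤ `window_years` (closed).

    Units: mL/min/1.73 m² per year.  Needs at least two visits at distinct
    times inside the window.
    """
    t = np.asarray(times_yr, dtype=float)
    y = np.asarray(egfr, dtype=float)
    keep = t <= window_years
    t, y = t[keep], y[keep]
    if t.size < 2 or np.ptp(t) == 0:
        raise UndefinedResultError(
            f"need ≥ 2 eGFR measurements at distinct times within {window_years} years"
        )
    tc = t - t.mean()
    return float((tc * (y - y.mean())).sum() / (tc ** 2).sum())


def patient_slopes(long_df: pd.DataFrame, window_years: float = 2.0) -> pd.DataFrame:
    """Per-patient table with covariates plus the fitted `egfr_slope` column."""
    patients = _per_patient(long_df)
    slopes = (
        long_df.groupby("patient_id")
        .apply(
            lambda d: egfr_slope(d["visit_time_yr"], d["egfr"], window_years),
            include_groups=False,
        )
        .rename("egfr_slope")
    )
    return patients.merge(slopes, on="patient_id")


def _zscore_frame(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=1)
    bad = sd[sd == 0].index.tolist()
    if bad:
        raise InvalidInputError(f"constant predictor columns: {bad}")
    return (X - X.mean()) / sd


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 − R²ⱼ).

    R²ⱼ comes from regressing predictor j on all the others (with
    intercept).  Perfectly collinear predictors are flagged as ``inf``.
    """
    X = predictors.astype(float)
    if X.shape[1] < 2:
        raise InvalidInputError("VIF needs at least two predictors")
    if (X.std(ddof=1) == 0).any():
        raise InvalidInputError("VIF undefined for constant predictors")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        fit = sm.OLS(X[col].to_numpy(), others).fit()
        r2 = min(fit.rsquared, 1.0)
        out[col] = float("inf") if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class RegressionReport:
    """Standardized-beta regression table plus model-level fit statistics."""

    table: pd.DataFrame  # index: variables; columns: beta, se, p, vif
    raw_table: pd.DataFrame  # same, on the predictors' natural scale
    r_squared: float
    n: int
    outcome: str = "egfr_slope"

    def to_json_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "r_squared": self.r_squared,
            "n": self.n,
            "variables": {
                var: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for var, row in self.table.to_dict("index").items()
            },
        }

    def formatted(self) -> pd.DataFrame:
        """Display table with "beta (SE)" cells, p and VIF columns."""
        return pd.DataFrame(
            {
                "beta (SE)": [
                    f"{b:.3f} ({s:.3f})" for b, s in zip(self.table["beta"], self.table["se"])
                ],
                "p": [f"{p:.3g}" for p in self.table["p"]],
                "VIF": [f"{v:.1f}" for v in self.table["vif"]],
            },
            index=self.table.index,
        )


def fit_prognosis_model(
    patient_df: pd.DataFrame,
    predictors: tuple[str, ...] = PREDICTOR_COLUMNS,
    outcome: str = "egfr_slope",
    standardize_outcome: bool = False,
) -> RegressionReport:
    """Multivariate OLS of the eGFR slope on the six prognostic variables.

    Predictors (binaries included) are z-scored before fitting, so each
    beta is the expected change in eGFR slope per SD of that predictor,
    holding the others fixed.  Reports beta ± SE, two-sided per-coefficient
    t-test p-values, VIF per predictor, and model R².
    """
    missing = [c for c in (*predictors, outcome) if c not in patient_df.columns]
    if missing:
        raise InvalidInputError(f"missing columns: {missing}")
    df = patient_df.dropna(subset=[*predictors, outcome])
    n = len(df)
    if n <= len(predictors) + 1:
        raise InvalidInputError(
            f"need n > {len(predictors) + 1} complete cases, have {n}"
        )
    X = df[list(predictors)].astype(float)
    y = df[outcome].astype(float).to_numpy()

    rank = np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(axis=0))
    if rank < X.shape[1]:
        corr = X.corr().abs()
        dep: set[str] = set()
        for i, a in enumerate(predictors):
            for b in predictors[i + 1:]:
                if corr.loc[a, b] > 1 - 1e-10:
                    dep.update((a, b))
        raise MulticollinearityError(sorted(dep) or list(predictors))

    Z = _zscore_frame(X)
    if standardize_outcome:
        y = (y - y.mean()) / y.std(ddof=1)
    design = sm.add_constant(Z.to_numpy())
    fit = sm.OLS(y, design).fit()
    beta = fit.params[1:]
    se = fit.bse[1:]
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=fit.df_resid)

    vifs = vif(Z)
    table = pd.DataFrame(
        {"beta": beta, "se": se, "p": pvals, "vif": vifs[list(predictors)].to_numpy()},
        index=list(predictors),
    )

    raw_design = sm.add_constant(X.to_numpy())
    raw_fit = sm.OLS(df[outcome].astype(float).to_numpy(), raw_design).fit()
    raw_table = pd.DataFrame(
        {"beta": raw_fit.params[1:], "se": raw_fit.bse[1:], "p": raw_fit.pvalues[1:]},
        index=list(predictors),
    )
    return RegressionReport(
        table=table,
        raw_table=raw_table,
        r_squared=float(fit.rsquared),
        n=n,
        outcome=outcome,
    )
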