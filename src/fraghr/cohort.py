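"""Cohort regression program: transforms, standardized OLS fits, change-score
models, nested-model likelihood-ratio tests, quadratic age trends and
quartile descriptive tables.

Conventions
-----------
* Skewed variables are natural-log transformed; a registry records which
  received ln(x) and which ln(x+1) (the zero-inflated subset).
* Continuous independent variables are standardized to mean 0, SD 1 over
  their non-missing rows, so coefficients read as the expected score
  difference per one-SD increment of the predictor.  Outcomes are left on
  their native scale.
* Fits are ordinary least squares on complete cases with t-based 95% CIs.
* Change-score models regress dY = Y2 − Y1 on Y1 plus exposure and
  covariates; this is algebraically equivalent to regressing Y2 on the same
  design (all slopes equal; the Y1 coefficient differs by exactly 1).
* The likelihood-ratio test compares nested OLS fits on identical rows with
  the Gaussian likelihood; the statistic equals n·ln(RSS_base/RSS_ext).

Significance is read at p < 0.05 (two-sided), with p < 0.1 considered
borderline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LOG_VARIABLES",
    "LOG1P_VARIABLES",
    "MODEL_COVARIATES",
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "transform_variables",
    "standardize",
    "fit_model",
    "fit_change_model",
    "likelihood_ratio_test",
    "quadratic_age_trend",
    "quartile_table",
]

#: skewed variables receiving ln(x)
LOG_VARIABLES = ("rmssd", "sdnn", "hf", "physical_activity", "nt_probnp")
#: zero-inflated variables receiving ln(x + 1)
LOG1P_VARIABLES = ("pack_years", "pct_time_spo2_lt90", "odi", "cac")

#: nested covariate sets of the five adjustment models; change-score models
#: additionally include the baseline score
MODEL_COVARIATES: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("caide_apoe4",),
    3: ("age", "race_ethnicity", "male", "education"),
    4: (
        "age", "race_ethnicity", "male", "education",
        "apoe4", "antihypertensive_med", "lipid_med", "systolic_bp",
        "diabetes", "total_cholesterol", "hdl", "pack_years",
        "alcohol_use", "physical_activity", "depression",
        "antidepressant_med", "income_ge_75k", "avnn", "prevalent_cve_af",
    ),
    5: (
        "age", "race_ethnicity", "male", "education",
        "apoe4", "antihypertensive_med", "lipid_med", "systolic_bp",
        "diabetes", "total_cholesterol", "hdl", "pack_years",
        "alcohol_use", "physical_activity", "depression",
        "antidepressant_med", "income_ge_75k", "avnn", "prevalent_cve_af",
        "nt_probnp",
    ),
}

#: categorical covariates expanded to indicator columns when present
CATEGORICAL_COVARIATES = ("race_ethnicity", "education")


@dataclass
class ModelSpec:
    """One regression to run: outcome, exposure and adjustment set."""

    model_id: int
    outcome: str
    exposure: str
    covariates: tuple[str, ...] | None = None
    change_score: bool = False

    def __post_init__(self) -> None:
        if self.covariates is None:
            if self.model_id not in MODEL_COVARIATES:
                raise ValueError(f"unknown model_id {self.model_id}")
            self.covariates = MODEL_COVARIATES[self.model_id]
        self.covariates = tuple(self.covariates)


@dataclass
class FitResult:
    """OLS fit summary with per-term inference."""

    terms: pd.DataFrame  # term, estimate, ci_low, ci_high, p
    n: int
    r_squared: float
    adj_r_squared: float
    log_likelihood: float
    residual_sd: float
    rss: float
    row_index: pd.Index
    exog_names: tuple[str, ...]
    model_id: int | None = None
    outcome: str | None = None

    def coef(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.terms.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of two nested OLS fits."""

    statistic: float
    df: int
    p_value: float
    base_model: int | None = None
    extended_model: int | None = None


def transform_variables(
    cohort: pd.DataFrame, registry: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Apply the natural-log transform registry to the skewed variables.

    Columns in ``LOG_VARIABLES`` get ln(x); the zero-inflated columns in
    ``LOG1P_VARIABLES`` get ln(x+1).  Only columns present in the table are
    touched.  Returns the transformed table and the registry of applied
    transforms ``{column: 'ln' | 'ln1p'}``.
    """
    out = cohort.copy()
    applied: dict[str, str] = {}
    plan = registry or {
        **{c: "ln" for c in LOG_VARIABLES},
        **{c: "ln1p" for c in LOG1P_VARIABLES},
    }
    for col, kind in plan.items():
        if col not in out.columns:
            continue
        x = out[col].astype(float)
        shifted = x if kind == "ln" else x + 1.0
        bad = shifted <= 0
        if bad.any():
            idx = out.index[bad][0]
            raise ValueError(
                f"non-positive value in column {col!r} at row {idx}: "
                "cannot log-transform"
            )
        out[col] = np.log(shifted)
        applied[col] = kind
    return out, applied


def standardize(
    cohort: pd.DataFrame, variables: list[str] | tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score the given columns over non-missing rows.

    Returns the standardized table and a scaling registry (variable, mean,
    sd) so per-SD coefficients can be mapped back to native units.
    """
    out = cohort.copy()
    recs = []
    for col in variables:
        x = out[col].astype(float)
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"zero or undefined SD for column {col!r}")
        out[col] = (x - mean) / sd
        recs.append({"variable": col, "mean": mean, "sd": sd})
    return out, pd.DataFrame(recs)


def _design(cohort: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    """Build the exog matrix, expanding known categoricals to indicators."""
    parts = []
    for col in columns:
        if col in CATEGORICAL_COVARIATES and not pd.api.types.is_numeric_dtype(
            cohort[col]
        ):
            dummies = pd.get_dummies(
                cohort[col], prefix=col, drop_first=True, dtype=float
            )
            parts.append(dummies)
        else:
            parts.append(cohort[[col]].astype(float))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cohort.index)
    return sm.add_constant(X, has_constant="add")


def _fit_ols(
    y: pd.Series, X: pd.DataFrame, model_id: int | None, outcome: str | None
) -> FitResult:
    mask = y.notna() & X.notna().all(axis=1)
    y_, X_ = y[mask], X[mask]
    n, k = X_.shape
    if n < k + 10:
        raise ValueError(f"too few complete cases (n={n}) for {k} parameters")
    rank = np.linalg.matrix_rank(X_.to_numpy())
    if rank < k:
        raise ValueError(
            f"rank-deficient design ({rank} < {k}); collinear terms among "
            f"{list(X_.columns)}"
        )
    res = sm.OLS(y_.to_numpy(float), X_.to_numpy(float)).fit()
    ci = res.conf_int(alpha=0.05)
    terms = pd.DataFrame(
        {
            "term": list(X_.columns),
            "estimate": res.params,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": res.pvalues,
        }
    )
    rss = float(np.sum(res.resid**2))
    return FitResult(
        terms=terms,
        n=int(n),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        log_likelihood=float(res.llf),
        residual_sd=float(np.sqrt(res.scale)),
        rss=rss,
        row_index=y_.index,
        exog_names=tuple(X_.columns),
        model_id=model_id,
        outcome=outcome,
    )


def fit_model(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the OLS regression of ``spec.outcome`` on exposure + covariates.

    Complete-case: rows missing any involved column are dropped.  Dispatches
    to :func:`fit_change_model` when ``spec.change_score`` is set.
    """
    if spec.change_score:
        return fit_change_model(cohort, spec)
    cols = (spec.exposure, *spec.covariates) if spec.exposure else spec.covariates
    X = _design(cohort, cols)
    return _fit_ols(cohort[spec.outcome], X, spec.model_id, spec.outcome)


def fit_change_model(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    baseline: str | None = None,
    followup: str | None = None,
) -> FitResult:
    """Regress the score change (exam 2 − exam 1) on baseline + exposure +
    covariates.

    ``spec.outcome`` names the follow-up score column unless ``followup`` is
    given; ``baseline`` defaults to the conventional pairing
    ``<outcome>_exam1`` / ``<outcome>_exam2`` when the outcome carries an
    exam suffix, else must be passed explicitly.
    """
    y2_col = followup or spec.outcome
    if baseline is None:
        if y2_col.endswith("_exam2"):
            baseline = y2_col[: -len("_exam2")] + "_exam1"
        else:
            raise ValueError("baseline score column must be specified")
    delta = cohort[y2_col] - cohort[baseline]
    cols = (baseline, spec.exposure, *spec.covariates)
    X = _design(cohort, cols)
    res = _fit_ols(delta, X, spec.model_id, f"delta_{y2_col}")
    return res


def likelihood_ratio_test(base: FitResult, extended: FitResult) -> LRTResult:
    """Gaussian likelihood-ratio test of two nested OLS fits.

    Both fits must use the identical rows and the base design must be a
    subset of the extended one.  The statistic 2·(ll_ext − ll_base) equals
    n·ln(RSS_base/RSS_ext); the p-value comes from the chi-square
    distribution with df = added-parameter count.
    """
    if len(base.row_index) != len(extended.row_index) or not base.row_index.equals(
        extended.row_index
    ):
        raise ValueError("fits must use identical rows")
    if not set(base.exog_names) <= set(extended.exog_names):
        raise ValueError("models are not nested")
    df = len(extended.exog_names) - len(base.exog_names)
    stat = max(2.0 * (extended.log_likelihood - base.log_likelihood), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    if df == 0:
        p = 1.0
    return LRTResult(
        statistic=float(stat),
        df=int(df),
        p_value=p,
        base_model=base.model_id,
        extended_model=extended.model_id,
    )


def quadratic_age_trend(
    cohort: pd.DataFrame, metric: str, age_col: str = "age"
) -> dict:
    """OLS fit of ``metric`` on age and age² with a pointwise 95% CI band.

    Returns a dict with the fit (terms ``const``, ``age``, ``age2``), a grid
    of ages, the fitted curve and its confidence band derived from the
    coefficient covariance.
    """
    df = cohort[[age_col, metric]].dropna()
    if len(df) < 10:
        raise ValueError("need at least 10 observations for the quadratic fit")
    age = df[age_col].to_numpy(float)
    X = np.column_stack([np.ones_like(age), age, age**2])
    res = sm.OLS(df[metric].to_numpy(float), X).fit()
    grid = np.linspace(age.min(), age.max(), 100)
    Xg = np.column_stack([np.ones_like(grid), grid, grid**2])
    pred = Xg @ res.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, res.cov_params(), Xg))
    tcrit = stats.t.ppf(0.975, res.df_resid)
    ci = res.conf_int(alpha=0.05)
    return {
        "coefficients": dict(zip(("const", "age", "age2"), res.params)),
        "p_values": dict(zip(("const", "age", "age2"), res.pvalues)),
        "ci": {k: tuple(ci[i]) for i, k in enumerate(("const", "age", "age2"))},
        "age_grid": grid,
        "fitted": pred,
        "band_low": pred - tcrit * se,
        "band_high": pred + tcrit * se,
        "n": int(res.nobs),
    }


def _quartile_assign(x: np.ndarray) -> np.ndarray:
    """Quartile index (0-3) at the empirical 25/50/75 percentiles, ties to
    the lower quartile."""
    cuts = np.percentile(x, [25, 50, 75])
    return np.searchsorted(cuts, x, side="left")


def quartile_table(
    cohort: pd.DataFrame,
    by: str,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Descriptive table across quartiles of an exposure.

    Continuous variables are summarised as mean (SD) per quartile with a
    one-way ANOVA p-value; categoricals as count (%) per quartile with a
    chi-square p-value.  Returns a tidy frame (variable, statistic per
    quartile, p_value, test).
    """
    df = cohort.dropna(subset=[by]).copy()
    if len(df) < 8:
        raise ValueError("need at least 8 subjects for quartiles")
    df["_q"] = _quartile_assign(df[by].to_numpy(float))
    continuous = continuous or []
    categorical = categorical or []
    rows = []
    for var in continuous:
        groups = [
            df.loc[df["_q"] == q, var].dropna().to_numpy(float) for q in range(4)
        ]
        valid = [g for g in groups if g.size > 1]
        p = float(stats.f_oneway(*valid).pvalue) if len(valid) >= 2 else float("nan")
        row = {"variable": var, "test": "anova", "p_value": p}
        for q, g in enumerate(groups):
            row[f"q{q + 1}_mean"] = float(np.mean(g)) if g.size else float("nan")
            row[f"q{q + 1}_sd"] = float(np.std(g, ddof=1)) if g.size > 1 else float("nan")
        rows.append(row)
    for var in categorical:
        tab = pd.crosstab(df["_q"], df[var])
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            p = float(stats.chi2_contingency(tab.to_numpy())[1])
        else:
            p = float("nan")
        row = {"variable": var, "test": "chi2", "p_value": p}
        for q in range(4):
            sub = df.loc[df["_q"] == q, var]
            n_pos = int((sub == sub.max()).sum()) if len(sub) else 0
            row[f"q{q + 1}_n"] = int(len(sub))
        rows.append(row)
    return pd.DataFrame(rows)


def two_group_compare(
    cohort: pd.DataFrame, group: str, variable: str, categorical: bool = False
) -> float:
    """Two-group comparison p-value: Mann-Whitney for continuous variables,
    chi-square for categoricals."""
    df = cohort.dropna(subset=[group, variable])
    levels = sorted(df[group].unique())
    if len(levels) != 2:
        raise ValueError("grouping variable must have exactly two levels")
    if categorical:
        tab = pd.crosstab(df[group], df[variable])
        return float(stats.chi2_contingency(tab.to_numpy())[1])
    a = df.loc[df[group] == levels[0], variable].to_numpy(float)
    b = df.loc[df[group] == levels[1], variable].to_numpy(float)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
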