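"""Nested-adjustment linear regressions for the exposure-outcome program.

Four exposure families (age-specific BMI z-scores, residualised BMI change,
excess-bodyweight duration per decade, cumulative BMI-years per SD) are each
related to standardised midlife cognition under three nested covariate sets:

* model 1 -- age at midlife assessment and sex;
* model 2 -- model 1 + childhood cognitive function (factor score);
* model 3 -- model 2 + mother's and father's BMI, birthweight, household
  overcrowding, socioeconomic status, and highest education (indicator-coded).

Attenuation of an exposure coefficient from model 1 to model 3 is the
package's fingerprint of confounding by early-life factors.  Fits run per
cohort or pooled with cohort indicators, on a single dataset or across an
imputed set with Rubin pooling.  The tertile-trajectory analysis regresses
age-specific BMI z-scores on childhood-cognition tertiles to trace the
divergence of weight trajectories by early cognitive ability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .impute import ImputedSet, pool_rubin

MODEL1_COVARIATES = ["age_midlife", "sex"]
MODEL2_EXTRA = ["cog_child_score"]
MODEL3_EXTRA = ["mother_bmi", "father_bmi", "birthweight", "overcrowding", "ses", "education"]
CATEGORICAL_COVARIATES = {"education"}   # indicator-coded; others enter numerically


class ModelLevel(str, Enum):
    model1 = "model1"
    model2 = "model2"
    model3 = "model3"


@dataclass(frozen=True)
class AdjustmentModel:
    """One of the three nested covariate sets."""

    level: ModelLevel

    @property
    def covariates(self) -> list[str]:
        cov = list(MODEL1_COVARIATES)
        if self.level in (ModelLevel.model2, ModelLevel.model3):
            cov += MODEL2_EXTRA
        if self.level is ModelLevel.model3:
            cov += MODEL3_EXTRA
        return cov


@dataclass
class RegressionEstimate:
    """One cell of the exposure x adjustment-model estimate grid."""

    exposure: str
    outcome: str
    model_level: str
    beta: float
    se: float
    ci_lo: float
    ci_hi: float
    p: float
    n_effective: float
    pooled_cohorts: bool = False

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not (self.ci_lo <= self.beta <= self.ci_hi):
            raise ValueError("CI must contain the point estimate")


def _design(data: pd.DataFrame, exposure: str, covariates: list[str],
            add_cohort: bool) -> tuple[np.ndarray, list[str]]:
    cols = [data[exposure].to_numpy(float)]
    names = [exposure]
    for c in covariates:
        if c in CATEGORICAL_COVARIATES:
            d = pd.get_dummies(data[c].astype("category"), prefix=c, drop_first=True)
            for dc in d.columns:
                cols.append(d[dc].to_numpy(float))
                names.append(str(dc))
        else:
            cols.append(data[c].to_numpy(float))
            names.append(c)
    if add_cohort:
        d = pd.get_dummies(data["cohort"].astype("category"), prefix="cohort", drop_first=True)
        for dc in d.columns:
            cols.append(d[dc].to_numpy(float))
            names.append(str(dc))
    X = np.column_stack([np.ones(len(data))] + cols)
    return X, ["const"] + names


def _fit_single(data: pd.DataFrame, outcome: str, exposure: str,
                covariates: list[str], add_cohort: bool):
    X, names = _design(data, exposure, covariates, add_cohort)
    y = data[outcome].to_numpy(float)
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    Xo, yo = X[ok], y[ok]
    rank = np.linalg.matrix_rank(Xo)
    if rank < Xo.shape[1]:
        # name the offending columns for the error message
        _, r = np.linalg.qr(Xo)
        bad = [names[j] for j in range(len(names)) if abs(r[j, j]) < 1e-8]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear terms: {bad}")
    fit = sm.OLS(yo, Xo).fit()
    return fit, int(ok.sum())


def fit_adjusted(
    data: pd.DataFrame | ImputedSet,
    outcome: str,
    exposure: str,
    model: AdjustmentModel | ModelLevel | str,
    add_cohort: bool = False,
) -> RegressionEstimate:
    """OLS of a standardised outcome on one exposure under a nested model.

    With an :class:`ImputedSet`, the model is fitted in every completed
    dataset and the exposure coefficient combined by Rubin's rules with
    Barnard-Rubin degrees of freedom; otherwise a single Wald fit is
    returned.
    """
    if not isinstance(model, AdjustmentModel):
        model = AdjustmentModel(ModelLevel(model))
    cov = model.covariates
    if isinstance(data, ImputedSet):
        betas, variances, ns = [], [], []
        for df in data.datasets:
            fit, n = _fit_single(df, outcome, exposure, cov, add_cohort)
            betas.append(fit.params[1])
            variances.append(fit.bse[1] ** 2)
            ns.append(n)
        df_com = ns[0] - len(fit.params)
        pooled = pool_rubin(betas, variances, df_complete=df_com)
        return RegressionEstimate(
            exposure=exposure, outcome=outcome, model_level=model.level.value,
            beta=pooled.beta, se=pooled.se, ci_lo=pooled.ci_lo, ci_hi=pooled.ci_hi,
            p=pooled.p, n_effective=float(np.mean(ns)), pooled_cohorts=add_cohort,
        )
    fit, n = _fit_single(data, outcome, exposure, cov, add_cohort)
    ci = fit.conf_int()[1]
    return RegressionEstimate(
        exposure=exposure, outcome=outcome, model_level=model.level.value,
        beta=float(fit.params[1]), se=float(fit.bse[1]),
        ci_lo=float(ci[0]), ci_hi=float(ci[1]), p=float(fit.pvalues[1]),
        n_effective=float(n), pooled_cohorts=add_cohort,
    )


def fit_pooled(
    data: pd.DataFrame | ImputedSet,
    outcome: str,
    exposure: str,
    model: AdjustmentModel | ModelLevel | str,
) -> RegressionEstimate:
    """Pooled-cohort fit: same nested model plus cohort indicator covariates."""
    frame = data.datasets[0] if isinstance(data, ImputedSet) else data
    if frame["cohort"].nunique() < 2:
        raise ValueError("single-cohort input: use fit_adjusted without pooling")
    return fit_adjusted(data, outcome, exposure, model, add_cohort=True)


def estimate_grid(
    data: pd.DataFrame | ImputedSet,
    outcome: str,
    exposures: list[str],
    levels=("model1", "model2", "model3"),
    pooled: bool = True,
) -> pd.DataFrame:
    """Long-format table of estimates: one row per (exposure, model level)."""
    rows = []
    for exp in exposures:
        for lev in levels:
            est = (fit_pooled if pooled else fit_adjusted)(data, outcome, exp, lev)
            rows.append(dict(
                exposure=est.exposure, outcome=est.outcome, model=est.model_level,
                beta=est.beta, se=est.se, ci_lo=est.ci_lo, ci_hi=est.ci_hi,
                p=est.p, n=est.n_effective, pooled=est.pooled_cohorts,
            ))
    return pd.DataFrame(rows)


def tertile_trajectories(
    data: pd.DataFrame,
    z_columns: list[str],
    tertile_col: str = "cog_tertile",
    adjustment: list[str] | None = None,
) -> pd.DataFrame:
    """Adjusted mean BMI z-score per (childhood-cognition tertile, age).

    For each age's z-score column, regress z on tertile indicators plus the
    adjustment covariates; the emitted values are predicted means per tertile
    with other covariates held at their sample means, with 95% CIs.  Empty
    tertile-age cells produce missing rows with a warning.
    """
    import warnings as _w

    adjustment = adjustment or ["sex"]
    records = []
    for col in z_columns:
        sub = data[[col, tertile_col] + adjustment].dropna()
        for t in (1.0, 2.0, 3.0):
            if (sub[tertile_col] == t).sum() == 0:
                _w.warn(f"empty tertile {t:g} for {col}")
                records.append(dict(age_column=col, tertile=t, mean=np.nan,
                                    ci_lo=np.nan, ci_hi=np.nan, n=0))
        d2 = pd.get_dummies(pd.Categorical(sub[tertile_col], categories=[1.0, 2.0, 3.0]),
                            prefix="t", drop_first=True).astype(float)
        X = np.column_stack([np.ones(len(sub)), d2.to_numpy(),
                             sub[adjustment].to_numpy(float)])
        fit = sm.OLS(sub[col].to_numpy(float), X).fit()
        covbar = sub[adjustment].mean().to_numpy(float)
        for i, t in enumerate((1.0, 2.0, 3.0)):
            if (sub[tertile_col] == t).sum() == 0:
                continue
            xrow = np.concatenate([[1.0],
                                   np.eye(3)[i, 1:],      # dummy row for tertile t
                                   covbar])
            mean = float(xrow @ fit.params)
            se = float(np.sqrt(xrow @ fit.cov_params() @ xrow))
            records.append(dict(age_column=col, tertile=t, mean=mean,
                                ci_lo=mean - 1.96 * se, ci_hi=mean + 1.96 * se,
                                n=int((sub[tertile_col] == t).sum())))
    return pd.DataFrame(records)


def plot_tertile_trajectories(traj: pd.DataFrame, ages, path=None):
    """Figure-style line graph: one line per tertile across the nominal ages."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {1.0: "tab:red", 2.0: "tab:green", 3.0: "tab:blue"}
    labels = {1.0: "lowest tertile", 2.0: "middle tertile", 3.0: "highest tertile"}
    cols = list(dict.fromkeys(traj["age_column"]))
    for t in (1.0, 2.0, 3.0):
        sub = traj[traj["tertile"] == t].set_index("age_column").loc[cols]
        ax.plot(ages, sub["mean"], marker="o", color=colors[t], label=labels[t])
        ax.fill_between(ages, sub["ci_lo"], sub["ci_hi"], color=colors[t], alpha=0.15)
    ax.axhline(0.0, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("BMI z-score (predicted mean)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
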