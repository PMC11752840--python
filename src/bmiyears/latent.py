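"""Latent general cognitive ability (g) from small test batteries.

Childhood cognition is measured by four tests (verbal reasoning, non-verbal
reasoning, mathematics, reading) at ages 10-11, midlife cognition by four
tests (immediate recall, delayed recall, animal naming, letter-search speed)
at ages 47-53.  Each battery is summarised by a single-factor model

    x_j = lambda_j * g + e_j,    Var(g) = 1,  Var(e_j) = psi_j,

fitted by maximum likelihood on internally standardised indicators.  Factor
scores use the regression (Thomson) method, which has a natural conditional
form when some of a person's indicators are missing.  Scores can then be cut
into tertiles for the trajectory analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize


class HeywoodError(RuntimeError):
    """A uniqueness collapsed to (near) zero during estimation."""


@dataclass
class LatentModel:
    """A fitted one-factor measurement model on standardised indicators."""

    indicator_names: list[str]
    loadings: np.ndarray          # standardised-metric loadings
    uniquenesses: np.ndarray      # residual variances, standardised metric
    means: np.ndarray             # raw-scale means used for standardisation
    sds: np.ndarray               # raw-scale SDs used for standardisation
    loglik: float
    loglik_independence: float
    n_used: int
    converged: bool
    factor_variance: float = 1.0

    def implied_cov(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.uniquenesses)

    def to_json(self) -> str:
        return json.dumps(
            dict(
                indicator_names=list(self.indicator_names),
                loadings=self.loadings.tolist(),
                uniquenesses=self.uniquenesses.tolist(),
                means=self.means.tolist(),
                sds=self.sds.tolist(),
                loglik=self.loglik,
                loglik_independence=self.loglik_independence,
                n_used=self.n_used,
                converged=self.converged,
            ),
            indent=2,
        )

    @classmethod
    def from_json(cls, s: str) -> "LatentModel":
        d = json.loads(s)
        return cls(
            indicator_names=d["indicator_names"],
            loadings=np.asarray(d["loadings"]),
            uniquenesses=np.asarray(d["uniquenesses"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            loglik=d["loglik"],
            loglik_independence=d["loglik_independence"],
            n_used=d["n_used"],
            converged=d["converged"],
        )


def _pairwise_cov(z: np.ndarray) -> tuple[np.ndarray, int]:
    """Pairwise-complete covariance of standardised data, and min pair count."""
    p = z.shape[1]
    S = np.empty((p, p))
    nmin = z.shape[0]
    for i in range(p):
        for j in range(i, p):
            ok = np.isfinite(z[:, i]) & np.isfinite(z[:, j])
            n = int(ok.sum())
            nmin = min(nmin, n)
            if n < 2:
                raise ValueError(f"indicators {i},{j}: <2 complete pairs")
            xi, xj = z[ok, i], z[ok, j]
            S[i, j] = S[j, i] = np.mean((xi - xi.mean()) * (xj - xj.mean()))
    return S, nmin


def fit_one_factor(
    indicator_table: pd.DataFrame,
    min_obs: int = 50,
    gtol: float = 1e-6,
    max_iter: int = 500,
    heywood_tol: float = 1e-3,
) -> LatentModel:
    """ML one-factor model with factor variance fixed to 1.

    Indicators are standardised internally (observed mean/SD, n-1
    denominator) before fitting, since the tests are on incommensurable score
    scales.  The discrepancy minimised is the Wishart ML function
    ``log|Sigma| + tr(S Sigma^-1) - log|S| - p`` with
    ``Sigma = lambda lambda' + diag(psi)``; uniquenesses are log-parametrised
    so they stay positive, and a solution with any uniqueness at (or pressed
    against) zero raises :class:`HeywoodError` naming the indicator.
    Loadings are sign-anchored so the first indicator loads positively.
    """
    names = list(indicator_table.columns)
    x = indicator_table.to_numpy(float)
    p = x.shape[1]
    if p < 4:
        raise ValueError("need at least 4 indicators")
    nobs = np.isfinite(x).sum(axis=0)
    if np.any(nobs < min_obs):
        bad = names[int(np.argmin(nobs))]
        raise ValueError(f"indicator {bad!r} has {nobs.min()} observed values (<{min_obs})")
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(f"indicator {names[int(np.argmin(sd))]!r} is constant")
    z = (x - mu) / sd
    S, n_used = _pairwise_cov(z)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("pairwise-complete covariance is not positive definite")

    def unpack(theta):
        return theta[:p], np.exp(theta[p:])

    def fval_grad(theta):
        lam, psi = unpack(theta)
        Sigma = np.outer(lam, lam) + np.diag(psi)
        Sinv = np.linalg.inv(Sigma)
        sign_m, logdet = np.linalg.slogdet(Sigma)
        f = logdet + np.trace(S @ Sinv) - logdet_S - p
        dF = Sinv - Sinv @ S @ Sinv          # dF/dSigma
        g_lam = 2.0 * dF @ lam
        g_psi = np.diag(dF) * psi            # chain rule through log-parametrisation
        return f, np.concatenate([g_lam, g_psi])

    # principal-component start on the correlation-scale covariance
    w, v = np.linalg.eigh(S)
    lam0 = v[:, -1] * np.sqrt(max(w[-1], 0.1))
    psi0 = np.clip(np.diag(S) - lam0**2, 0.05, None)
    theta0 = np.concatenate([lam0, np.log(psi0)])
    bounds = [(None, None)] * p + [(np.log(1e-8), None)] * p
    res = minimize(
        fval_grad, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options=dict(maxiter=max_iter, gtol=gtol, ftol=0.0),
    )
    gnorm = float(np.max(np.abs(res.jac)))
    lam, psi = unpack(res.x)
    if lam[0] < 0:
        lam = -lam
    # a uniqueness pressed against (near) zero is a Heywood case, whether or
    # not the optimiser formally converged at the bound
    if np.any(psi < heywood_tol):
        bad = names[int(np.argmin(psi))]
        raise HeywoodError(f"Heywood case: uniqueness of {bad!r} collapsed to {psi.min():.2e}")
    if not res.success and gnorm > 1e-4:
        raise RuntimeError(f"one-factor fit did not converge: {res.message}; |grad|={gnorm:.2e}")
    Sigma = np.outer(lam, lam) + np.diag(psi)
    ll = _gauss_loglik(S, Sigma, n_used, p)
    ll0 = _gauss_loglik(S, np.diag(np.diag(S)), n_used, p)
    return LatentModel(
        indicator_names=names, loadings=lam, uniquenesses=psi,
        means=mu, sds=sd, loglik=ll, loglik_independence=ll0,
        n_used=n_used, converged=True,
    )


def _gauss_loglik(S, Sigma, n, p):
    sign, logdet = np.linalg.slogdet(Sigma)
    return float(-0.5 * n * (p * np.log(2 * np.pi) + logdet + np.trace(S @ np.linalg.inv(Sigma))))


def factor_scores(model: LatentModel, indicator_table: pd.DataFrame) -> pd.Series:
    """Regression-method (Thomson) factor scores, missing-tolerant.

    For a person with observed indicator subset o the score is the
    conditional expectation ``E[g | x_o] = lambda_o' Sigma_oo^-1 x_o`` on the
    standardised scale; persons with no observed indicator get a missing
    score.  Scores are re-standardised to mean 0, SD 1 in-sample.
    """
    x = indicator_table[model.indicator_names].to_numpy(float)
    z = (x - model.means) / model.sds
    Sigma = model.implied_cov()
    lam = model.loadings
    n = z.shape[0]
    raw = np.full(n, np.nan)
    obs_mask = np.isfinite(z)
    # group rows by missingness pattern: one solve per pattern
    keys = obs_mask @ (1 << np.arange(z.shape[1]))
    for key in np.unique(keys):
        rows = np.where(keys == key)[0]
        o = np.where(obs_mask[rows[0]])[0]
        if o.size == 0:
            continue
        w = np.linalg.solve(Sigma[np.ix_(o, o)], lam[o])
        raw[rows] = z[np.ix_(rows, o)] @ w
    ok = np.isfinite(raw)
    if ok.sum() >= 2:
        raw[ok] = (raw[ok] - raw[ok].mean()) / raw[ok].std(ddof=1)
    return pd.Series(raw, index=indicator_table.index, name="g_score")


def fit_scores(
    table: pd.DataFrame,
    indicator_cols: list[str],
    by_cohort: bool = True,
) -> tuple[pd.Series, dict[object, LatentModel]]:
    """Fit one-factor models per cohort and return pooled, re-standardised scores.

    Mirrors a harmonised design: each cohort's battery is modelled on its own
    scale, and the resulting scores are pooled and re-standardised for the
    pooled analyses.
    """
    scores = pd.Series(np.nan, index=table.index, dtype=float)
    models: dict[object, LatentModel] = {}
    groups = table.groupby("cohort", observed=True) if by_cohort else [("all", table)]
    for name, g in groups:
        m = fit_one_factor(g[indicator_cols])
        models[name] = m
        scores.loc[g.index] = factor_scores(m, g[indicator_cols]).to_numpy()
    ok = scores.notna()
    if ok.sum() >= 2:
        scores[ok] = (scores[ok] - scores[ok].mean()) / scores[ok].std(ddof=1)
    return scores, models


def tertile_split(
    scores: pd.Series,
    cohort: pd.Series | None = None,
    min_stratum: int = 3,
) -> pd.Series:
    """Cut scores into empirical tertiles (1 = lowest, 3 = highest).

    Cut-points are the 1/3 and 2/3 empirical quantiles, within cohort when a
    cohort series is supplied.  Values exactly at a cut-point fall into the
    lower tertile.  Degenerate strata (too few scores, or coincident
    cut-points from tied data) raise.
    """
    out = pd.Series(np.nan, index=scores.index, dtype=float)
    if cohort is None:
        strata = [("all", scores.index)]
    else:
        strata = [(k, idx) for k, idx in scores.groupby(cohort, observed=True).groups.items()]
    for name, idx in strata:
        vals = scores.loc[idx]
        obs = vals.dropna()
        if len(obs) < min_stratum:
            raise ValueError(f"stratum {name!r}: only {len(obs)} scores")
        q1, q2 = np.quantile(obs.to_numpy(), [1 / 3, 2 / 3])
        if q1 == q2:
            raise ValueError(f"stratum {name!r}: tertile cut-points coincide (tied scores)")
        out.loc[idx] = 1.0 + (vals > q1).astype(float) + (vals > q2).astype(float)
    out[scores.isna()] = np.nan
    return out.rename("cog_tertile")
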