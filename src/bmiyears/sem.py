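"""Cross-lagged latent-variable SEM estimated by full-information ML.

The model is declared as a :class:`SEMSpec`: latent factors with their
indicator blocks, observed structural nodes, directed paths obeying a
temporal ordering (childhood variables -> education -> cumulative exposure
-> midlife variables), exogenous covariates entering every endogenous
equation, and free residual covariances.  Internally the spec compiles to a
RAM parameterisation

    v = A v + u,    Cov(u) = S,    E[u] = m,
    Sigma = F (I-A)^-1 S (I-A)^-T F',   mu = F (I-A)^-1 m,

where ``v`` stacks latents and observed variables and ``F`` selects the
observed rows.  With incomplete data the casewise Gaussian log-likelihood is
maximised over the observed sub-vector of each missingness pattern
(full-information maximum likelihood, valid under MAR); patterns are grouped
and their sufficient statistics cached, so each objective evaluation costs
one pass over distinct patterns rather than over cases.  Gradients are
analytic throughout; standard errors come from the observed information
matrix.  Standardised coefficients, delta-method SEs, product-of-paths
indirect effects and RMSEA/CFI/TLI fit indices are derived from the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

_PENALTY = 1e12


# ---------------------------------------------------------------------------
# model declaration
# ---------------------------------------------------------------------------

@dataclass
class SEMSpec:
    """Declarative measurement + structural model.

    ``edges`` are (from, to) directed paths among latents and observed
    structural nodes.  ``temporal_order`` maps each structural variable to a
    rank; every edge must go strictly forward in rank (covariates are
    unranked and may point anywhere).  ``exogenous_covariates`` get a path
    into every endogenous variable.  ``free_covariances`` are residual
    covariance pairs.
    """

    latents: dict[str, list[str]]
    observed_structural: list[str]
    edges: list[tuple[str, str]]
    exogenous_covariates: list[str] = field(default_factory=list)
    free_covariances: list[tuple[str, str]] = field(default_factory=list)
    temporal_order: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.edges = [tuple(e) for e in self.edges]
        self.free_covariances = [tuple(c) for c in self.free_covariances]
        self.validate()

    # -- structure checks ---------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        for lat, inds in self.latents.items():
            if len(inds) < 2:
                raise ValueError(
                    f"latent {lat!r} needs >=2 indicators to be identified")
            for i in inds:
                if i in seen:
                    raise ValueError(f"indicator {i!r} appears in more than one latent block")
                seen.add(i)
        nodes = set(self.latents) | set(self.observed_structural) | set(self.exogenous_covariates)
        for a, b in self.edges:
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown variable")
        # acyclicity by Kahn's algorithm over the declared edges
        succ: dict[str, set[str]] = {v: set() for v in nodes}
        indeg = {v: 0 for v in nodes}
        for a, b in self.edges:
            if b not in succ[a]:
                succ[a].add(b)
                indeg[b] += 1
        queue = [v for v in nodes if indeg[v] == 0]
        seen_n = 0
        while queue:
            v = queue.pop()
            seen_n += 1
            for w in succ[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if seen_n != len(nodes):
            raise ValueError("edge set contains a cycle")
        if self.temporal_order:
            for a, b in self.edges:
                ra, rb = self.temporal_order.get(a), self.temporal_order.get(b)
                if ra is not None and rb is not None and ra >= rb:
                    raise ValueError(f"edge ({a!r}->{b!r}) violates the temporal ordering")

    # -- derived sets --------------------------------------------------------
    @property
    def endogenous(self) -> list[str]:
        targets = {b for _, b in self.edges}
        order = list(self.latents) + list(self.observed_structural)
        return [v for v in order if v in targets]

    def all_edges(self) -> list[tuple[str, str]]:
        """Declared edges plus the covariate path into every endogenous equation."""
        full = list(self.edges)
        for cov in self.exogenous_covariates:
            for v in self.endogenous:
                if (cov, v) not in full:
                    full.append((cov, v))
        return full

    @property
    def observed_columns(self) -> list[str]:
        cols: list[str] = []
        for inds in self.latents.values():
            cols.extend(inds)
        cols.extend(self.observed_structural)
        cols.extend(self.exogenous_covariates)
        return cols

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        return dict(
            latents={k: list(v) for k, v in self.latents.items()},
            observed_structural=list(self.observed_structural),
            edges=[list(e) for e in self.edges],
            exogenous_covariates=list(self.exogenous_covariates),
            free_covariances=[list(c) for c in self.free_covariances],
            temporal_order=self.temporal_order,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SEMSpec":
        return cls(
            latents=d["latents"],
            observed_structural=d["observed_structural"],
            edges=[tuple(e) for e in d["edges"]],
            exogenous_covariates=d.get("exogenous_covariates", []),
            free_covariances=[tuple(c) for c in d.get("free_covariances", [])],
            temporal_order=d.get("temporal_order"),
        )

    @classmethod
    def from_file(cls, path) -> "SEMSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_DEFAULT_ORDER = {"cog_child": 0, "bmi_child": 0, "education": 1,
                  "exposure": 2, "cog_mid": 3, "bmi_mid": 3}

_DEFAULT_EDGES = [
    ("cog_child", "education"), ("bmi_child", "education"),
    ("cog_child", "exposure"), ("bmi_child", "exposure"), ("education", "exposure"),
    ("cog_child", "cog_mid"), ("bmi_child", "cog_mid"),
    ("education", "cog_mid"), ("exposure", "cog_mid"),
    ("cog_child", "bmi_mid"), ("bmi_child", "bmi_mid"),
    ("education", "bmi_mid"), ("exposure", "bmi_mid"),
]


def default_spec(
    child_tests: list[str],
    mid_tests: list[str],
    covariates: list[str] = ("sex", "overcrowding", "ses"),
) -> SEMSpec:
    """The default cross-lagged model, with the sex/overcrowding/SES block."""
    return SEMSpec(
        latents={"cog_child": list(child_tests), "cog_mid": list(mid_tests)},
        observed_structural=["bmi_child", "education", "exposure", "bmi_mid"],
        edges=list(_DEFAULT_EDGES),
        exogenous_covariates=list(covariates),
        free_covariances=[("cog_child", "bmi_child")],
        temporal_order=dict(_DEFAULT_ORDER),
    )


def core_spec(child_tests: list[str], mid_tests: list[str]) -> SEMSpec:
    """The cross-lagged core without the covariate block (validation model)."""
    return default_spec(child_tests, mid_tests, covariates=[])


# ---------------------------------------------------------------------------
# RAM compilation
# ---------------------------------------------------------------------------

@dataclass
class _Compiled:
    spec: SEMSpec
    variables: list[str]          # latents first, then observed columns
    obs_cols: list[str]
    obs_pos: np.ndarray           # position of each observed column in `variables`
    a_params: list[tuple[str, int, int]]     # (label, row=to, col=from) free A entries
    a_fixed: list[tuple[int, int, float]]    # fixed loading-of-1 entries
    s_params: list[tuple[str, int, int]]
    m_params: list[tuple[str, int]]

    @property
    def n_par(self) -> int:
        return len(self.a_params) + len(self.s_params) + len(self.m_params)


def _compile(spec: SEMSpec) -> _Compiled:
    latents = list(spec.latents)
    obs_cols = spec.observed_columns
    variables = latents + obs_cols
    vidx = {v: i for i, v in enumerate(variables)}
    obs_pos = np.array([vidx[c] for c in obs_cols])

    a_params: list[tuple[str, int, int]] = []
    a_fixed: list[tuple[int, int, float]] = []
    for lat, inds in spec.latents.items():
        a_fixed.append((vidx[inds[0]], vidx[lat], 1.0))  # scale anchor
        for ind in inds[1:]:
            a_params.append((f"{lat}=~{ind}", vidx[ind], vidx[lat]))
    for a, b in spec.all_edges():
        a_params.append((f"{a}->{b}", vidx[b], vidx[a]))

    endo = set(spec.endogenous)
    exo_nodes = [v for v in list(spec.latents) + list(spec.observed_structural)
                 if v not in endo] + list(spec.exogenous_covariates)
    s_params: list[tuple[str, int, int]] = []
    for v in variables:
        s_params.append((f"{v}~~{v}", vidx[v], vidx[v]))
    # free covariances among exogenous (non-indicator) nodes
    for i, a in enumerate(exo_nodes):
        for b in exo_nodes[i + 1:]:
            s_params.append((f"{a}~~{b}", vidx[a], vidx[b]))
    for a, b in spec.free_covariances:
        if (f"{a}~~{b}" not in [p[0] for p in s_params]
                and f"{b}~~{a}" not in [p[0] for p in s_params]):
            s_params.append((f"{a}~~{b}", vidx[a], vidx[b]))

    m_params = [(f"{c}~1", vidx[c]) for c in obs_cols]  # latent intercepts fixed at 0
    return _Compiled(spec=spec, variables=variables, obs_cols=obs_cols, obs_pos=obs_pos,
                     a_params=a_params, a_fixed=a_fixed, s_params=s_params, m_params=m_params)


def _unpack(comp: _Compiled, theta: np.ndarray):
    t = len(comp.variables)
    A = np.zeros((t, t))
    S = np.zeros((t, t))
    m = np.zeros(t)
    k = 0
    for _, i, j in comp.a_params:
        A[i, j] = theta[k]
        k += 1
    for i, j, val in comp.a_fixed:
        A[i, j] = val
    for _, i, j in comp.s_params:
        S[i, j] = theta[k]
        S[j, i] = theta[k]
        k += 1
    for _, i in comp.m_params:
        m[i] = theta[k]
        k += 1
    return A, S, m


# ---------------------------------------------------------------------------
# missingness patterns
# ---------------------------------------------------------------------------

@dataclass
class _Patterns:
    """Per-pattern sufficient statistics, grouped by observed-set size."""

    groups: list[dict]            # each: idx (k,m), w (k,), xbar (k,m), scat (k,m,m)
    n_used: int
    n_patterns: int
    n_dropped: int                # rows with zero observed variables
    p: int


def _extract_patterns(X: np.ndarray) -> _Patterns:
    n, p = X.shape
    obs = np.isfinite(X)
    keys = obs @ (1 << np.arange(p, dtype=object))
    order = np.argsort(keys, kind="stable")
    keys_sorted = keys[order]
    boundaries = np.flatnonzero(np.r_[True, keys_sorted[1:] != keys_sorted[:-1]])
    by_size: dict[int, list] = {}
    n_used = 0
    n_dropped = 0
    n_patterns = 0
    for s, e in zip(boundaries, np.r_[boundaries[1:], len(keys_sorted)]):
        rows = order[s:e]
        o = np.flatnonzero(obs[rows[0]])
        if o.size == 0:
            n_dropped += len(rows)
            continue
        n_patterns += 1
        n_used += len(rows)
        xo = X[np.ix_(rows, o)]
        xbar = xo.mean(axis=0)
        d = xo - xbar
        scat = d.T @ d / len(rows)
        by_size.setdefault(o.size, []).append((o, len(rows), xbar, scat))
    groups = []
    for size, items in by_size.items():
        groups.append(dict(
            idx=np.array([it[0] for it in items]),
            n=np.array([it[1] for it in items], dtype=float),
            xbar=np.array([it[2] for it in items]),
            scat=np.array([it[3] for it in items]),
        ))
    return _Patterns(groups=groups, n_used=n_used, n_patterns=n_patterns,
                     n_dropped=n_dropped, p=p)


def _pattern_loglik(pat: _Patterns, Sigma: np.ndarray, mu: np.ndarray) -> float:
    """FIML log-likelihood of pattern statistics under N(mu, Sigma)."""
    ll = 0.0
    log2pi = np.log(2 * np.pi)
    for grp in pat.groups:
        idx, nw, xbar, scat = grp["idx"], grp["n"], grp["xbar"], grp["scat"]
        sub = Sigma[idx[:, :, None], idx[:, None, :]]
        msub = mu[idx]
        L = np.linalg.cholesky(sub)
        logdet = 2.0 * np.log(np.einsum("kii->ki", L)).sum(axis=1)
        K = np.linalg.inv(sub)
        d = xbar - msub
        tr = np.einsum("kij,kij->k", K, scat)
        quad = np.einsum("ki,kij,kj->k", d, K, d)
        mdim = idx.shape[1]
        ll += float(np.sum(-0.5 * nw * (mdim * log2pi + logdet + tr + quad)))
    return ll


def _fiml_value_grad(pat: _Patterns, Sigma, mu):
    """Scaled deviance f = -2 loglik / n and its gradient wrt (Sigma, mu)."""
    n = pat.n_used
    p = pat.p
    G = np.zeros((p, p))
    g = np.zeros(p)
    f = 0.0
    log2pi = np.log(2 * np.pi)
    for grp in pat.groups:
        idx, nw, xbar, scat = grp["idx"], grp["n"], grp["xbar"], grp["scat"]
        sub = Sigma[idx[:, :, None], idx[:, None, :]]
        msub = mu[idx]
        L = np.linalg.cholesky(sub)            # raises if non-PD (guarded upstream)
        logdet = 2.0 * np.log(np.einsum("kii->ki", L)).sum(axis=1)
        K = np.linalg.inv(sub)
        d = xbar - msub
        Kd = np.einsum("kij,kj->ki", K, d)
        tr = np.einsum("kij,kij->k", K, scat)
        quad = np.einsum("ki,ki->k", d, Kd)
        mdim = idx.shape[1]
        f += float(np.sum(nw * (mdim * log2pi + logdet + tr + quad)))
        w = nw / n
        KSK = np.einsum("kij,kjl,klm->kim", K, scat, K)
        Kdd = np.einsum("ki,kj->kij", Kd, Kd)
        Gc = w[:, None, None] * (K - KSK - Kdd)
        np.add.at(G, (idx[:, :, None], idx[:, None, :]), Gc)
        np.add.at(g, idx, -2.0 * w[:, None] * Kd)
    return f / n, G, g


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitIndices:
    chi2: float
    df: int
    rmsea: float
    cfi: float
    tli: float
    baseline_chi2: float
    baseline_df: int


@dataclass
class SEMResult:
    spec: SEMSpec
    param_names: list[str]
    theta: np.ndarray
    cov_theta: np.ndarray | None
    unstandardized: dict[str, tuple[float, float]]
    standardized: dict[str, tuple[float, float]]
    loadings: dict[str, float]
    fit: FitIndices | None
    loglik: float
    loglik_saturated: float
    loglik_baseline: float
    converged: bool
    n_used: int
    n_patterns: int
    indirect: dict[str, tuple[float, float]] = field(default_factory=dict)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for name, (est, se) in self.unstandardized.items():
            std = self.standardized.get(name, (np.nan, np.nan))
            rows.append(dict(parameter=name, estimate=est, se=se,
                             std_estimate=std[0], std_se=std[1]))
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        out = dict(
            converged=self.converged, loglik=self.loglik,
            loglik_saturated=self.loglik_saturated, loglik_baseline=self.loglik_baseline,
            n_used=self.n_used, n_patterns=self.n_patterns,
            unstandardized={k: list(v) for k, v in self.unstandardized.items()},
            standardized={k: list(v) for k, v in self.standardized.items()},
            loadings=self.loadings,
            indirect={k: list(v) for k, v in self.indirect.items()},
        )
        if self.fit is not None:
            out["fit"] = dict(chi2=self.fit.chi2, df=self.fit.df, rmsea=self.fit.rmsea,
                              cfi=self.fit.cfi, tli=self.fit.tli,
                              baseline_chi2=self.fit.baseline_chi2,
                              baseline_df=self.fit.baseline_df)
        return json.dumps(out, indent=2)


class NotConvergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _start_values(comp: _Compiled, X: np.ndarray) -> np.ndarray:
    """Moment-based starting values; fixed fallbacks for empty cells."""
    means = np.nanmean(X, axis=0)
    variances = np.nanvar(X, axis=0, ddof=1)
    variances = np.where(np.isfinite(variances) & (variances > 0), variances, 1.0)
    col_of = {c: j for j, c in enumerate(comp.obs_cols)}
    vvar = {}
    for v in comp.variables:
        if v in comp.spec.latents:
            vvar[v] = 0.5 * variances[col_of[comp.spec.latents[v][0]]]
        else:
            vvar[v] = variances[col_of[v]]
    theta = []
    endo = set(comp.spec.endogenous)
    for label, i, j in comp.a_params:
        theta.append(0.5 if "=~" in label else 0.0)
    for label, i, j in comp.s_params:
        a = comp.variables[i]
        if i == j:
            v0 = vvar[a]
            if a in comp.spec.latents:
                theta.append(max(v0, 0.05))
            elif any(a in inds for inds in comp.spec.latents.values()):
                theta.append(0.5 * v0)        # uniqueness share
            elif a in endo:
                theta.append(0.7 * v0)
            else:
                theta.append(v0)
        else:
            theta.append(0.0)
    for label, i in comp.m_params:
        theta.append(means[col_of[comp.variables[i]]])
    return np.asarray(theta)


def fiml_fit(
    spec: SEMSpec,
    data: pd.DataFrame,
    compute_se: bool = True,
    fit_indices_wanted: bool = True,
    indirect_chains: list[list[tuple[str, str]]] | None = None,
    gtol: float = 1e-5,
    max_iter: int = 2000,
    scale_observed: bool = True,
) -> SEMResult:
    """Fit the declared model by full-information maximum likelihood.

    Cases contribute through the observed sub-vector of their missingness
    pattern; estimation maximises the summed pattern-wise Gaussian
    log-likelihood with analytic gradients under a quasi-Newton
    (L-BFGS-B) scheme, to projected-gradient norm below ``gtol`` on the
    per-case deviance scale.  SEs come from the observed information matrix
    (finite differences of the analytic gradient).
    """
    comp = _compile(spec)
    X = data[comp.obs_cols].to_numpy(float)
    if scale_observed:
        # divide each column by its observed SD: a pure reparameterisation
        # that conditions the optimisation; standardised output is invariant
        col_sd = np.nanstd(X, axis=0, ddof=1)
        col_sd = np.where(np.isfinite(col_sd) & (col_sd > 0), col_sd, 1.0)
        X = X / col_sd
    pat = _extract_patterns(X)
    n = pat.n_used
    t = len(comp.variables)
    obs = comp.obs_pos
    n_a, n_s = len(comp.a_params), len(comp.s_params)

    def value_grad(theta):
        A, S, m = _unpack(comp, theta)
        B = np.linalg.inv(np.eye(t) - A)
        V = B @ S @ B.T
        Sigma = V[np.ix_(obs, obs)]
        mu = (B @ m)[obs]
        try:
            np.linalg.cholesky(Sigma + 1e-12 * np.eye(len(obs)))
        except np.linalg.LinAlgError:
            return _PENALTY, np.zeros_like(theta)
        f, G, g = _fiml_value_grad(pat, Sigma, mu)
        Gt = np.zeros((t, t))
        Gt[np.ix_(obs, obs)] = G
        gt = np.zeros(t)
        gt[obs] = g
        W = B @ S @ B.T
        M1 = W @ Gt @ B          # A-gradient kernel (Sigma part)
        M2 = B.T @ Gt @ B        # S-gradient kernel
        u = B.T @ gt             # mean chain
        w_vec = B @ m
        grad = np.empty_like(theta)
        k = 0
        for _, i, j in comp.a_params:
            grad[k] = 2.0 * M1[j, i] + u[i] * w_vec[j]
            k += 1
        for _, i, j in comp.s_params:
            grad[k] = (1.0 if i == j else 2.0) * M2[i, j]
            k += 1
        for _, i in comp.m_params:
            grad[k] = u[i]
            k += 1
        return f, grad

    theta0 = _start_values(comp, X)
    bounds = []
    k = 0
    for _ in comp.a_params:
        bounds.append((None, None))
    for _, i, j in comp.s_params:
        bounds.append((1e-6, None) if i == j else (None, None))
    for _ in comp.m_params:
        bounds.append((None, None))
    res = minimize(value_grad, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options=dict(maxiter=max_iter, maxfun=10 * max_iter,
                                ftol=1e-12, gtol=gtol * 1e-2))
    f_final, grad_final = value_grad(res.x)
    gnorm = float(np.max(np.abs(grad_final)))
    converged = bool(res.success or gnorm < gtol)
    if not converged:
        raise NotConvergedError(
            f"FIML did not converge: {res.message}; |grad|={gnorm:.2e}\n"
            f"trace: nit={res.nit}, nfev={res.nfev}, f={res.fun:.6f}"
        )
    theta = res.x
    loglik = -0.5 * n * f_final

    cov_theta = None
    if compute_se:
        cov_theta = _observed_info_cov(value_grad, theta, n)

    names = ([p[0] for p in comp.a_params] + [p[0] for p in comp.s_params]
             + [p[0] for p in comp.m_params])
    se_vec = (np.sqrt(np.clip(np.diag(cov_theta), 0, None))
              if cov_theta is not None else np.full(len(theta), np.nan))
    unstd = {nm: (float(v), float(s)) for nm, v, s in zip(names, theta, se_vec)}

    std_est, std_cov = _standardize(comp, theta, cov_theta)
    std = {}
    for nm in names:
        if nm in std_est:
            i = list(std_est).index(nm)
            s = (float(np.sqrt(max(std_cov[i, i], 0.0)))
                 if std_cov is not None else np.nan)
            std[nm] = (float(std_est[nm]), s)
    loadings = _std_loadings(comp, theta)

    ll_sat, ll_base, df_model, df_base = _reference_logliks(comp, pat, X)
    fit = None
    if fit_indices_wanted and df_model > 0:
        fit = fit_indices(loglik, ll_sat, ll_base, df_model, df_base, n)

    result = SEMResult(
        spec=spec, param_names=names, theta=theta, cov_theta=cov_theta,
        unstandardized=unstd, standardized=std, loadings=loadings,
        fit=fit, loglik=float(loglik), loglik_saturated=float(ll_sat),
        loglik_baseline=float(ll_base), converged=converged,
        n_used=n, n_patterns=pat.n_patterns,
    )
    if indirect_chains:
        result.indirect = indirect_effects(result, indirect_chains, comp=comp)
    return result


def _observed_info_cov(value_grad, theta, n):
    """Parameter covariance from the observed information matrix.

    The objective is the per-case deviance f = -2 loglik / n, so the
    information is (n/2) * Hessian(f); the Hessian is obtained by central
    finite differences of the analytic gradient.
    """
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        h = 1e-5 * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = value_grad(tp)
        _, gm = value_grad(tm)
        H[i] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T) * (n / 2.0)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# standardisation and indirect effects
# ---------------------------------------------------------------------------

def _std_map(comp: _Compiled, theta: np.ndarray) -> dict[str, float]:
    """Standardised value of every A and off-diagonal S parameter."""
    A, S, m = _unpack(comp, theta)
    t = A.shape[0]
    B = np.linalg.inv(np.eye(t) - A)
    V = B @ S @ B.T
    sd = np.sqrt(np.clip(np.diag(V), 1e-12, None))
    out = {}
    for label, i, j in comp.a_params:
        out[label] = A[i, j] * sd[j] / sd[i]
    for label, i, j in comp.s_params:
        if i != j:
            out[label] = S[i, j] / (sd[i] * sd[j])
    return out


def _standardize(comp: _Compiled, theta, cov_theta):
    """Delta-method standardised estimates: Jacobian of the standardisation
    map propagates the parameter covariance."""
    est = _std_map(comp, theta)
    if cov_theta is None:
        return est, None
    names = list(est)
    k = len(theta)

    def vec(th):
        s = _std_map(comp, th)
        return np.array([s[nm] for nm in names])

    J = np.zeros((len(names), k))
    base = vec(theta)
    for i in range(k):
        h = 1e-6 * (1.0 + abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        J[:, i] = (vec(tp) - base) / h
    return est, J @ cov_theta @ J.T


def standardize(result: SEMResult) -> dict[str, tuple[float, float]]:
    """Standardised edge map of a converged fit (exposed for direct use)."""
    if not result.converged:
        raise NotConvergedError("cannot standardise a non-converged fit")
    comp = _compile(result.spec)
    est, cov = _standardize(comp, result.theta, result.cov_theta)
    out = {}
    for i, nm in enumerate(est):
        se = float(np.sqrt(max(cov[i, i], 0.0))) if cov is not None else np.nan
        out[nm] = (float(est[nm]), se)
    return out


def _std_loadings(comp: _Compiled, theta) -> dict[str, float]:
    A, S, _ = _unpack(comp, theta)
    t = A.shape[0]
    B = np.linalg.inv(np.eye(t) - A)
    V = B @ S @ B.T
    sd = np.sqrt(np.clip(np.diag(V), 1e-12, None))
    vidx = {v: i for i, v in enumerate(comp.variables)}
    out = {}
    for lat, inds in comp.spec.latents.items():
        for ind in inds:
            i, j = vidx[ind], vidx[lat]
            out[f"{lat}=~{ind}"] = float(A[i, j] * sd[j] / sd[i])
    return out


def indirect_effects(
    result: SEMResult,
    chains: list[list[tuple[str, str]]],
    comp: _Compiled | None = None,
) -> dict[str, tuple[float, float]]:
    """Product-of-standardised-coefficients indirect effects with delta SEs.

    Each chain is a list of (from, to) edges that must all be present in the
    fitted model; the estimate is the exact product of the fitted
    standardised coefficients, the SE follows from the multivariate delta
    method on the standardised parameter covariance.
    """
    if comp is None:
        comp = _compile(result.spec)
    est_map, cov_std = _standardize(comp, result.theta, result.cov_theta)
    names = list(est_map)
    out = {}
    for chain in chains:
        labels = [f"{a}->{b}" for a, b in chain]
        for lab in labels:
            if lab not in est_map:
                raise KeyError(f"chain references edge {lab!r} absent from the model")
        vals = np.array([est_map[lab] for lab in labels])
        prod = float(np.prod(vals))
        if cov_std is not None:
            idx = [names.index(lab) for lab in labels]
            grad = np.array([np.prod(np.delete(vals, i)) for i in range(len(vals))])
            sub = cov_std[np.ix_(idx, idx)]
            se = float(np.sqrt(max(grad @ sub @ grad, 0.0)))
        else:
            se = np.nan
        out[" -> ".join([chain[0][0]] + [b for _, b in chain])] = (prod, se)
    return out


def total_effect(result: SEMResult, source: str, target: str) -> float:
    """Direct + sum of all forward-path indirect standardised effects."""
    comp = _compile(result.spec)
    est_map, _ = _standardize(comp, result.theta, None)
    edges = {}
    for nm, v in est_map.items():
        if "->" in nm:
            a, b = nm.split("->")
            edges.setdefault(a, []).append((b, v))

    def paths_from(node, acc):
        if node == target:
            return [acc]
        out = []
        for b, v in edges.get(node, []):
            out.extend(paths_from(b, acc * v))
        return out

    return float(sum(paths_from(source, 1.0)))


# ---------------------------------------------------------------------------
# reference models and fit indices
# ---------------------------------------------------------------------------

def _em_saturated(pat: _Patterns, X: np.ndarray, tol: float = 1e-8, max_iter: int = 500):
    """Unstructured (mu, Sigma) ML under missing data via EM."""
    p = pat.p
    mu = np.nanmean(X, axis=0)
    Sigma = np.diag(np.nanvar(X, axis=0) + 1e-6)
    cc = X[np.all(np.isfinite(X), axis=1)]
    if len(cc) > p + 1:
        Sigma = np.cov(cc, rowvar=False, ddof=0) + 1e-6 * np.eye(p)
    # raw per-pattern sums
    raw = []
    for grp in pat.groups:
        for krow in range(len(grp["n"])):
            o = grp["idx"][krow]
            npat = grp["n"][krow]
            xbar = grp["xbar"][krow]
            scat = grp["scat"][krow]
            A_o = npat * xbar
            M_oo = npat * (scat + np.outer(xbar, xbar))
            raw.append((o, npat, A_o, M_oo))
    n = pat.n_used
    ll_old = -np.inf
    for _ in range(max_iter):
        tot1 = np.zeros(p)
        tot2 = np.zeros((p, p))
        for o, npat, A_o, M_oo in raw:
            miss = np.setdiff1d(np.arange(p), o, assume_unique=True)
            if miss.size == 0:
                tot1[o] += A_o
                tot2[np.ix_(o, o)] += M_oo
                continue
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(miss, o)]
            W = Smo @ np.linalg.inv(Soo)
            mu_o, mu_m = mu[o], mu[miss]
            A_m = npat * mu_m + W @ (A_o - npat * mu_o)
            Cmo = np.outer(mu_m, A_o) + W @ (M_oo - np.outer(mu_o, A_o))
            dA = A_o - npat * mu_o
            Coo_c = M_oo - np.outer(mu_o, A_o) - np.outer(A_o, mu_o) + npat * np.outer(mu_o, mu_o)
            Vm = Sigma[np.ix_(miss, miss)] - W @ Smo.T
            Cmm = (npat * np.outer(mu_m, mu_m) + np.outer(mu_m, W @ dA)
                   + np.outer(W @ dA, mu_m) + W @ Coo_c @ W.T + npat * Vm)
            tot1[o] += A_o
            tot1[miss] += A_m
            tot2[np.ix_(o, o)] += M_oo
            tot2[np.ix_(miss, o)] += Cmo
            tot2[np.ix_(o, miss)] += Cmo.T
            tot2[np.ix_(miss, miss)] += Cmm
        mu = tot1 / n
        Sigma = tot2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T) + 1e-10 * np.eye(p)
        ll = _pattern_loglik(pat, Sigma, mu)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return mu, Sigma, ll


def _baseline_loglik(X: np.ndarray) -> float:
    """Independence model: per-variable Gaussian ML on observed values."""
    ll = 0.0
    for j in range(X.shape[1]):
        x = X[:, j]
        x = x[np.isfinite(x)]
        v = x.var()
        ll += float(-0.5 * len(x) * (np.log(2 * np.pi * v) + 1.0))
    return ll


def _reference_logliks(comp: _Compiled, pat: _Patterns, X: np.ndarray):
    p = pat.p
    p_star = p * (p + 3) // 2
    df_model = p_star - comp.n_par
    df_base = p_star - 2 * p
    if pat.n_patterns == 1 and pat.groups[0]["idx"].shape[1] == p:
        grp = pat.groups[0]
        mu = grp["xbar"][0]
        Sigma = grp["scat"][0]
        ll_sat = _pattern_loglik(pat, Sigma + 1e-12 * np.eye(p), mu)
    else:
        _, _, ll_sat = _em_saturated(pat, X)
    ll_base = _baseline_loglik(X)
    return ll_sat, ll_base, df_model, df_base


def fit_indices(loglik_model, loglik_saturated, loglik_baseline,
                df_model, df_baseline, n) -> FitIndices:
    """RMSEA, CFI and TLI from the model / saturated / baseline log-likelihoods.

    chi2   = 2 (l_sat - l_model)
    rmsea  = sqrt(max((chi2 - df) / (df (n-1)), 0))
    cfi    = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0)
    tli    = ((chi2_b/df_b) - (chi2/df)) / ((chi2_b/df_b) - 1)

    Conventional read-outs: RMSEA < 0.1, CFI > 0.9 and TLI > 0.9 indicate an
    acceptable fit.
    """
    if df_baseline <= df_model:
        raise ValueError("baseline model must be more restrictive than the fitted model")
    if df_model <= 0:
        raise ValueError("fitted model is saturated (df <= 0)")
    chi2 = max(2.0 * (loglik_saturated - loglik_model), 0.0)
    chi2_b = max(2.0 * (loglik_saturated - loglik_baseline), 0.0)
    rmsea = float(np.sqrt(max((chi2 - df_model) / (df_model * (n - 1)), 0.0)))
    denom = max(chi2_b - df_baseline, chi2 - df_model, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df_model, 0.0) / denom
    ratio_b = chi2_b / df_baseline
    tli = float((ratio_b - chi2 / df_model) / (ratio_b - 1.0))
    return FitIndices(chi2=float(chi2), df=int(df_model), rmsea=rmsea,
                      cfi=float(cfi), tli=tli,
                      baseline_chi2=float(chi2_b), baseline_df=int(df_baseline))
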