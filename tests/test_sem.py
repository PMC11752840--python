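"""FIML SEM: estimation, standardisation, mediation, fit indices."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from bmiyears import SEMSpec, core_spec, fiml_fit, fit_indices, indirect_effects
from bmiyears import simulate as simu
from bmiyears.sem import (
    NotConvergedError,
    _compile,
    _em_saturated,
    _extract_patterns,
    _pattern_loglik,
    _std_map,
    _unpack,
)

CHILD = list(simu.CHILD_TESTS)
MID = list(simu.MID_TESTS)


def path_spec():
    return SEMSpec(latents={}, observed_structural=["x", "m", "y"],
                   edges=[("x", "m"), ("x", "y"), ("m", "y")])


def mediation_data(rng, n=3000, a=0.5, b=0.4, c=0.2):
    x = rng.standard_normal(n)
    m_ = a * x + rng.standard_normal(n) * np.sqrt(1 - a * a)
    y = b * m_ + c * x + rng.standard_normal(n) * 0.8
    return pd.DataFrame(dict(x=x, m=m_, y=y))


class TestSpecValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            SEMSpec(latents={}, observed_structural=["a", "b"],
                    edges=[("a", "b"), ("b", "a")])

    def test_temporal_order_violation_rejected(self):
        with pytest.raises(ValueError, match="temporal"):
            SEMSpec(latents={}, observed_structural=["a", "b"],
                    edges=[("b", "a")], temporal_order={"a": 0, "b": 1})

    def test_duplicate_indicator_rejected(self):
        with pytest.raises(ValueError, match="more than one latent"):
            SEMSpec(latents={"f": ["i1", "i2"], "g": ["i2", "i3"]},
                    observed_structural=[], edges=[])

    def test_single_indicator_latent_rejected(self):
        with pytest.raises(ValueError, match="identified"):
            SEMSpec(latents={"f": ["i1"]}, observed_structural=[], edges=[])

    def test_yaml_roundtrip(self, tmp_path):
        spec = core_spec(CHILD, MID)
        p = tmp_path / "model.yaml"
        spec.to_file(p)
        back = SEMSpec.from_file(p)
        assert back.to_dict() == spec.to_dict()


class TestFIMLCorrectness:
    def test_complete_data_equals_ols(self, rng):
        """On complete data a recursive path model's ML solution is exactly
        per-equation OLS; the FIML code must reproduce it."""
        df = mediation_data(rng)
        res = fiml_fit(path_spec(), df, compute_se=True,
                       fit_indices_wanted=False, scale_observed=False)
        ols_m = sm.OLS(df["m"], sm.add_constant(df["x"])).fit()
        ols_y = sm.OLS(df["y"], sm.add_constant(df[["x", "m"]])).fit()
        assert res.unstandardized["x->m"][0] == pytest.approx(ols_m.params["x"], abs=1e-4)
        assert res.unstandardized["x->y"][0] == pytest.approx(ols_y.params["x"], abs=1e-4)
        assert res.unstandardized["m->y"][0] == pytest.approx(ols_y.params["m"], abs=1e-4)
        assert res.unstandardized["m->y"][1] == pytest.approx(ols_y.bse["m"], rel=0.02)

    def test_just_identified_model_attains_saturated_loglik(self, rng):
        df = mediation_data(rng, n=800)
        res = fiml_fit(path_spec(), df, compute_se=False, fit_indices_wanted=False)
        assert res.loglik == pytest.approx(res.loglik_saturated, abs=1e-3)
        assert res.fit is None  # df = 0: no fit indices for a saturated model

    def test_missingness_shrinks_to_complete_estimates(self):
        """FIML at 5% and 20% MCAR stays close to the complete-data solution,
        and closer the less is missing."""
        df, _ = simu.generate_sem_dataset(n=4000, seed=31)
        spec = core_spec(CHILD, MID)
        ref = fiml_fit(spec, df, compute_se=False, fit_indices_wanted=False)
        rng = np.random.default_rng(5)
        diffs = {}
        for rate in (0.05, 0.20):
            dfm = df.mask(pd.DataFrame(rng.random(df.shape) < rate,
                                       columns=df.columns))
            res = fiml_fit(spec, dfm, compute_se=False, fit_indices_wanted=False)
            diffs[rate] = max(
                abs(res.standardized[k][0] - ref.standardized[k][0])
                for k in ref.standardized)
        assert diffs[0.05] < 0.04
        assert diffs[0.20] < 0.10
        assert diffs[0.05] < diffs[0.20]

    def test_likelihood_ordering(self):
        df, _ = simu.generate_sem_dataset(n=1500, seed=8, missing_rate=0.15)
        res = fiml_fit(core_spec(CHILD, MID), df, compute_se=False)
        assert res.loglik_baseline <= res.loglik + 1e-6
        assert res.loglik <= res.loglik_saturated + 1e-6

    def test_em_saturated_matches_direct_optimum(self):
        df, _ = simu.generate_sem_dataset(n=400, seed=2, missing_rate=0.15)
        X = df[["bmi_child", "education", "exposure", "bmi_mid"]].to_numpy()
        pat = _extract_patterns(X)
        mu, Sig, ll = _em_saturated(pat, X)
        # oracle: direct Nelder-Mead over a Cholesky parameterisation
        from scipy.optimize import minimize
        p = X.shape[1]
        def nll(t):
            mu_ = t[:p]
            L = np.zeros((p, p))
            L[np.tril_indices(p)] = t[p:]
            S = L @ L.T + 1e-10 * np.eye(p)
            try:
                return -_pattern_loglik(pat, S, mu_)
            except np.linalg.LinAlgError:
                return 1e12
        cc = X[np.all(np.isfinite(X), axis=1)]
        L0 = np.linalg.cholesky(np.cov(cc.T))
        t0 = np.concatenate([np.nanmean(X, axis=0), L0[np.tril_indices(p)]])
        r = minimize(nll, t0, method="Nelder-Mead",
                     options=dict(maxiter=20000, xatol=1e-8, fatol=1e-10))
        assert ll == pytest.approx(-r.fun, abs=1e-3)


class TestStandardisation:
    def test_scale_invariance_of_standardised_map(self, rng):
        """Rescaling an observed structural variable is absorbed exactly by
        the standardisation map."""
        df = mediation_data(rng, n=1500)
        res = fiml_fit(path_spec(), df, compute_se=False,
                       fit_indices_wanted=False, scale_observed=False)
        comp = _compile(path_spec())
        base = _std_map(comp, res.theta)
        # transform theta exactly as doubling variable m would: A, S, m rows/cols
        A, S, m = _unpack(comp, res.theta)
        i = comp.variables.index("m")
        c = 2.0
        A[i, :] *= c
        A[:, i] /= c
        S[i, :] *= c
        S[:, i] *= c
        m[i] *= c
        theta2 = res.theta.copy()
        k = 0
        for _, a, b in comp.a_params:
            theta2[k] = A[a, b]; k += 1
        for _, a, b in comp.s_params:
            theta2[k] = S[a, b]; k += 1
        for _, a in comp.m_params:
            theta2[k] = m[a]; k += 1
        scaled = _std_map(comp, theta2)
        for key in base:
            assert scaled[key] == pytest.approx(base[key], abs=1e-10)

    def test_constructed_exact_moments_recover_paths(self, rng):
        """Data whose sample moments exactly equal the implied covariance of
        the chain x -(0.5)-> m -(0.4)-> y return those coefficients."""
        n = 400
        Z = rng.standard_normal((n, 3))
        Z = (Z - Z.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(Z.T, ddof=0)).T)
        target = np.array([  # implied correlations of the pure chain
            [1.0, 0.5, 0.2],
            [0.5, 1.0, 0.4],
            [0.2, 0.4, 1.0]])
        X = Z @ np.linalg.cholesky(target).T
        df = pd.DataFrame(X, columns=["x", "m", "y"])
        spec = SEMSpec(latents={}, observed_structural=["x", "m", "y"],
                       edges=[("x", "m"), ("m", "y")])
        res = fiml_fit(spec, df, compute_se=False, fit_indices_wanted=False)
        assert res.standardized["x->m"][0] == pytest.approx(0.5, abs=1e-5)
        assert res.standardized["m->y"][0] == pytest.approx(0.4, abs=1e-5)


class TestIndirectEffects:
    def test_product_rule_and_zero_edge(self, rng):
        df = mediation_data(rng)
        res = fiml_fit(path_spec(), df, compute_se=True, fit_indices_wanted=False,
                       indirect_chains=[[("x", "m"), ("m", "y")]])
        (name, (est, se)), = res.indirect.items()
        prod = res.standardized["x->m"][0] * res.standardized["m->y"][0]
        assert est == prod  # exact product, not an approximation
        assert se > 0
        chain = indirect_effects(res, [[("x", "m"), ("m", "y")]])
        assert list(chain.values())[0][0] == pytest.approx(prod)

    def test_absent_edge_rejected(self, rng):
        df = mediation_data(rng)
        res = fiml_fit(path_spec(), df, compute_se=False, fit_indices_wanted=False)
        with pytest.raises(KeyError, match="absent"):
            indirect_effects(res, [[("y", "x")]])

    def test_pure_mediation_decomposition(self):
        """Generator with no direct cognition->midlife-BMI path but the edge
        kept in the model: direct estimate ~ 0, indirect ~ product of truth."""
        paths = simu.default_sem_truth()
        paths["cog_child->bmi_mid"] = 0.0
        df, truth = simu.generate_sem_dataset(n=6000, seed=17, paths=paths)
        spec = core_spec(CHILD, MID)
        res = fiml_fit(spec, df, compute_se=False, fit_indices_wanted=False,
                       indirect_chains=[[("cog_child", "education"),
                                         ("education", "bmi_mid")]])
        assert abs(res.standardized["cog_child->bmi_mid"][0]) < 0.03
        expected = truth["cog_child->education"] * truth["education->bmi_mid"]
        (est, _), = res.indirect.values()
        assert est == pytest.approx(expected, abs=0.03)


class TestFitIndices:
    def test_perfect_expected_fit(self):
        fi = fit_indices(-500.0, -450.0, -2000.0, df_model=100,
                         df_baseline=120, n=1001)
        assert fi.chi2 == pytest.approx(100.0)
        assert fi.rmsea == 0.0
        assert fi.cfi == 1.0

    def test_hand_evaluated_case(self):
        # chi2=150, df=100, n=1001, chi2_b=2100, df_b=120
        fi = fit_indices(-75.0, 0.0, -1050.0, df_model=100, df_baseline=120, n=1001)
        assert fi.chi2 == pytest.approx(150.0)
        assert fi.rmsea == pytest.approx(np.sqrt(50.0 / 100000.0), abs=1e-6)
        assert fi.cfi == pytest.approx(1.0 - 50.0 / 1980.0, abs=1e-6)
        assert fi.tli == pytest.approx((17.5 - 1.5) / 16.5, abs=1e-6)

    def test_baseline_must_be_more_restrictive(self):
        with pytest.raises(ValueError, match="baseline"):
            fit_indices(-75.0, 0.0, -1050.0, df_model=120, df_baseline=100, n=500)

    def test_correctly_specified_model_lands_in_good_fit_regime(self):
        df, _ = simu.generate_sem_dataset(n=6000, seed=23)
        res = fiml_fit(core_spec(CHILD, MID), df, compute_se=False)
        assert res.fit.rmsea < 0.05
        assert res.fit.cfi > 0.95
        assert res.fit.tli > 0.90
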