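"""Nested-adjustment regressions, pooled fits, tertile trajectories."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from bmiyears import (
    AdjustmentModel,
    ImputedSet,
    ModelLevel,
    estimate_grid,
    fit_adjusted,
    fit_pooled,
    prepare_analysis,
    tertile_trajectories,
)
from bmiyears import simulate as simu
from bmiyears.regress import _fit_single


def synthetic_frame(rng, n=3000, slope=0.3, cohort_shift=(0.0, 0.0, 0.0),
                    intercept_shift=(0.0, 0.0, 0.0)):
    cohort = np.repeat(list("ABC"), n // 3)
    shift = np.repeat(cohort_shift, n // 3)
    icept = np.repeat(intercept_shift, n // 3)
    x = rng.normal(0, 1, n) + shift
    y = icept + slope * x + rng.normal(0, 1, n)
    return pd.DataFrame({
        "person_id": range(n), "cohort": cohort, "x": x, "y": y,
        "age_midlife": rng.normal(50, 1, n), "sex": rng.integers(0, 2, n),
    })


class TestNestedModels:
    def test_covariate_sets_nest(self):
        c1 = set(AdjustmentModel(ModelLevel.model1).covariates)
        c2 = set(AdjustmentModel(ModelLevel.model2).covariates)
        c3 = set(AdjustmentModel(ModelLevel.model3).covariates)
        assert c1 < c2 < c3

    def test_attenuation_of_confounded_exposure(self, attenuation_prep):
        """Zero direct effect + cognition confounding: the minimally adjusted
        coefficient is clearly negative, adjusting childhood cognition more
        than halves it, and the full covariate block removes it."""
        prep, _ = attenuation_prep
        b1 = fit_pooled(prep, "cog_mid_score", "duration_decades", "model1")
        b2 = fit_pooled(prep, "cog_mid_score", "duration_decades", "model2")
        b3 = fit_pooled(prep, "cog_mid_score", "duration_decades", "model3")
        assert b1.beta < 0 and abs(b1.beta) > 2 * b1.se
        assert abs(b2.beta) < 0.5 * abs(b1.beta)
        assert abs(b3.beta) <= 0.02

    def test_unconfounded_effect_recovered_at_all_levels(self):
        paths = simu.default_path_coefficients()
        paths.update({"exposure->cog_mid": -0.10, "education->bmi_adult": 0.0,
                      "cog_child->bmi_adult": 0.0, "ses->cog_mid": 0.0,
                      "education->cog_mid": 0.0, "ses->bmi_child": 0.0})
        truth = simu.GroundTruth(n_per_cohort=2000, seed=13,
                                 path_coefficients=paths)
        table, _ = simu.generate_cohorts(truth)
        prep = prepare_analysis(table)
        b1 = fit_pooled(prep, "cog_mid_score", "auc_sd_units", "model1")
        b3 = fit_pooled(prep, "cog_mid_score", "auc_sd_units", "model3")
        assert b1.beta == pytest.approx(-0.10, abs=0.03)
        assert b3.beta == pytest.approx(-0.10, abs=0.03)

    def test_null_calibration_p_uniform(self):
        """With a pure-noise outcome, p-values are uniform and the 5% test
        rejects at its nominal rate across replicates."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(500):
            n = 500
            x = rng.normal(0, 1, n)
            df = pd.DataFrame({
                "person_id": range(n), "x": x,
                "y": rng.normal(0, 1, n),
                "age_midlife": rng.normal(50, 1, n),
                "sex": rng.integers(0, 2, n),
            })
            pvals.append(fit_adjusted(df, "y", "x", "model1").p)
        pvals = np.asarray(pvals)
        rate = (pvals < 0.05).mean()
        assert 0.02 <= rate <= 0.08  # 3 binomial SDs around 0.05
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPooledFits:
    def test_pooled_beta_between_per_cohort_betas(self, rng):
        df = synthetic_frame(rng)
        per = [fit_adjusted(df[df.cohort == c], "y", "x", "model1").beta
               for c in "ABC"]
        pooled = fit_pooled(df, "y", "x", "model1").beta
        assert min(per) - 1e-9 <= pooled <= max(per) + 1e-9

    def test_intercept_shifts_need_cohort_dummies(self, rng):
        df = synthetic_frame(rng, n=6000, cohort_shift=(0.0, 1.0, 2.0),
                             intercept_shift=(0.0, -1.0, -2.0))
        with_dummies = fit_pooled(df, "y", "x", "model1").beta
        without = fit_adjusted(df, "y", "x", "model1").beta
        assert with_dummies == pytest.approx(0.3, abs=0.02)
        assert abs(without - 0.3) > 0.1  # omitted-dummy bias

    def test_single_cohort_rejected(self, rng):
        df = synthetic_frame(rng)
        with pytest.raises(ValueError, match="single-cohort"):
            fit_pooled(df[df.cohort == "A"], "y", "x", "model1")


class TestInvariants:
    def test_linear_rescaling_equivariance(self, rng):
        df = synthetic_frame(rng)
        df["x10"] = df["x"] / 10.0
        a = fit_adjusted(df, "y", "x", "model1")
        b = fit_adjusted(df, "y", "x10", "model1")
        assert b.beta == pytest.approx(10 * a.beta, rel=1e-10)
        assert b.ci_lo == pytest.approx(10 * a.ci_lo, rel=1e-9)

    def test_m1_imputedset_matches_direct_path(self, rng):
        df = synthetic_frame(rng)
        direct = fit_adjusted(df, "y", "x", "model1")
        iset = ImputedSet(datasets=[df, df], method_map={}, seed=0, iterations=0)
        via_mi = fit_adjusted(iset, "y", "x", "model1")
        assert via_mi.beta == pytest.approx(direct.beta, abs=1e-12)

    def test_r2_nondecreasing_across_models(self, attenuation_prep):
        prep, _ = attenuation_prep
        r2 = []
        for lev in ("model1", "model2", "model3"):
            fit, _ = _fit_single(prep, "cog_mid_score", "duration_decades",
                                 AdjustmentModel(ModelLevel(lev)).covariates, True)
            r2.append(fit.rsquared)
        assert r2[0] <= r2[1] <= r2[2]

    def test_rank_deficiency_reported(self, rng):
        df = synthetic_frame(rng)
        df["sex"] = 1.0  # constant covariate collides with the intercept
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_adjusted(df, "y", "x", "model1")


class TestTertileTrajectories:
    def test_divergence_under_cognition_to_bmi_paths(self, attenuation_prep):
        """Negative cognition -> adult BMI truth: lowest tertile drifts above
        the age-specific norm after adolescence, highest below, with the gap
        widest in young adulthood."""
        prep, _ = attenuation_prep
        zcols = [f"z_bmi_{a}" for a in (10, 16, 23, 33, 42, 50)]
        traj = tertile_trajectories(prep, zcols, adjustment=["sex"])
        wide = traj.pivot(index="age_column", columns="tertile", values="mean")
        gap = (wide[1.0] - wide[3.0]).reindex(zcols)
        assert gap["z_bmi_33"] > 0.1
        assert wide.loc["z_bmi_33", 1.0] > 0 > wide.loc["z_bmi_33", 3.0]
        assert gap[["z_bmi_23", "z_bmi_33"]].max() > gap["z_bmi_10"]
        assert gap[["z_bmi_23", "z_bmi_33"]].max() >= gap["z_bmi_50"] - 0.02

    def test_upstream_adjustment_shrinks_gap(self, attenuation_prep):
        prep, _ = attenuation_prep
        zcols = ["z_bmi_23", "z_bmi_33"]
        t_min = tertile_trajectories(prep, zcols, adjustment=["sex"])
        t_adj = tertile_trajectories(
            prep, zcols, adjustment=["sex", "mother_bmi", "father_bmi",
                                     "birthweight", "overcrowding", "ses"])
        def gap(t):
            w = t.pivot(index="age_column", columns="tertile", values="mean")
            return (w[1.0] - w[3.0]).mean()
        assert gap(t_adj) < gap(t_min)

    def test_null_world_flat_curves(self):
        from test_simulate import null_truth
        table, _ = simu.generate_cohorts(null_truth(n=1500, seed=21))
        prep = prepare_analysis(table)
        zcols = [f"z_bmi_{a}" for a in (10, 16, 23, 33, 42, 50)]
        traj = tertile_trajectories(prep, zcols, adjustment=["sex"])
        assert (traj["ci_lo"] < 0).all() and (traj["ci_hi"] > 0).all()


class TestEstimateGrid:
    def test_grid_shape_and_monotone_attenuation(self, attenuation_prep):
        prep, _ = attenuation_prep
        grid = estimate_grid(prep, "cog_mid_score",
                             ["duration_decades", "auc_sd_units"], pooled=True)
        assert len(grid) == 6
        for exp in ("duration_decades", "auc_sd_units"):
            sub = grid[grid.exposure == exp].set_index("model")["beta"].abs()
            assert sub["model3"] < sub["model1"]
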