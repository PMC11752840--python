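"""Trajectory construction and excess-bodyweight exposure geometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bmiyears import (
    InsufficientTrajectoryError,
    age_specific_zscores,
    build_trajectory,
    excess_metrics,
    residual_change,
    scale_exposures,
)
from bmiyears.exposures import BMITrajectory, grid_oracle

from conftest import example_trajectory_row


class TestBuildTrajectory:
    def test_window_endpoint_interpolated(self):
        traj = build_trajectory(example_trajectory_row())
        # age 40 between observed 33 and 42: 28 + (27-28)*(40-33)/(42-33)
        assert traj(40.0) == pytest.approx(28 + (27 - 28) * 7 / 9, abs=1e-9)
        assert traj.span == (10.0, 40.0)

    def test_single_point_is_insufficient(self):
        row = pd.Series({"person_id": 2, "bmi_10": 22.0, "bmi_16": np.nan,
                         "bmi_23": np.nan, "bmi_33": np.nan, "bmi_42": np.nan,
                         "bmi_50": np.nan})
        with pytest.raises(InsufficientTrajectoryError):
            build_trajectory(row)

    def test_constant_bmi_stays_constant(self):
        row = pd.Series({"person_id": 3, **{f"bmi_{a}": 22.0
                                            for a in (10, 16, 23, 33, 42, 50)}})
        traj = build_trajectory(row)
        assert np.allclose(traj(np.linspace(10, 40, 7)), 22.0)

    def test_no_extrapolation(self):
        traj = build_trajectory(example_trajectory_row())
        with pytest.raises(ValueError, match="extrapolation"):
            traj(45.0)


class TestExcessMetrics:
    def test_worked_example(self):
        traj = build_trajectory(example_trajectory_row())
        m = excess_metrics(traj, threshold=25.0)
        assert m.onset_age == pytest.approx(19.5, abs=1e-9)
        assert m.duration_years == pytest.approx(20.5, abs=1e-9)
        # triangle 1.75 + trapezoid 20.0 + trapezoid 18.2778
        assert m.auc_bmi_years == pytest.approx(40.0278, abs=0.01)
        dur_o, auc_o = grid_oracle(traj, 25.0)
        assert m.duration_years == pytest.approx(dur_o, abs=0.01)
        assert m.auc_bmi_years == pytest.approx(auc_o, abs=0.01)

    def test_below_threshold_unexposed(self):
        row = pd.Series({"person_id": 4, **{f"bmi_{a}": 21.0
                                            for a in (10, 16, 23, 33, 42, 50)}})
        m = excess_metrics(build_trajectory(row))
        assert not m.ever_exposed
        assert m.onset_age is None
        assert m.duration_years == 0.0 and m.auc_bmi_years == 0.0

    def test_constant_above_threshold_rectangle(self):
        row = pd.Series({"person_id": 5, **{f"bmi_{a}": 27.0
                                            for a in (10, 16, 23, 33, 42, 50)}})
        m = excess_metrics(build_trajectory(row))
        assert m.duration_years == pytest.approx(30.0)
        assert m.auc_bmi_years == pytest.approx(60.0)
        assert m.onset_age == pytest.approx(10.0)

    def test_threshold_validation(self):
        traj = build_trajectory(example_trajectory_row())
        with pytest.raises(ValueError):
            excess_metrics(traj, threshold=-1.0)


@st.composite
def trajectories(draw):
    n = draw(st.integers(min_value=2, max_value=6))
    ages = sorted(draw(st.lists(
        st.floats(min_value=8.0, max_value=50.0), min_size=n, max_size=n,
        unique_by=lambda a: round(a, 1))))
    if len(ages) < 2 or min(np.diff(ages)) < 0.5:
        ages = np.linspace(10, 42, n)
    bmis = draw(st.lists(st.floats(min_value=15.0, max_value=45.0),
                         min_size=len(ages), max_size=len(ages)))
    return BMITrajectory(person_id=0, ages=np.asarray(ages, float),
                         bmis=np.asarray(bmis, float))


class TestExposureProperties:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(traj=trajectories(), thr=st.floats(min_value=18.0, max_value=35.0))
    def test_exact_matches_grid_oracle(self, traj, thr):
        m = excess_metrics(traj, threshold=thr)
        dur_o, auc_o = grid_oracle(traj, thr)
        assert m.duration_years == pytest.approx(dur_o, abs=0.01)
        assert m.auc_bmi_years == pytest.approx(auc_o, abs=0.01)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(traj=trajectories(), thr=st.floats(min_value=18.0, max_value=30.0),
           bump=st.floats(min_value=0.5, max_value=5.0))
    def test_threshold_monotone_and_translation_invariant(self, traj, thr, bump):
        m0 = excess_metrics(traj, threshold=thr)
        m1 = excess_metrics(traj, threshold=thr + bump)
        assert m1.duration_years <= m0.duration_years + 1e-12
        assert m1.auc_bmi_years <= m0.auc_bmi_years + 1e-12
        shifted = BMITrajectory(person_id=0, ages=traj.ages, bmis=traj.bmis + bump,
                                window=traj.window)
        m2 = excess_metrics(shifted, threshold=thr + bump)
        assert m2.duration_years == pytest.approx(m0.duration_years, abs=1e-9)
        assert m2.auc_bmi_years == pytest.approx(m0.auc_bmi_years, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(traj=trajectories())
    def test_auc_additive_over_subwindows(self, traj):
        full = BMITrajectory(0, traj.ages, traj.bmis, window=(10.0, 40.0))
        left = BMITrajectory(0, traj.ages, traj.bmis, window=(10.0, 25.0))
        right = BMITrajectory(0, traj.ages, traj.bmis, window=(25.0, 40.0))
        a_full = excess_metrics(full).auc_bmi_years
        a_l = excess_metrics(left).auc_bmi_years
        a_r = excess_metrics(right).auc_bmi_years
        if full.span[1] > full.span[0] and left.span[1] >= left.span[0] \
                and right.span[1] >= right.span[0]:
            assert a_full == pytest.approx(a_l + a_r, abs=1e-8)


class TestZScores:
    def test_mean_zero_sd_one(self, complete_cohort):
        _, table, _ = complete_cohort
        z = age_specific_zscores(table, by_cohort=True)
        merged = z.merge(table[["person_id", "cohort"]], on="person_id")
        for cohort, g in merged.groupby("cohort"):
            assert abs(g["z_bmi_33"].mean()) < 1e-10
            assert g["z_bmi_33"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_two_person_stratum(self):
        t = pd.DataFrame({"person_id": [1, 2], "cohort": ["A", "A"],
                          "bmi_10": [20.0, 30.0]})
        z = age_specific_zscores(t, by_cohort=False, bmi_columns=("bmi_10",))
        assert np.allclose(sorted(z["z_bmi_10"]), [-0.7071, 0.7071], atol=1e-4)

    def test_zero_sd_stratum_raises(self):
        t = pd.DataFrame({"person_id": [1, 2, 3], "cohort": ["A"] * 3,
                          "bmi_10": [22.0, 22.0, 22.0]})
        with pytest.raises(ValueError, match="bmi_10"):
            age_specific_zscores(t, by_cohort=False, bmi_columns=("bmi_10",))

    def test_all_missing_stratum_stays_missing(self):
        t = pd.DataFrame({"person_id": [1, 2], "cohort": ["A", "A"],
                          "bmi_10": [np.nan, np.nan]})
        z = age_specific_zscores(t, by_cohort=False, bmi_columns=("bmi_10",))
        assert z["z_bmi_10"].isna().all()


class TestResidualChange:
    def test_orthogonal_to_earlier_bmi(self, complete_cohort):
        _, table, _ = complete_cohort
        r = residual_change(table, (23, 33))
        ok = table["bmi_23"].notna() & r.reset_index(drop=True).notna()
        corr = np.corrcoef(table.loc[ok.to_numpy(), "bmi_23"],
                           r.to_numpy()[ok.to_numpy()])[0, 1]
        assert abs(corr) < 1e-10

    def test_identical_ages_give_zero_residuals(self):
        t = pd.DataFrame({"person_id": range(10),
                          "bmi_23": np.linspace(20, 30, 10)})
        t["bmi_33"] = t["bmi_23"]
        r = residual_change(t, (23, 33))
        assert np.allclose(r, 0.0, atol=1e-10)

    def test_residual_sd_matches_noise_sd(self, rng):
        n = 5000
        x = rng.normal(24, 3, n)
        y = 0.8 * x + rng.normal(0, 1, n)
        t = pd.DataFrame({"person_id": range(n), "bmi_23": x, "bmi_33": y})
        r = residual_change(t, (23, 33))
        assert 0.95 < r.std(ddof=1) < 1.05

    def test_zero_variance_regressor_raises(self):
        t = pd.DataFrame({"person_id": range(5), "bmi_23": [22.0] * 5,
                          "bmi_33": np.linspace(20, 30, 5)})
        with pytest.raises(ValueError):
            residual_change(t, (23, 33))


class TestScaleExposures:
    def test_units(self, complete_cohort):
        _, table, _ = complete_cohort
        from bmiyears import exposure_table
        ex = exposure_table(table)
        scaled = scale_exposures(ex)
        assert np.allclose(scaled.table["duration_decades"] * 10,
                           ex["duration_years"], equal_nan=True)
        assert scaled.table["auc_sd_units"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert scaled.auc_sd == pytest.approx(ex["auc_bmi_years"].std(ddof=1))

    def test_zero_variance_raises(self):
        ex = pd.DataFrame({"person_id": [1, 2], "duration_years": [0.0, 0.0],
                           "auc_bmi_years": [0.0, 0.0], "ever_exposed": [0, 0]})
        with pytest.raises(ValueError):
            scale_exposures(ex)
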