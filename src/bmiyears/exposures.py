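"""Child-to-adult BMI trajectories and excess-bodyweight exposure metrics.

Each person's serial BMI measurements (nominal ages 10, 16, 23, 33, 42 and
50 y) define a piecewise-linear trajectory.  Within an analysis window
(default 10-40 y) we derive, for a threshold separating normal weight from
excess bodyweight (default 25 kg/m2):

* ``onset_age``      -- earliest age at which interpolated BMI exceeds the
                        threshold,
* ``duration_years`` -- total time spent above the threshold, and
* ``auc_bmi_years``  -- cumulative severity, the integral of
                        ``max(BMI(t) - threshold, 0)`` in BMI-years.

Crossing times and areas are solved exactly on each linear segment
(triangles and trapezoids), never by grid approximation.  The module also
provides the regression-ready transforms: age-specific BMI z-scores,
residualised BMI change between adjacent ages, and unit scaling of the
exposure metrics (duration per decade, severity per sample SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NOMINAL_AGES = (10.0, 16.0, 23.0, 33.0, 42.0, 50.0)
BMI_COLUMNS = ("bmi_10", "bmi_16", "bmi_23", "bmi_33", "bmi_42", "bmi_50")
DEFAULT_WINDOW = (10.0, 40.0)
DEFAULT_THRESHOLD = 25.0

BMI_LO, BMI_HI = 10.0, 70.0


class InsufficientTrajectoryError(ValueError):
    """Fewer than two usable BMI points intersect the analysis window."""


@dataclass(frozen=True)
class BMITrajectory:
    """Ordered (age, BMI) points for one person, clipped to the window.

    Interior values are defined by linear interpolation between adjacent
    observed points; no extrapolation beyond the observed span is ever
    performed, so the realised evaluation window may be narrower than the
    requested one.
    """

    person_id: object
    ages: np.ndarray
    bmis: np.ndarray
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        bmis = np.asarray(self.bmis, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "bmis", bmis)
        if ages.size < 2:
            raise InsufficientTrajectoryError(
                f"person {self.person_id!r}: need >=2 points, got {ages.size}"
            )
        if not np.all(np.diff(ages) > 0):
            raise ValueError(f"person {self.person_id!r}: ages must strictly increase")
        if np.any(bmis <= BMI_LO) or np.any(bmis >= BMI_HI):
            raise ValueError(
                f"person {self.person_id!r}: BMI outside plausible range ({BMI_LO}, {BMI_HI})"
            )

    @property
    def span(self) -> tuple[float, float]:
        """Realised evaluation interval: window intersected with observed span."""
        return (max(self.window[0], self.ages[0]), min(self.window[1], self.ages[-1]))

    def __call__(self, age):
        """Interpolated BMI at ``age`` (must lie within the observed span)."""
        age = np.asarray(age, dtype=float)
        if np.any(age < self.ages[0]) or np.any(age > self.ages[-1]):
            raise ValueError("no extrapolation outside the observed span")
        return np.interp(age, self.ages, self.bmis)


@dataclass(frozen=True)
class ExcessExposure:
    """Excess-bodyweight summary for one trajectory."""

    person_id: object
    ever_exposed: bool
    onset_age: float | None
    duration_years: float
    auc_bmi_years: float
    threshold: float = DEFAULT_THRESHOLD
    window_start: float = DEFAULT_WINDOW[0]
    window_end: float = DEFAULT_WINDOW[1]

    def __post_init__(self) -> None:
        if not self.ever_exposed:
            if self.onset_age is not None or self.duration_years != 0 or self.auc_bmi_years != 0:
                raise ValueError("unexposed person must have zero duration and severity")
        if self.duration_years < 0 or self.auc_bmi_years < 0:
            raise ValueError("duration and severity must be non-negative")


def build_trajectory(
    row,
    nominal_ages=NOMINAL_AGES,
    bmi_columns=BMI_COLUMNS,
    window=DEFAULT_WINDOW,
) -> BMITrajectory:
    """Build one person's windowed piecewise-linear trajectory from a table row.

    Observed points are clipped to ``window``; a window endpoint lying strictly
    inside the observed span is included as an interpolated point so that
    downstream integrals cover exactly ``window ∩ observed span``.

    Raises
    ------
    InsufficientTrajectoryError
        if fewer than two non-missing BMI values fall on segments
        intersecting the window.
    """
    ages = np.asarray(nominal_ages, dtype=float)
    vals = np.array([row[c] for c in bmi_columns], dtype=float)
    keep = np.isfinite(vals)
    ages, vals = ages[keep], vals[keep]
    if ages.size < 2:
        raise InsufficientTrajectoryError(
            f"person {row.get('person_id', '?')!r}: {ages.size} usable BMI points"
        )
    lo, hi = max(window[0], ages[0]), min(window[1], ages[-1])
    if hi <= lo:
        raise InsufficientTrajectoryError(
            f"person {row.get('person_id', '?')!r}: observed span does not intersect window"
        )
    # clip to [lo, hi], interpolating the endpoints onto the polyline
    grid = np.unique(np.concatenate([[lo, hi], ages[(ages > lo) & (ages < hi)]]))
    bmis = np.interp(grid, ages, vals)
    return BMITrajectory(
        person_id=row.get("person_id", None), ages=grid, bmis=bmis, window=(window[0], window[1])
    )


def _segment_excess(t0, t1, b0, b1, thr):
    """(time above thr, area above thr, first crossing age or None) on one segment."""
    e0, e1 = b0 - thr, b1 - thr
    dt = t1 - t0
    if e0 <= 0 and e1 <= 0:
        return 0.0, 0.0, None
    if e0 > 0 and e1 > 0:
        return dt, 0.5 * (e0 + e1) * dt, t0
    # exactly one strict sign change: solve the linear crossing
    tc = t0 + (thr - b0) / (b1 - b0) * dt
    if e0 > 0:  # above then below: triangle from t0 to tc
        return tc - t0, 0.5 * e0 * (tc - t0), t0
    # below then above: triangle from tc to t1
    return t1 - tc, 0.5 * e1 * (t1 - tc), tc


def excess_metrics(traj: BMITrajectory, threshold: float = DEFAULT_THRESHOLD) -> ExcessExposure:
    """Exact duration, onset and cumulative severity of excess bodyweight.

    Exposure is defined by the strict inequality ``BMI(t) > threshold``; a
    trajectory touching the threshold exactly contributes zero duration and
    zero area (measure-zero by construction).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    lo, hi = traj.span
    if hi <= lo:  # window does not intersect the observed span
        return ExcessExposure(person_id=traj.person_id, ever_exposed=False,
                              onset_age=None, duration_years=0.0, auc_bmi_years=0.0,
                              threshold=float(threshold), window_start=lo, window_end=lo)
    inner = traj.ages[(traj.ages > lo) & (traj.ages < hi)]
    ages = np.unique(np.concatenate([[lo, hi], inner]))
    bmis = np.interp(ages, traj.ages, traj.bmis)
    duration = 0.0
    auc = 0.0
    onset = None
    for i in range(ages.size - 1):
        d, a, c = _segment_excess(ages[i], ages[i + 1], bmis[i], bmis[i + 1], threshold)
        duration += d
        auc += a
        if onset is None and c is not None:
            onset = float(c)
    exposed = duration > 0.0
    return ExcessExposure(
        person_id=traj.person_id,
        ever_exposed=exposed,
        onset_age=onset if exposed else None,
        duration_years=float(duration),
        auc_bmi_years=float(auc),
        threshold=float(threshold),
        window_start=lo,
        window_end=hi,
    )


def exposure_table(
    table: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    window=DEFAULT_WINDOW,
    nominal_ages=NOMINAL_AGES,
    bmi_columns=BMI_COLUMNS,
) -> pd.DataFrame:
    """Per-person exposure metrics for a whole cohort table.

    Persons with fewer than two usable BMI points get all-missing metrics and
    are counted in the frame's ``attrs['n_insufficient']``.
    """
    records = []
    n_bad = 0
    for _, row in table.iterrows():
        pid = row["person_id"]
        try:
            traj = build_trajectory(row, nominal_ages, bmi_columns, window)
            exp = excess_metrics(traj, threshold)
            records.append(
                dict(
                    person_id=pid,
                    ever_exposed=int(exp.ever_exposed),
                    onset_age=exp.onset_age if exp.onset_age is not None else np.nan,
                    duration_years=exp.duration_years,
                    auc_bmi_years=exp.auc_bmi_years,
                    window_start=exp.window_start,
                    window_end=exp.window_end,
                    threshold=exp.threshold,
                )
            )
        except InsufficientTrajectoryError:
            n_bad += 1
            records.append(
                dict(
                    person_id=pid,
                    ever_exposed=np.nan,
                    onset_age=np.nan,
                    duration_years=np.nan,
                    auc_bmi_years=np.nan,
                    window_start=np.nan,
                    window_end=np.nan,
                    threshold=float(threshold),
                )
            )
    out = pd.DataFrame.from_records(records)
    out.attrs["n_insufficient"] = n_bad
    return out


def grid_oracle(traj: BMITrajectory, threshold: float = DEFAULT_THRESHOLD, dt: float = 1e-3):
    """Fine-grid trapezoid approximation of (duration, AUC); validation oracle.

    Deliberately independent of :func:`excess_metrics`: it never solves for
    crossing points, it just samples the polyline on a dense grid.
    """
    lo, hi = traj.span
    t = np.arange(lo, hi + dt / 2, dt)
    excess = np.maximum(np.interp(t, traj.ages, traj.bmis) - threshold, 0.0)
    auc = np.trapezoid(excess, t)
    duration = np.trapezoid((excess > 0).astype(float), t)
    return float(duration), float(auc)


def age_specific_zscores(
    table: pd.DataFrame,
    by_cohort: bool = True,
    bmi_columns=BMI_COLUMNS,
) -> pd.DataFrame:
    """Standardise each BMI column to mean 0, SD 1 within its age stratum.

    The SD uses the n-1 denominator.  When ``by_cohort`` is set, strata are
    (age, cohort) cells.  Missing values stay missing; an all-missing stratum
    yields an all-missing column for that stratum; a zero-SD stratum is an
    error naming the stratum.
    """
    out = table[["person_id"]].copy()
    groups = table.groupby("cohort", observed=True) if by_cohort else [(None, table)]
    for col in bmi_columns:
        z = pd.Series(np.nan, index=table.index, dtype=float)
        for name, g in groups:
            vals = g[col]
            obs = vals.dropna()
            if len(obs) == 0:
                continue
            if len(obs) < 2:
                raise ValueError(f"stratum ({col}, cohort={name}): fewer than 2 observed values")
            sd = obs.std(ddof=1)
            if sd == 0:
                raise ValueError(f"stratum ({col}, cohort={name}): zero SD")
            z.loc[g.index] = (vals - obs.mean()) / sd
        out["z_" + col] = z
    return out


def residual_change(table: pd.DataFrame, age_pair: tuple[int, int]) -> pd.Series:
    """Residualised BMI change: later-age BMI regressed on earlier-age BMI.

    OLS with intercept on pairwise-complete rows; the residual is the part of
    later BMI not predicted by earlier BMI, the exposure used in place of raw
    change scores.  Returns a person_id-indexed series, missing wherever
    either BMI is missing.
    """
    a0, a1 = age_pair
    c0, c1 = f"bmi_{a0}", f"bmi_{a1}"
    x, y = table[c0].to_numpy(float), table[c1].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError(f"fewer than 3 complete pairs for ages {a0}->{a1}")
    xo = x[ok]
    if np.std(xo) == 0:
        raise ValueError(f"bmi_{a0} has zero variance on complete pairs")
    slope, intercept = np.polyfit(xo, y[ok], 1)
    res = np.full(len(table), np.nan)
    res[ok] = y[ok] - (intercept + slope * xo)
    return pd.Series(res, index=table["person_id"].to_numpy(), name=f"dbmi_{a0}_{a1}")


@dataclass
class ScaledExposures:
    """Exposure covariates in the units used for reporting."""

    table: pd.DataFrame
    auc_sd: float


def scale_exposures(exposure: pd.DataFrame) -> ScaledExposures:
    """Duration per decade and severity per sample SD.

    Division of duration by 10 gives effects "per 10 years" of excess
    bodyweight; the BMI-years AUC is standardised to unit SD (computed on
    observed values, n-1 denominator) so effects read "per 1 SD of
    cumulative exposure".
    """
    auc = exposure["auc_bmi_years"]
    sd = auc.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("AUC has zero or undefined variance; cannot standardise")
    out = exposure[["person_id"]].copy()
    out["duration_decades"] = exposure["duration_years"] / 10.0
    out["auc_sd_units"] = auc / sd
    out["ever_exposed"] = exposure["ever_exposed"]
    return ScaledExposures(table=out, auc_sd=float(sd))
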