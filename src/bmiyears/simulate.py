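"""Synthetic multi-cohort data with known structural truth.

Real counterparts of these data (three British birth cohorts with serial
BMI from age 10 to 50 and cognitive batteries in childhood and midlife) are
access-restricted, so every downstream stage is exercised on simulated
cohorts whose generating parameters are kept alongside the data
(:class:`GroundTruth`) for recovery testing.

Two generators live here:

* :func:`generate_cohorts` / :func:`apply_missingness` -- the full cohort
  emulation: three cohorts with later-cohort upward BMI shifts (earlier,
  more severe excess-bodyweight exposure), person-level BMI growth curves,
  single-factor cognitive batteries in score units, ordinal early-life
  covariates from thresholded latent normals, and missing-at-random
  missingness driven by always-observed variables (cohort, sex, SES).
* :func:`generate_sem_dataset` -- a linear-Gaussian cross-lagged system on
  standardised scales whose coefficients are exactly the standardised paths
  a correctly specified structural model should recover; used to validate
  the FIML estimator.

All randomness flows through ``numpy.random.SeedSequence(seed)`` substreams
named per stage, so a run is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .exposures import BMI_COLUMNS, NOMINAL_AGES

COHORTS = ("A", "B", "C")
CHILD_TESTS = ("child_test_1", "child_test_2", "child_test_3", "child_test_4")
MID_TESTS = ("mid_test_1", "mid_test_2", "mid_test_3", "mid_test_4")

# raw score scales for the simulated batteries (mean, SD), loosely matching
# typical ranges of verbal/non-verbal reasoning, maths, reading scores and of
# recall / animal-naming / letter-search scores
_CHILD_SCALES = ((30.0, 11.0), (28.0, 9.0), (27.0, 11.0), (30.0, 7.0))
_MID_SCALES = ((7.0, 1.5), (6.0, 2.0), (23.0, 6.0), (320.0, 85.0))

# ordinal thresholds (cumulative proportions) for latent-normal cuts
_SES_CUM = (0.05, 0.19, 0.72, 0.94)          # 5 classes, unskilled .. professional
_OVERCROWD_CUM = (0.60, 0.87, 0.97)          # 4 classes, <=1 .. >2 persons/room
_EDU_CUM = (0.30, 0.65, 0.82)                # 4 classes, < ordinary .. higher ed

_ADULT_BMI_SD = 3.5                          # scale for standardised adult-BMI effects


def default_path_coefficients() -> dict[str, float]:
    """Generating standardised coefficients for the full cohort emulation.

    The exposure -> midlife-cognition path is zero by default: the synthetic
    world has no direct effect of excess bodyweight on cognition, only
    confounding through childhood cognition and family background, which is
    the structure the attenuation analyses are designed to expose.
    """
    return {
        "ses->cog_child": 0.30,
        "overcrowding->cog_child": -0.10,
        "cog_child->education": 0.45,
        "ses->education": 0.25,
        "education->bmi_adult": -0.15,
        "cog_child->bmi_adult": -0.05,
        "parents_bmi->bmi_child": 0.30,
        "ses->bmi_child": -0.05,
        "cog_child->cog_mid": 0.55,
        "education->cog_mid": 0.20,
        "exposure->cog_mid": 0.0,
        "bmi_child->cog_mid": 0.0,
        "sex->cog_mid": 0.05,
        "ses->cog_mid": 0.10,
    }


def default_missing_rates() -> dict[str, float]:
    """Per-variable missingness proportions.

    Chosen to resemble the observed-n gradients of long-running birth
    cohorts (adolescent BMI the most incomplete; midlife cognition complete
    by inclusion; cohort, sex and SES always observed so the MAR mechanism
    conditions only on observed data).
    """
    rates = {
        "bmi_10": 0.15, "bmi_16": 0.30, "bmi_23": 0.15,
        "bmi_33": 0.10, "bmi_42": 0.08, "bmi_50": 0.12,
        "mother_bmi": 0.12, "father_bmi": 0.20, "birthweight": 0.05,
        "overcrowding": 0.07, "education": 0.12,
    }
    rates.update({c: 0.13 for c in CHILD_TESTS})
    return rates


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic multi-cohort dataset."""

    n_per_cohort: int = 2000
    cohort_bmi_shift: tuple[float, float, float] = (0.0, 0.7, 1.4)
    loadings_child: tuple[float, ...] = (0.8, 0.7, 0.6, 0.5)
    loadings_mid: tuple[float, ...] = (0.75, 0.8, 0.6, 0.55)
    uniquenesses: tuple[float, ...] | None = None   # default: 1 - loading^2
    path_coefficients: dict[str, float] = field(default_factory=default_path_coefficients)
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.uniquenesses is None:
            lam = np.concatenate([self.loadings_child, self.loadings_mid])
            self.uniquenesses = tuple(1.0 - lam**2)
        self.validate()

    def validate(self) -> None:
        if self.n_per_cohort < 1:
            raise ValueError("n_per_cohort must be >= 1")
        if len(self.cohort_bmi_shift) != 3:
            raise ValueError("cohort_bmi_shift must have length 3")
        for name, lam in (("loadings_child", self.loadings_child),
                          ("loadings_mid", self.loadings_mid)):
            if len(lam) != 4 or any(v <= 0 for v in lam):
                raise ValueError(f"{name}: need 4 positive loadings")
        if len(self.uniquenesses) != 8 or any(v <= 0 for v in self.uniquenesses):
            raise ValueError("uniquenesses: need 8 positive variances")
        for k, v in self.path_coefficients.items():
            if not -1 < v < 1:
                raise ValueError(f"path_coefficients[{k!r}]={v} outside (-1, 1)")
        for k, v in self.missing_rates.items():
            if not 0 <= v < 1:
                raise ValueError(f"missing_rates[{k!r}]={v} outside [0, 1)")

    def to_dict(self) -> dict:
        return dict(
            n_per_cohort=int(self.n_per_cohort),
            cohort_bmi_shift=[float(v) for v in self.cohort_bmi_shift],
            loadings_child=[float(v) for v in self.loadings_child],
            loadings_mid=[float(v) for v in self.loadings_mid],
            uniquenesses=[float(v) for v in self.uniquenesses],
            path_coefficients={k: float(v) for k, v in self.path_coefficients.items()},
            missing_rates={k: float(v) for k, v in self.missing_rates.items()},
            seed=int(self.seed),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        for k in ("cohort_bmi_shift", "loadings_child", "loadings_mid", "uniquenesses"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def default_truth(seed: int = 0, n_per_cohort: int = 2000, with_missingness: bool = True) -> GroundTruth:
    rates = default_missing_rates() if with_missingness else {}
    return GroundTruth(n_per_cohort=n_per_cohort, seed=seed, missing_rates=rates)


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _ordinalize(latent: np.ndarray, cum: tuple[float, ...]) -> np.ndarray:
    """Cut a latent normal at fixed population quantiles into 1..k codes."""
    from scipy.stats import norm

    cuts = norm.ppf(cum)
    return 1.0 + np.searchsorted(cuts, latent, side="right").astype(float)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _mean_bmi_curve(age: float) -> float:
    # population mean BMI at the nominal ages, reference (earliest) cohort
    table = dict(zip(NOMINAL_AGES, (17.2, 20.4, 22.4, 24.2, 25.3, 27.0)))
    return table[age]


def generate_cohorts(truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a complete-data cohort table plus the true latent factors.

    BMI at the six nominal ages follows a person-level growth curve: a
    cohort-shifted mean curve plus a person random intercept (loaded on
    parents' BMI and SES) and random slope, with the structural effect of
    childhood cognition entering only at adult ages (>= 23) through achieved
    education and a small direct path, plus occasion-level noise.  Cognitive
    test scores are loadings x factor + unique noise, rescaled to
    instrument-like units.
    """
    truth.validate()
    n = truth.n_per_cohort
    N = 3 * n
    pc = truth.path_coefficients
    rng = _streams(truth.seed, [
        "family", "ses", "cog_child", "tests_child", "education",
        "growth", "cog_mid", "tests_mid",
    ])

    cohort = np.repeat(list(COHORTS), n)
    shift = np.repeat(np.asarray(truth.cohort_bmi_shift, dtype=float), n)
    sex = rng["family"].integers(0, 2, size=N).astype(float)
    sex_c = 2.0 * (sex - 0.5)  # +-1 coding, unit scale

    # family background: shared parental adiposity + social position
    fam = rng["family"].standard_normal(N)
    mother_bmi = 23.0 + 3.0 * (0.7 * fam + np.sqrt(1 - 0.49) * rng["family"].standard_normal(N))
    father_bmi = 24.0 + 3.2 * (0.7 * fam + np.sqrt(1 - 0.49) * rng["family"].standard_normal(N))
    birthweight = 3.35 + 0.5 * (0.25 * fam + np.sqrt(1 - 0.0625) * rng["family"].standard_normal(N))

    ses_lat = rng["ses"].standard_normal(N)
    oc_lat = -0.5 * ses_lat + np.sqrt(1 - 0.25) * rng["ses"].standard_normal(N)
    ses = _ordinalize(ses_lat, _SES_CUM)
    overcrowding = _ordinalize(oc_lat, _OVERCROWD_CUM)
    z_ses, z_oc = _zscore(ses), _zscore(overcrowding)

    # childhood cognition: unit-variance latent loaded on social background
    b_ses, b_oc = pc["ses->cog_child"], pc["overcrowding->cog_child"]
    lin = b_ses * z_ses + b_oc * z_oc
    res_var = max(1.0 - np.var(lin), 0.05)
    cog_child = lin + np.sqrt(res_var) * rng["cog_child"].standard_normal(N)
    cog_child = _zscore(cog_child)

    lam_c = np.asarray(truth.loadings_child)
    psi = np.asarray(truth.uniquenesses)
    child_scores = {}
    for j, name in enumerate(CHILD_TESTS):
        zj = lam_c[j] * cog_child + np.sqrt(psi[j]) * rng["tests_child"].standard_normal(N)
        m, s = _CHILD_SCALES[j]
        child_scores[name] = m + s * zj / np.sqrt(lam_c[j] ** 2 + psi[j])

    # education from cognition and social position, thresholded to 4 levels
    b_cog, b_s = pc["cog_child->education"], pc["ses->education"]
    lin = b_cog * cog_child + b_s * z_ses
    res_var = max(1.0 - np.var(lin), 0.05)
    edu_lat = lin + np.sqrt(res_var) * rng["education"].standard_normal(N)
    education = _ordinalize(_zscore(edu_lat), _EDU_CUM)
    z_edu = _zscore(education)

    # person growth curve: random intercept/slope + adult-age structural effects
    u0 = 2.0 * (
        pc["parents_bmi->bmi_child"] * fam
        + pc["ses->bmi_child"] * z_ses
        + np.sqrt(max(1 - pc["parents_bmi->bmi_child"] ** 2 - pc["ses->bmi_child"] ** 2, 0.1))
        * rng["growth"].standard_normal(N)
    )
    u1 = 0.04 * (0.2 * u0 / 2.0 + np.sqrt(1 - 0.04) * rng["growth"].standard_normal(N))
    adult_effect = _ADULT_BMI_SD * (
        pc["education->bmi_adult"] * z_edu + pc["cog_child->bmi_adult"] * cog_child
    )
    bmi = {}
    for age, col in zip(NOMINAL_AGES, BMI_COLUMNS):
        x = (
            _mean_bmi_curve(age) + shift + u0 + u1 * (age - 10.0)
            + (adult_effect if age >= 23 else 0.0)
            + 0.8 * rng["growth"].standard_normal(N)
        )
        bmi[col] = np.clip(x, 12.0, 65.0)

    # cumulative exposure computed from the generated curve, so that any
    # generating exposure->cognition path acts through the analysis-scale metric
    auc = _complete_auc(bmi)
    z_auc = _zscore(auc)
    z_bmi10 = _zscore(bmi["bmi_10"])

    lin = (
        pc["cog_child->cog_mid"] * cog_child
        + pc["education->cog_mid"] * z_edu
        + pc["exposure->cog_mid"] * z_auc
        + pc["bmi_child->cog_mid"] * z_bmi10
        + pc["sex->cog_mid"] * sex_c
        + pc["ses->cog_mid"] * z_ses
    )
    res_var = max(1.0 - np.var(lin), 0.05)
    cog_mid = _zscore(lin + np.sqrt(res_var) * rng["cog_mid"].standard_normal(N))

    lam_m = np.asarray(truth.loadings_mid)
    mid_scores = {}
    for j, name in enumerate(MID_TESTS):
        zj = lam_m[j] * cog_mid + np.sqrt(psi[4 + j]) * rng["tests_mid"].standard_normal(N)
        m, s = _MID_SCALES[j]
        mid_scores[name] = m + s * zj / np.sqrt(lam_m[j] ** 2 + psi[4 + j])

    # age at the midlife assessment: later cohorts assessed younger
    age_mid_center = np.repeat([53.0, 50.0, 47.0], n)
    age_mid_sd = np.repeat([0.5, 1.0, 1.0], n)
    age_midlife = age_mid_center + age_mid_sd * rng["family"].standard_normal(N)

    table = pd.DataFrame({
        "person_id": np.arange(N),
        "cohort": cohort,
        "sex": sex,
        "age_midlife": age_midlife,
        **bmi,
        **child_scores,
        **mid_scores,
        "mother_bmi": mother_bmi,
        "father_bmi": father_bmi,
        "birthweight": birthweight,
        "overcrowding": overcrowding,
        "ses": ses,
        "education": education,
    })
    latents = pd.DataFrame({
        "person_id": np.arange(N),
        "cog_child": cog_child,
        "cog_mid": cog_mid,
        "auc_true": auc,
        "education_latent": edu_lat,
    })
    return table, latents


def _complete_auc(bmi: dict[str, np.ndarray], threshold: float = 25.0,
                  window: tuple[float, float] = (10.0, 40.0)) -> np.ndarray:
    """Vectorised exact BMI-years AUC on complete generated trajectories."""
    ages = np.asarray(NOMINAL_AGES)
    vals = np.column_stack([bmi[c] for c in BMI_COLUMNS])
    lo, hi = window
    grid = np.unique(np.concatenate([ages[(ages > lo) & (ages < hi)], [lo, hi]]))
    interp = np.vstack([np.interp(grid, ages, row) for row in vals])
    total = np.zeros(vals.shape[0])
    for k in range(grid.size - 1):
        t0, t1 = grid[k], grid[k + 1]
        e0, e1 = interp[:, k] - threshold, interp[:, k + 1] - threshold
        both_up = (e0 > 0) & (e1 > 0)
        up_down = (e0 > 0) & (e1 <= 0)
        down_up = (e0 <= 0) & (e1 > 0)
        dt = t1 - t0
        area = np.zeros_like(total)
        area[both_up] = 0.5 * (e0[both_up] + e1[both_up]) * dt
        with np.errstate(divide="ignore", invalid="ignore"):
            tc = t0 + (0.0 - e0) / (e1 - e0) * dt
        area[up_down] = 0.5 * e0[up_down] * (tc[up_down] - t0)
        area[down_up] = 0.5 * e1[down_up] * (t1 - tc[down_up])
        total += area
    return total


def apply_missingness(
    table: pd.DataFrame, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impose missing-at-random missingness; returns (masked table, mask).

    For each variable with a positive rate, the missingness probability is a
    logistic function of always-observed variables only (cohort, sex, SES),
    with the intercept solved so the expected proportion equals the
    configured rate; this makes the mechanism MAR by construction.  The mask
    table codes 1 = missing.
    """
    truth.validate()
    rng = _streams(truth.seed, ["missingness"])["missingness"]
    out = table.copy()
    mask = pd.DataFrame(0, index=table.index, columns=table.columns, dtype=int)
    z_ses = _zscore(table["ses"].to_numpy(float))
    sex_c = 2.0 * (table["sex"].to_numpy(float) - 0.5)
    cohort_idx = table["cohort"].map({c: i for i, c in enumerate(COHORTS)}).to_numpy(float)
    score = 0.5 * (-z_ses) + 0.2 * sex_c + 0.25 * (cohort_idx - 1.0)
    for var, rate in sorted(truth.missing_rates.items()):
        if rate <= 0:
            continue
        if var not in table.columns:
            raise ValueError(f"missing_rates names unknown variable {var!r}")
        if var in ("cohort", "sex", "ses", "person_id"):
            raise ValueError(f"{var!r} must stay always-observed (MAR conditioning set)")

        def mean_rate(alpha):
            return expit(alpha + score).mean() - rate

        alpha = brentq(mean_rate, -30.0, 30.0)
        p = expit(alpha + score)
        miss = rng.random(len(table)) < p
        out.loc[miss, var] = np.nan
        mask.loc[miss, var] = 1
    return out, mask


# ---------------------------------------------------------------------------
# linear-Gaussian cross-lagged system for SEM validation
# ---------------------------------------------------------------------------

SEM_STRUCTURAL = ("bmi_child", "education", "exposure", "bmi_mid")


def default_sem_truth() -> dict[str, float]:
    """Standardised generating paths for the cross-lagged core system.

    The childhood-cognition -> adult-weight cross-lag is -0.10 and the
    reverse (childhood weight -> midlife cognition) lags are zero, the
    asymmetric structure the cross-lagged model is built to separate.
    """
    return {
        "cog_child->education": 0.45,
        "bmi_child->education": -0.05,
        "cog_child->exposure": -0.10,
        "bmi_child->exposure": 0.35,
        "education->exposure": -0.15,
        "cog_child->cog_mid": 0.55,
        "bmi_child->cog_mid": 0.0,
        "education->cog_mid": 0.20,
        "exposure->cog_mid": 0.0,
        "cog_child->bmi_mid": -0.05,
        "bmi_child->bmi_mid": 0.30,
        "education->bmi_mid": -0.10,
        "exposure->bmi_mid": 0.45,
        "cog_child~~bmi_child": -0.15,
    }


def generate_sem_dataset(
    n: int,
    seed: int,
    paths: dict[str, float] | None = None,
    loadings_child: tuple[float, ...] = (0.8, 0.7, 0.6, 0.5),
    loadings_mid: tuple[float, ...] = (0.75, 0.8, 0.6, 0.55),
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate the cross-lagged linear system on standardised scales.

    Every variable (latent or observed) has unit variance by construction,
    so the generating coefficients are themselves the standardised truth a
    correctly specified FIML fit should recover.  Residual variances are
    derived analytically from the running implied covariance of the already
    generated variables.  Optional MCAR masking deletes each observed cell
    independently with probability ``missing_rate``.
    """
    paths = dict(default_sem_truth() if paths is None else paths)
    rng = _streams(seed, ["exo", "struct", "ind", "mask"])

    phi = paths.get("cog_child~~bmi_child", 0.0)
    cov = np.array([[1.0, phi], [phi, 1.0]])
    L = np.linalg.cholesky(cov)
    exo = rng["exo"].standard_normal((n, 2)) @ L.T
    values = {"cog_child": exo[:, 0], "bmi_child": exo[:, 1]}
    implied = {("cog_child", "cog_child"): 1.0, ("bmi_child", "bmi_child"): 1.0,
               ("cog_child", "bmi_child"): phi, ("bmi_child", "cog_child"): phi}

    order = ["education", "exposure", "cog_mid", "bmi_mid"]
    parents_of = {v: [] for v in order}
    for edge, val in paths.items():
        if "->" not in edge:
            continue
        src, dst = edge.split("->")
        parents_of[dst].append((src, val))

    for var in order:
        pars = parents_of[var]
        lin = np.zeros(n)
        for (pi, ci) in pars:
            lin += ci * values[pi]
        var_lin = sum(
            ci * cj * implied[(pi, pj)] for (pi, ci) in pars for (pj, cj) in pars
        )
        if var_lin >= 1.0:
            raise ValueError(f"paths into {var!r} imply variance >= 1")
        e = np.sqrt(1.0 - var_lin) * rng["struct"].standard_normal(n)
        values[var] = lin + e
        # update implied covariances: cov(var, w) = sum_i c_i cov(p_i, w)
        for w in list({k[0] for k in implied}):
            implied[(var, w)] = implied[(w, var)] = sum(
                ci * implied[(pi, w)] for (pi, ci) in pars
            )
        implied[(var, var)] = 1.0

    data = {}
    for j, lam in enumerate(loadings_child):
        data[CHILD_TESTS[j]] = lam * values["cog_child"] + np.sqrt(1 - lam**2) * (
            rng["ind"].standard_normal(n)
        )
    for j, lam in enumerate(loadings_mid):
        data[MID_TESTS[j]] = lam * values["cog_mid"] + np.sqrt(1 - lam**2) * (
            rng["ind"].standard_normal(n)
        )
    for var in SEM_STRUCTURAL:
        data[var] = values[var]
    df = pd.DataFrame(data)
    if missing_rate > 0:
        mask = rng["mask"].random(df.shape) < missing_rate
        df = df.mask(mask)
    truth = {k: v for k, v in paths.items() if "->" in k}
    truth["cog_child~~bmi_child"] = phi
    return df, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohorts(table: pd.DataFrame, path) -> None:
    """UTF-8 CSV with header, missing cells as empty fields."""
    table.to_csv(path, index=False, na_rep="")


def read_cohorts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["cohort"] = df["cohort"].astype(str)
    return df
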