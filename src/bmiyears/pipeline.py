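"""End-to-end orchestration: simulate -> exposures -> latent -> impute ->
regress -> sem -> report.

Each stage reads the previous stage's delimited-text artifacts from the
output directory, writes its own, and records itself in a JSON run manifest
(seed, row counts, warnings).  A re-run with the same config and seed
reproduces the simulated inputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exposures as expo
from . import impute as imp
from . import latent as lat
from . import regress as reg
from . import sem as semmod
from . import simulate as simu

log = logging.getLogger(__name__)

STAGES = ("simulate", "exposures", "latent", "impute", "regress", "sem", "report")

_STAGE_DEPS = {
    "simulate": (),
    "exposures": ("simulate",),
    "latent": ("simulate",),
    "impute": ("simulate",),
    "regress": ("exposures", "latent", "impute"),
    "sem": ("exposures", "latent"),
    "report": ("regress",),
}


@dataclass
class RunConfig:
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    n_per_cohort: int = 1000
    m_imputations: int = 5
    mice_iterations: int = 5
    threshold: float = 25.0
    window: tuple[float, float] = (10.0, 40.0)
    model_file: str | None = None
    output_dir: str = "bmiyears_run"
    strict: bool = False
    with_missingness: bool = True

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        order = {s: i for i, s in enumerate(STAGES)}
        if list(self.stages) != sorted(self.stages, key=order.get):
            raise ValueError("stages must respect the dependency order "
                             f"{' -> '.join(STAGES)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "window" in d:
            d["window"] = tuple(d["window"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class MissingArtifactError(FileNotFoundError):
    pass


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"{path.name} not found: run the {producing_stage!r} stage first"
        )
    return path


def prepare_analysis(
    table: pd.DataFrame,
    latent_models: dict | None = None,
    threshold: float = 25.0,
    window: tuple[float, float] = (10.0, 40.0),
) -> pd.DataFrame:
    """Derive all analysis variables from a (possibly completed) cohort table.

    Adds per-person excess-bodyweight metrics (recomputed passively from the
    table's BMI values, so imputed datasets get their own), scaled exposure
    units, within-cohort age-specific BMI z-scores, residualised BMI changes,
    and the childhood/midlife cognition factor scores.
    """
    out = table.copy()
    ex = expo.exposure_table(table, threshold=threshold, window=window)
    scaled = expo.scale_exposures(ex)
    out = out.merge(ex[["person_id", "ever_exposed", "onset_age", "duration_years",
                        "auc_bmi_years"]], on="person_id")
    out = out.merge(scaled.table[["person_id", "duration_decades", "auc_sd_units"]],
                    on="person_id")
    z = expo.age_specific_zscores(table, by_cohort=True)
    out = out.merge(z, on="person_id")
    ages = [10, 16, 23, 33, 42, 50]
    for a0, a1 in zip(ages[:-1], ages[1:]):
        r = expo.residual_change(table, (a0, a1))
        out[f"dbmi_{a0}_{a1}"] = r.reindex(out["person_id"]).to_numpy()
    if latent_models is None:
        child_scores, child_models = lat.fit_scores(out, list(simu.CHILD_TESTS))
        mid_scores, mid_models = lat.fit_scores(out, list(simu.MID_TESTS))
    else:
        child_models, mid_models = latent_models["child"], latent_models["mid"]
        child_scores = _scores_from_models(out, child_models, list(simu.CHILD_TESTS))
        mid_scores = _scores_from_models(out, mid_models, list(simu.MID_TESTS))
    out["cog_child_score"] = child_scores
    out["cog_mid_score"] = mid_scores
    out["cog_tertile"] = lat.tertile_split(out["cog_child_score"], out["cohort"])
    return out


def _scores_from_models(table, models, cols):
    scores = pd.Series(np.nan, index=table.index, dtype=float)
    for name, g in table.groupby("cohort", observed=True):
        scores.loc[g.index] = lat.factor_scores(models[name], g[cols]).to_numpy()
    ok = scores.notna()
    scores[ok] = (scores[ok] - scores[ok].mean()) / scores[ok].std(ddof=1)
    return scores


EXPOSURE_FAMILIES = (
    ["z_bmi_10", "z_bmi_16", "z_bmi_23", "z_bmi_33", "z_bmi_42", "z_bmi_50"]
    + ["dbmi_10_16", "dbmi_16_23", "dbmi_23_33", "dbmi_33_42", "dbmi_42_50"]
    + ["duration_decades", "auc_sd_units"]
)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order; returns the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = dict(
        seed=config.seed, config_hash=config.config_hash(),
        config=asdict(config), stages={}, warnings=[],
    )
    t_start = time.time()
    for stage in config.stages:
        t0 = time.time()
        info = _STAGE_RUNNERS[stage](config, out, manifest)
        info["seconds"] = round(time.time() - t0, 2)
        manifest["stages"][stage] = info
        log.info("stage %s done in %.1fs", stage, info["seconds"])
    manifest["total_seconds"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_simulate(config: RunConfig, out: Path, manifest: dict) -> dict:
    truth = simu.default_truth(seed=config.seed, n_per_cohort=config.n_per_cohort,
                               with_missingness=config.with_missingness)
    table, latents = simu.generate_cohorts(truth)
    masked, mask = simu.apply_missingness(table, truth)
    simu.write_cohorts(table, out / "cohorts_complete.csv")
    simu.write_cohorts(masked, out / "cohorts.csv")
    mask.to_csv(out / "missingness_mask.csv", index=False)
    latents.to_csv(out / "latents.csv", index=False)
    (out / "truth.yaml").write_text(yaml.safe_dump(truth.to_dict(), sort_keys=False))
    return dict(rows=len(table), missing_cells=int(mask.to_numpy().sum()))


def _stage_exposures(config: RunConfig, out: Path, manifest: dict) -> dict:
    table = simu.read_cohorts(_require(out / "cohorts.csv", "simulate"))
    ex = expo.exposure_table(table, threshold=config.threshold, window=config.window)
    ex.to_csv(out / "exposures.csv", index=False)
    z = expo.age_specific_zscores(table, by_cohort=True)
    z.to_csv(out / "bmi_zscores.csv", index=False)
    if ex.attrs.get("n_insufficient", 0):
        manifest["warnings"].append(
            f"exposures: {ex.attrs['n_insufficient']} persons with insufficient trajectory")
    return dict(rows=len(ex), n_insufficient=ex.attrs.get("n_insufficient", 0),
                ever_exposed=int(np.nansum(ex["ever_exposed"])))


def _stage_latent(config: RunConfig, out: Path, manifest: dict) -> dict:
    table = simu.read_cohorts(_require(out / "cohorts.csv", "simulate"))
    child_scores, child_models = lat.fit_scores(table, list(simu.CHILD_TESTS))
    mid_scores, mid_models = lat.fit_scores(table, list(simu.MID_TESTS))
    scores = table[["person_id"]].copy()
    scores["cog_child_score"] = child_scores
    scores["cog_mid_score"] = mid_scores
    scores.to_csv(out / "cognition_scores.csv", index=False)
    models_json = {
        "child": {k: json.loads(m.to_json()) for k, m in child_models.items()},
        "mid": {k: json.loads(m.to_json()) for k, m in mid_models.items()},
    }
    (out / "latent_models.json").write_text(json.dumps(models_json, indent=2))
    return dict(rows=len(scores),
                mean_child_loading=float(np.mean(
                    [m.loadings.mean() for m in child_models.values()])))


def _stage_impute(config: RunConfig, out: Path, manifest: dict) -> dict:
    table = simu.read_cohorts(_require(out / "cohorts.csv", "simulate"))
    iset = imp.mice(table, m=config.m_imputations, iterations=config.mice_iterations,
                    seed=config.seed)
    iset.write(out / "imputed")
    if iset.diagnostics:
        manifest["warnings"].extend(iset.diagnostics[:20])
    return dict(m=iset.m, iterations=iset.iterations,
                n_fallbacks=len(iset.diagnostics))


def _stage_regress(config: RunConfig, out: Path, manifest: dict) -> dict:
    imp_dir = out / "imputed"
    _require(imp_dir / "imputed_manifest.json", "impute")
    man = json.loads((imp_dir / "imputed_manifest.json").read_text())
    raw_sets = [simu.read_cohorts(imp_dir / f"imputed_{i + 1:02d}.csv")
                for i in range(man["m"])]
    prepared = [prepare_analysis(df, threshold=config.threshold, window=config.window)
                for df in raw_sets]
    iset = imp.ImputedSet(datasets=prepared, method_map=man["method_map"],
                          seed=man["seed"], iterations=man["iterations"])
    grid = reg.estimate_grid(iset, "cog_mid_score", EXPOSURE_FAMILIES, pooled=True)
    grid.to_csv(out / "regression_estimates.csv", index=False)
    first = prepared[0]
    zcols = [f"z_bmi_{a}" for a in (10, 16, 23, 33, 42, 50)]
    traj_min = reg.tertile_trajectories(first, zcols, adjustment=["sex"])
    traj_adj = reg.tertile_trajectories(
        first, zcols,
        adjustment=["sex", "mother_bmi", "father_bmi", "birthweight", "overcrowding", "ses"])
    traj_min.to_csv(out / "tertile_trajectories_minimal.csv", index=False)
    traj_adj.to_csv(out / "tertile_trajectories_adjusted.csv", index=False)
    reg.plot_tertile_trajectories(traj_min, [10, 16, 23, 33, 42, 50],
                                  out / "tertile_trajectories.png")
    return dict(estimates=len(grid))


def _stage_sem(config: RunConfig, out: Path, manifest: dict) -> dict:
    table = simu.read_cohorts(_require(out / "cohorts.csv", "simulate"))
    prepared = prepare_analysis(table, threshold=config.threshold, window=config.window)
    if config.model_file:
        spec = semmod.SEMSpec.from_file(config.model_file)
    else:
        spec = semmod.default_spec(list(simu.CHILD_TESTS), list(simu.MID_TESTS))
    results = {}
    for cohort, g in prepared.groupby("cohort", observed=True):
        frame = _sem_frame(g)
        try:
            res = semmod.fiml_fit(spec, frame, indirect_chains=[
                [("cog_child", "education"), ("education", "bmi_mid")],
                [("cog_child", "exposure"), ("exposure", "bmi_mid")],
                [("cog_child", "education"), ("education", "exposure"),
                 ("exposure", "bmi_mid")],
            ])
        except semmod.NotConvergedError as exc:
            manifest["warnings"].append(f"sem cohort {cohort}: {exc}")
            if config.strict:
                raise
            continue
        results[cohort] = res
        (out / f"sem_{cohort}.json").write_text(res.to_json())
        res.edge_table().to_csv(out / f"sem_{cohort}_edges.csv", index=False)
    return dict(cohorts_fit=sorted(results),
                rmsea={c: round(r.fit.rmsea, 4) for c, r in results.items() if r.fit})


def _sem_frame(g: pd.DataFrame) -> pd.DataFrame:
    """Assemble the SEM's observed columns on analysis scales for one cohort."""
    frame = g[list(simu.CHILD_TESTS) + list(simu.MID_TESTS)].copy()
    frame["bmi_child"] = g["z_bmi_10"]
    frame["education"] = g["education"]
    frame["exposure"] = g["auc_sd_units"]
    frame["bmi_mid"] = g["z_bmi_50"]
    frame["sex"] = g["sex"]
    frame["overcrowding"] = g["overcrowding"]
    frame["ses"] = g["ses"]
    return frame.reset_index(drop=True)


def _stage_report(config: RunConfig, out: Path, manifest: dict) -> dict:
    from .report import build_report

    path = build_report(out)
    return dict(report=str(path))


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "exposures": _stage_exposures,
    "latent": _stage_latent,
    "impute": _stage_impute,
    "regress": _stage_regress,
    "sem": _stage_sem,
    "report": _stage_report,
}
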