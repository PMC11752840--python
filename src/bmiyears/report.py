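"""Markdown report assembly from pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def build_report(run_dir) -> Path:
    """Tabulate regression and SEM outputs into ``report.md``.

    Requires at least one of the regression or SEM artifacts; sections whose
    artifacts are absent are replaced by a notice.
    """
    run_dir = Path(run_dir)
    if not run_dir.exists():
        raise FileNotFoundError(f"output directory {run_dir} does not exist")
    reg_path = run_dir / "regression_estimates.csv"
    sem_paths = sorted(run_dir.glob("sem_*_edges.csv"))
    if not reg_path.exists() and not sem_paths:
        raise FileNotFoundError("no regression or SEM artifacts to report on")

    lines = ["# Excess bodyweight and midlife cognition: run report", ""]
    man_path = run_dir / "manifest.json"
    if man_path.exists():
        man = json.loads(man_path.read_text())
        lines += [f"Seed {man['seed']}, config hash `{man['config_hash']}`.", ""]

    lines += ["## Exposure-by-adjustment estimate grid", ""]
    if reg_path.exists():
        grid = pd.read_csv(reg_path)
        wide = grid.pivot_table(index="exposure", columns="model", values="beta")
        wide = wide.reindex(columns=["model1", "model2", "model3"])
        lines.append(_md_table(wide.round(3).reset_index()))
        lines.append("")
        lines.append("Betas are SD of midlife cognition per exposure unit; "
                     "model 1 adjusts age and sex, model 2 adds childhood cognition, "
                     "model 3 adds the early-life covariate block.")
    else:
        lines.append("_Regression artifacts absent; run the regress stage._")
    lines.append("")

    traj = run_dir / "tertile_trajectories_minimal.csv"
    if traj.exists():
        lines += ["## BMI trajectories by childhood-cognition tertile", "",
                  "See `tertile_trajectories.png`; tables in "
                  "`tertile_trajectories_minimal.csv` / `_adjusted.csv`.", ""]

    lines += ["## Cross-lagged SEM", ""]
    if sem_paths:
        for p in sem_paths:
            cohort = p.stem.replace("sem_", "").replace("_edges", "")
            df = pd.read_csv(p)
            paths_only = df[df["parameter"].str.contains("->")]
            lines.append(f"### Cohort {cohort}")
            lines.append("")
            lines.append(_md_table(paths_only[["parameter", "std_estimate", "std_se"]]
                                   .round(3)))
            fitj = run_dir / f"sem_{cohort}.json"
            if fitj.exists():
                fit = json.loads(fitj.read_text()).get("fit")
                if fit:
                    lines.append("")
                    lines.append(
                        f"Fit: chi2={fit['chi2']:.1f} (df={fit['df']}), "
                        f"RMSEA={fit['rmsea']:.3f}, CFI={fit['cfi']:.3f}, "
                        f"TLI={fit['tli']:.3f}")
            lines.append("")
    else:
        lines.append("_SEM artifacts absent; run the sem stage._")
    lines.append("")

    imp_man = run_dir / "imputed" / "imputed_manifest.json"
    if imp_man.exists():
        man = json.loads(imp_man.read_text())
        lines += ["## Imputation", "",
                  f"m={man['m']} completed datasets, {man['iterations']} cycles each; "
                  f"{len(man.get('diagnostics', []))} fallback warnings.", ""]

    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path


def _md_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    head = "| " + " | ".join(str(c) for c in cols) + " |"
    sep = "|" + "|".join("---" for _ in cols) + "|"
    rows = ["| " + " | ".join(str(v) for v in rec) + " |" for rec in df.to_numpy()]
    return "\n".join([head, sep] + rows)
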