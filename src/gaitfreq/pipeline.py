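"""End-to-end orchestration: simulate -> features -> fit -> evaluate -> severity.

A single run produces seven artifacts in the output directory (features
CSV, CV curve JSON, coefficient-path CSV, coefficient report CSV, two
evaluation JSONs, severity CSV) plus a MANIFEST.json with checksums, the
seed, a config hash and per-stage timings.  One global seed is expanded
into independent per-stage streams so adding a stage never perturbs the
draws of earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import default_config, generate_cohort, read_metadata, read_trial
from .evaluate import compare_models
from .features import build_feature_table
from .lasso import cv_select_lambda, fit_at, fit_path
from .selective import selective_inference
from .severity import (
    KOOS_CRITERIA,
    assign_groups,
    auxiliary_tests,
    compare_table3,
    selected_feature_boxdata,
)
from .signal import cohort_feature_frame

log = logging.getLogger("gaitfreq")

ARTIFACTS = (
    "features.csv",
    "cv_curve.json",
    "lasso_path.csv",
    "coefficients.csv",
    "eval_full.json",
    "eval_confounders.json",
    "severity.csv",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the exit status."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, analysis parameters and mode flags of one pipeline run."""

    out_dir: str = "gaitfreq_out"
    seed: int = 0
    simulate: bool = True
    trials_dir: str | None = None
    metadata_csv: str | None = None
    n_harmonics: int = 6
    n_cycles: int = 10
    m_points: int = 64
    search_range: tuple = (0.4, 2.0)
    k_folds: int = 10
    n_repeats: int = 10
    train_frac: float = 0.75
    confounder_ablation: bool = True
    plots: bool = False
    cohort_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if not cfg.simulate:
            for p in (cfg.trials_dir, cfg.metadata_csv):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input path not resolvable: {p}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 4) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(cfg: RunConfig, cohort_seed: int, choice_seed: int):
    if cfg.simulate:
        sim_cfg = default_config(seed=cohort_seed, **cfg.cohort_overrides)
        return generate_cohort(sim_cfg)
    participants = read_metadata(cfg.metadata_csv)
    rng = np.random.default_rng(choice_seed)
    trials = []
    tdir = Path(cfg.trials_dir)
    for p in sorted(participants, key=lambda q: q.id):
        single = tdir / f"{p.id}.csv"
        if single.exists():
            trials.append(read_trial(single, p.id))
            continue
        candidates = sorted(tdir.glob(f"{p.id}_*.csv"))
        if not candidates:
            raise FileNotFoundError(f"no trial file for participant {p.id}")
        # randomly select the first or second recorded walk, seeded
        trials.append(read_trial(candidates[rng.integers(len(candidates))], p.id))
    return participants, trials


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_seed, cv_seed, eval_seed, choice_seed = _stage_seeds(cfg.seed)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "complete": False,
        "artifacts": {},
        "timings_s": {},
        "warnings": [],
    }

    def finish(stage, err=None):
        if err is not None:
            manifest["failed_stage"] = stage
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    def record(name):
        path = out / name
        manifest["artifacts"][name] = _sha256(path)

    state = {}
    stages = [
        ("cohort", _stage_cohort),
        ("features", _stage_features),
        ("fit", _stage_fit),
        ("evaluate", _stage_evaluate),
        ("severity", _stage_severity),
    ]
    seeds = {
        "cohort": cohort_seed,
        "cv": cv_seed,
        "eval": eval_seed,
        "choice": choice_seed,
    }
    for stage, fn in stages:
        t0 = time.perf_counter()
        try:
            fn(cfg, out, seeds, state, record)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
            finish(stage, exc)
            raise StageError(stage, exc) from exc
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2f s", stage, manifest["timings_s"][stage])
    manifest["complete"] = True
    finish(None)
    return manifest


def _stage_cohort(cfg, out, seeds, state, record):
    participants, trials = _load_cohort(cfg, seeds["cohort"], seeds["choice"])
    state["participants"], state["trials"] = participants, trials


def _stage_features(cfg, out, seeds, state, record):
    fdf = cohort_feature_frame(
        state["trials"],
        search_range=tuple(cfg.search_range),
        n_cycles=cfg.n_cycles,
        m_points=cfg.m_points,
    )
    fdf.to_csv(out / "features.csv")
    record("features.csv")
    state["feature_df"] = fdf
    state["table"] = build_feature_table(state["participants"], fdf)


def _stage_fit(cfg, out, seeds, state, record):
    table = state["table"]
    path = fit_path(table)
    path.coef_frame().to_csv(out / "lasso_path.csv", index=False)
    record("lasso_path.csv")

    cv = cv_select_lambda(table, k=cfg.k_folds, seed=seeds["cv"])
    (out / "cv_curve.json").write_text(
        json.dumps(
            {
                "lambdas": cv.lambdas.tolist(),
                "mean_deviance": cv.mean_deviance.tolist(),
                "se_deviance": cv.se_deviance.tolist(),
                "lambda_min": cv.lambda_min,
                "lambda_1se": cv.lambda_1se,
                "k": cv.k,
                "seed": cv.seed,
            },
            indent=2,
        )
    )
    record("cv_curve.json")

    fit = fit_at(table, cv.lambda_1se)
    report = pd.DataFrame(index=table.columns)
    report["coefficient"] = fit.coefficients
    report[["estimate", "lower", "upper", "p_value"]] = np.nan
    if fit.active_set:
        ci = selective_inference(fit, table)
        for col in ("estimate", "lower", "upper", "p_value"):
            report.loc[ci.table.index, col] = ci.table[col]
    report.index.name = "variable"
    with open(out / "coefficients.csv", "w") as fh:
        fh.write(f"# lambda_1se={cv.lambda_1se:.6g} seed={cfg.seed}\n")
        report.to_csv(fh)
    record("coefficients.csv")
    state["cv"], state["fit"] = cv, fit

    if cfg.plots:
        _plots(out, path, cv)


def _stage_evaluate(cfg, out, seeds, state, record):
    full, conf = compare_models(
        state["table"],
        seed=seeds["eval"],
        n_repeats=cfg.n_repeats,
        train_frac=cfg.train_frac,
        k_inner=cfg.k_folds,
    )
    full.to_json(out / "eval_full.json")
    record("eval_full.json")
    if cfg.confounder_ablation:
        conf.to_json(out / "eval_confounders.json")
    else:
        (out / "eval_confounders.json").write_text(json.dumps({"skipped": True}))
    record("eval_confounders.json")
    state["eval"] = (full, conf)


def _stage_severity(cfg, out, seeds, state, record):
    participants = state["participants"]
    fdf = state["feature_df"]
    # demographic variables can be active too; the severity report concerns
    # the selected gait features only
    selected = [f for f in state["fit"].active_set if f in fdf.columns]
    selected = selected or ["P_f2_CC"]
    frames = []
    for criterion in (*KOOS_CRITERIA, "kl"):
        grouping = assign_groups(participants, criterion)
        frames.append(selected_feature_boxdata(fdf, grouping, selected))
    severity = pd.concat(frames, ignore_index=True)
    severity.to_csv(out / "severity.csv", index=False)
    record("severity.csv")
    # side reports: patient-vs-control feature table and demographics tests
    groups = pd.Series({p.id: p.group for p in participants})
    compare_table3(fdf, groups).to_csv(out / "table3_features.csv")
    periods = {pid: 2 * np.pi / om for pid, om in fdf["omega"].items()}
    aux = auxiliary_tests(participants, periods)
    aux["sex_table"] = aux["sex_table"].to_dict()
    (out / "table2_aux.json").write_text(json.dumps(aux, indent=2, default=float))


def _plots(out, path, cv):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        np.log10(cv.lambdas), cv.mean_deviance, yerr=cv.se_deviance,
        fmt=".", ms=3, lw=0.5,
    )
    for lam, color in ((cv.lambda_min, "darkred"), (cv.lambda_1se, "salmon")):
        ax.axvline(np.log10(lam), ls="--", color=color)
    ax.set_xlabel("log10(lambda)")
    ax.set_ylabel("binomial deviance (CV mean +/- SE)")
    fig.tight_layout()
    fig.savefig(out / "cv_curve.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    with np.errstate(divide="ignore"):
        ax.plot(np.log10(path.lambdas), path.coefficients, lw=0.8)
    for lam, color in ((cv.lambda_min, "darkred"), (cv.lambda_1se, "salmon")):
        ax.axvline(np.log10(lam), ls="--", color=color)
    ax.set_xlabel("log10(lambda)")
    ax.set_ylabel("coefficient")
    fig.tight_layout()
    fig.savefig(out / "coef_profile.png", dpi=120)
    plt.close(fig)
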