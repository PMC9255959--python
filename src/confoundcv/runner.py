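"""Config-driven orchestration: simulate -> label -> checks -> explore ->
holdout -> attribute, with plain-text artifacts and full run metadata.

The experiment config is a YAML mapping with exactly one of a ``simulation``
block (cohort generator parameters) or an ``inputs`` block (a directory of
``features.csv`` / ``confounds.csv`` / ``phenotype.csv``).  Every stage
writes a diff-able text artifact into the output directory:

========================  ====================================================
``labels.csv``            subject_id, severity, label, included
``checks.tsv``            the five-combination diagnostic table
``explore_grid.tsv``      nested-CV mean/SD per model family
``holdout_result.json``   generalization-test scores and permutation p
``loso_result.json``      leave-one-site-out scores (stage ``loso``)
``importance.tsv``        per-run mean-|SHAP|, stability and direction
``run_metadata.json``     config, seeds, versions and recorded design choices
========================  ====================================================

Identical config + seeds reproduce identical numeric outputs for the
deterministic stages.
"""

from __future__ import annotations

import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import attribute, effect_direction, summarize_importance
from .checks import run_same_analysis_checks
from .cohort import Cohort, CohortConfig, cohort_summary, generate_cohort, load_cohort, save_cohort
from .confounds import ConfoundFrame
from .cv import (
    CVPlan,
    bonferroni_adjust,
    fit_pipeline,
    holdout_evaluate,
    leave_one_site_out,
    nested_cv,
    permutation_test,
    split_explore_holdout,
)
from .metrics import balanced_accuracy
from .models import ModelSpec
from .phenotypes import bin_severity, fit_trajectory, make_binary_labels
from .preprocessing import exclude_outlier_subjects

__all__ = ["ExperimentConfig", "run_experiment", "DESIGN_DECISIONS", "ALL_STAGES"]

ALL_STAGES = ("simulate", "label", "checks", "explore", "holdout", "attribute")

#: behavioral choices a reader of the artifacts should know about; every run
#: records them verbatim in run_metadata.json
DESIGN_DECISIONS = {
    "standardization": "population (divide-by-n) SD; zero-variance columns dropped; "
    "fitted on the (resampled) training rows only and applied unchanged to test rows",
    "standardization_vs_resampling": "standardizer fitted AFTER counterbalancing; the "
    "resampled set is what the model sees",
    "outlier_rule": "per-subject block-mean > 3 SD from the cohort block-mean, per "
    "feature block, applied at data preparation before any split",
    "severity_bins": "half-open [t_low, t_high); heavy inclusive at t_high; thresholds "
    "are configuration values",
    "trajectory_model": "per-subject OLS line on centered age summarizes the "
    "longitudinal scores",
    "counterbalancing_strata": "joint sex-by-site cells; equalizes label classes within "
    "every stratum, hence both confound marginals and the global class balance; strata "
    "missing one class are dropped with a warning",
    "onehot_convention": "drop-first + intercept for confound regression; full one-hot "
    "when confounds are classifier inputs",
    "multiclass_reduction": "one-vs-rest for SVM families on multiclass targets; native "
    "multiclass elsewhere; multiclass rows report balanced accuracy only (no AUC)",
    "hyperparameter_tiebreak": "grid order; the earliest combination wins ties",
    "inner_cv_metric": "balanced accuracy",
    "permutation_p": "add-one estimator (1 + #{null >= obs}) / (n_perm + 1); TRAIN "
    "labels shuffled, test labels fixed; label-independent stages prepared once",
    "holdout_retraining": "hyperparameters frozen from exploration; only model and "
    "resampling seeds vary across the 7 retrainings",
    "explore_holdout_stratification": "label x sex x site cells when all cells have "
    ">= 2 members, else label alone",
    "loso": "site is the CV unit in leave-one-site-out and cannot be counterbalanced; "
    "sex only",
    "shap_scale": "attributions on the decision-function scale (margin / log-odds)",
    "shap_background": "training rows sampled with a fixed seed",
    "stability_rule": "mean |SHAP| >= 2x grand mean (inclusive) in >= ceil(6k/7) of k "
    "runs",
}


class ExperimentConfig(dict):
    """Validated experiment configuration (a thin dict wrapper)."""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.validate(raw)

    @classmethod
    def validate(cls, raw: dict) -> "ExperimentConfig":
        has_sim = "simulation" in raw
        has_inp = "inputs" in raw
        if has_sim == has_inp:
            raise ValueError("config needs exactly one of 'simulation' or 'inputs'")
        if has_inp:
            d = Path(raw["inputs"]["dir"])
            for f in ("features.csv", "confounds.csv", "phenotype.csv"):
                if not (d / f).exists():
                    raise ValueError(f"missing input file {d / f}")
        cfg = cls(raw)
        cfg.setdefault("correction", "over")
        cfg.setdefault("seed", 0)
        cfg.setdefault("n_perm", 199)
        cfg.setdefault("n_holdout_seeds", 7)
        cfg.setdefault("model", {})
        cfg["model"].setdefault("families", ["logistic", "rbf-svm"])
        cfg.setdefault("cv", {})
        cfg.setdefault("phenotype", {})
        cfg["phenotype"].setdefault("mode", "final_score")
        cfg.setdefault("attribution", {})
        return cfg


def _build_cohort(cfg: ExperimentConfig, seed: int) -> Cohort:
    if "inputs" in cfg:
        return load_cohort(cfg["inputs"]["dir"])
    sim = dict(cfg["simulation"])
    sim.setdefault("seed", seed)
    return generate_cohort(CohortConfig(**sim))


def _label_cohort(cfg: ExperimentConfig, cohort: Cohort):
    ph = cfg["phenotype"]
    mode = ph["mode"]
    thresholds = cohort.truth.get("final_score_thresholds", {})
    t_low = ph.get("t_low", thresholds.get("t_low"))
    t_high = ph.get("t_high", thresholds.get("t_high"))
    if mode == "final_score":
        score = cohort.scores[:, -1]
    elif mode == "slope":
        score = fit_trajectory(cohort.scores, cohort.timepoints).slope
    else:
        raise ValueError(f"unknown phenotype mode {mode!r}")
    if t_low is None or t_high is None:
        raise ValueError("phenotype thresholds t_low/t_high are required")
    severity = bin_severity(score, float(t_low), float(t_high))
    return make_binary_labels(severity)


def run_experiment(
    config: str | Path | dict,
    seed: int | None = None,
    out: str | Path | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
    n_perm: int | None = None,
    correction: str | None = None,
) -> Path:
    """Execute the configured stages in order; returns the artifact directory.

    ``seed``, ``n_perm`` and ``correction`` override the config when given.
    A stage failure leaves the artifacts written so far plus an
    ``error_manifest.json`` naming the failed stage.
    """
    if isinstance(config, (str, Path)):
        cfg = ExperimentConfig.from_yaml(config)
    else:
        cfg = ExperimentConfig.validate(dict(config))
    if seed is not None:
        cfg["seed"] = int(seed)
    if n_perm is not None:
        cfg["n_perm"] = int(n_perm)
    if correction is not None:
        cfg["correction"] = correction
    outdir = Path(out if out is not None else cfg.get("out_dir", "confoundcv_run"))
    outdir.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    try:
        for stage in stages:
            _STAGE_FNS[stage](cfg, state, outdir)
    except Exception as exc:
        (outdir / "error_manifest.json").write_text(
            json.dumps({"failed_stage": stage, "error": repr(exc)}, indent=2)
        )
        raise
    _write_metadata(cfg, state, outdir)
    return outdir


def _stage_simulate(cfg, state, outdir):
    master = int(cfg["seed"])
    cohort = _build_cohort(cfg, master)
    # per-block outlier exclusion at data preparation, before any split
    keep = np.ones(cohort.n_subjects, dtype=bool)
    for block in ("t1w", "dti"):
        try:
            cols = cohort.block_columns(block)
        except KeyError:
            continue
        keep &= ~exclude_outlier_subjects(cohort.features[:, cols])
    state["n_outliers"] = int((~keep).sum())
    state["cohort"] = cohort.subset(keep)
    if cfg.get("write_cohort", False):
        save_cohort(state["cohort"], outdir / "cohort")
    cohort_summary(state["cohort"]).to_csv(outdir / "prevalence.tsv", sep="\t", index=False)


def _stage_label(cfg, state, outdir):
    cohort = state["cohort"]
    labels = _label_cohort(cfg, cohort)
    state["labels"] = labels
    inc = labels.included
    state["X"] = cohort.features[inc]
    state["y"] = labels.label[inc].astype(int)
    state["C"] = ConfoundFrame(cohort.sex[inc], cohort.site[inc])
    pd.DataFrame(
        {
            "subject_id": [f"sub-{i:05d}" for i in range(cohort.n_subjects)],
            "severity": labels.severity,
            "label": labels.label,
            "included": labels.included,
        }
    ).to_csv(outdir / "labels.csv", index=False)

    plan = CVPlan(**{**cfg["cv"], "seed": int(cfg["seed"])})
    state["plan"] = plan
    idx = np.arange(state["y"].size)
    explore, holdout = split_explore_holdout(idx, state["y"], state["C"], plan)
    state["explore"], state["holdout"] = explore, holdout


def _stage_checks(cfg, state, outdir):
    spec = ModelSpec(family=cfg["model"]["families"][0], seed=int(cfg["seed"]))
    ex = state["explore"]
    table = run_same_analysis_checks(
        spec,
        state["X"][ex],
        state["y"][ex],
        state["C"].subset(ex),
        plan=CVPlan(**{**cfg["cv"], "seed": int(cfg["seed"])}),
        correction=cfg["correction"],
        n_perm=int(cfg["n_perm"]),
        seed=int(cfg["seed"]),
    )
    state["checks"] = table
    table.to_csv(outdir / "checks.tsv", sep="\t")


def _stage_explore(cfg, state, outdir):
    ex = state["explore"]
    rows = []
    best = None
    for family in cfg["model"]["families"]:
        grid = cfg["model"].get("grids", {}).get(family)
        spec = ModelSpec(family=family, hyper_grid=grid or [], seed=int(cfg["seed"]))
        res = nested_cv(
            spec, state["X"][ex], state["y"][ex], state["C"].subset(ex),
            state["plan"], cfg["correction"],
        )
        # the most frequently selected combination is carried to the holdout
        counts: dict = {}
        for p in res.chosen_params:
            counts[json.dumps(p, sort_keys=True)] = counts.get(json.dumps(p, sort_keys=True), 0) + 1
        modal = json.loads(max(counts, key=counts.get))
        rows.append(
            {
                "family": family,
                "mean_balanced_accuracy": res.mean_score,
                "sd_balanced_accuracy": res.sd_score,
                "mean_auc": float(np.mean(res.aucs)) if res.aucs is not None else np.nan,
                "modal_params": json.dumps(modal, sort_keys=True),
            }
        )
        if best is None or res.mean_score > best[1]:
            best = (family, res.mean_score, modal)
    state["best_family"], _, state["best_params"] = best
    grid_df = pd.DataFrame(rows)
    state["explore_grid"] = grid_df
    grid_df.to_csv(outdir / "explore_grid.tsv", sep="\t", index=False, float_format="%.6f")


def _stage_holdout(cfg, state, outdir):
    ex, ho = state["explore"], state["holdout"]
    X, y, C = state["X"], state["y"], state["C"]
    family, params = state["best_family"], state["best_params"]
    res, pipes = holdout_evaluate(
        family, params, X[ex], y[ex], C.subset(ex), X[ho], y[ho], C.subset(ho),
        n_seeds=int(cfg["n_holdout_seeds"]), correction=cfg["correction"],
        base_seed=int(cfg["seed"]), explore_indices=ex, holdout_indices=ho,
    )
    state["holdout_pipes"] = pipes

    def evaluate(y_tr):
        pipe = fit_pipeline(family, params, X[ex], y_tr, C.subset(ex),
                            cfg["correction"], seed=int(cfg["seed"]))
        return balanced_accuracy(y[ho], pipe.predict(X[ho], C.subset(ho)))

    _, p, null = permutation_test(evaluate, y[ex], n_perm=int(cfg["n_perm"]),
                                  seed=int(cfg["seed"]))
    res.null_scores = null
    res.p_raw = p
    res.p_bonferroni = float(bonferroni_adjust([p], m=int(cfg.get("bonferroni_m", 1)))[0])
    state["holdout_result"] = res
    payload = res.to_dict()
    payload["null_scores_summary"] = {
        "mean": float(null.mean()), "sd": float(null.std()), "n_perm": int(cfg["n_perm"]),
    }
    (outdir / "holdout_result.json").write_text(json.dumps(payload, indent=2))


def _stage_attribute(cfg, state, outdir):
    at = cfg["attribution"]
    n_bg = int(at.get("n_background", 100))
    n_targets = at.get("n_targets")
    n_orderings = int(at.get("n_orderings", 1))
    ex, ho = state["explore"], state["holdout"]
    X, y, C = state["X"], state["y"], state["C"]
    rng = np.random.default_rng(int(cfg["seed"]))
    runs = []
    pipes = state["holdout_pipes"]
    for r, pipe in enumerate(pipes):
        Z_bg_full = pipe.transform(X[ex], C.subset(ex))
        bg = Z_bg_full[rng.choice(Z_bg_full.shape[0], min(n_bg, Z_bg_full.shape[0]), replace=False)]
        Z_ho = pipe.transform(X[ho], C.subset(ho))
        if n_targets is not None and int(n_targets) < Z_ho.shape[0]:
            sel = rng.choice(Z_ho.shape[0], int(n_targets), replace=False)
            Z_t = Z_ho[sel]
        else:
            Z_t = Z_ho
        runs.append(attribute(pipe.model, bg, Z_t, seed=int(cfg["seed"]) + r,
                              n_orderings=n_orderings))
    summary = summarize_importance(runs)
    if summary.stable_set.size:
        preds = pipes[0].predict(X[ho], C.subset(ho))
        try:
            summary.direction = effect_direction(
                pipes[0].transform(X[ho], C.subset(ho)), preds, summary.stable_set
            )
        except ValueError as exc:
            warnings.warn(f"direction skipped: {exc}", stacklevel=2)
    state["importance"] = summary
    names = state["cohort"].feature_names
    kept = pipes[0].standardizer.kept_columns
    summary.to_frame([names[j] for j in kept]).to_csv(
        outdir / "importance.tsv", sep="\t", index=False, float_format="%.6g"
    )


def run_loso(cfg_or_path, seed=None, out=None, correction=None) -> dict:
    """Leave-one-site-out experiment on the configured cohort."""
    cfg = (
        ExperimentConfig.from_yaml(cfg_or_path)
        if isinstance(cfg_or_path, (str, Path))
        else ExperimentConfig.validate(dict(cfg_or_path))
    )
    if seed is not None:
        cfg["seed"] = int(seed)
    if correction is not None:
        cfg["correction"] = correction
    state: dict = {}
    outdir = Path(out if out is not None else cfg.get("out_dir", "confoundcv_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    _stage_simulate(cfg, state, outdir)
    _stage_label(cfg, state, outdir)
    spec = ModelSpec(family=cfg["model"]["families"][0], seed=int(cfg["seed"]))
    holdout_site = cfg.get("loso_holdout_site", state["C"].site_categories[0])
    res = leave_one_site_out(spec, state["X"], state["y"], state["C"],
                             holdout_site, cfg["correction"])
    payload = res.to_dict()
    (outdir / "loso_result.json").write_text(json.dumps(payload, indent=2))
    return payload


def _write_metadata(cfg, state, outdir):
    import sklearn

    meta = {
        "confoundcv_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "sklearn": sklearn.__version__,
        "config": {k: v for k, v in cfg.items()},
        "seed": int(cfg["seed"]),
        "n_outliers_excluded": state.get("n_outliers"),
        "excluded_moderate": getattr(state.get("labels"), "excluded_count", None),
        "best_family": state.get("best_family"),
        "best_params": state.get("best_params"),
        "design_decisions": DESIGN_DECISIONS,
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "label": _stage_label,
    "checks": _stage_checks,
    "explore": _stage_explore,
    "holdout": _stage_holdout,
    "attribute": _stage_attribute,
}
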