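"""Two-stage evaluation: nested CV, holdout generalization, significance.

The design separates an *exploration* set (80%) from a *holdout* set (20%).
All model selection — hyperparameters via nested 7-outer / 5-inner
cross-validation, and any comparison across families or phenotypes — happens
on the exploration set.  The generalization test then retrains the selected
configuration on the full exploration set seven times with different random
seeds and scores each refit once on the untouched holdout, giving a mean and
spread that the holdout never influenced.

Significance comes from a permutation test that reruns the entire pipeline
with shuffled TRAINING labels while the test labels stay fixed; the add-one
estimator p = (1 + #{null >= observed}) / (n_perm + 1) never returns zero.
Label-independent stages (confound regression, standardization when no
resampling is active) are prepared once per fold — permuting y cannot change
them — while every label-dependent stage (counterbalancing, the model fit)
is redone per permutation.

A leave-one-site-out mode replaces the random outer folds with one fold per
recruitment site, probing geographic generalization; site obviously cannot
be counterbalanced there, so only sex is.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .confounds import (
    ConfoundFrame,
    RegressionParams,
    ResamplePlan,
    apply_confound_regressor,
    counterbalance,
    fit_confound_regressor,
)
from .metrics import auc_roc, balanced_accuracy
from .models import ModelSpec, decision_scores, make_estimator
from .preprocessing import Standardizer, apply_standardizer, fit_standardizer

__all__ = [
    "CVPlan",
    "EvalResult",
    "FittedPipeline",
    "fit_pipeline",
    "split_explore_holdout",
    "nested_cv",
    "holdout_evaluate",
    "permutation_test",
    "bonferroni_adjust",
    "leave_one_site_out",
]

CORRECTION_MODES = ("none", "regression", "under", "over")


@dataclass
class CVPlan:
    outer_folds: int = 7
    inner_folds: int = 5
    holdout_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")


@dataclass
class EvalResult:
    """Per-fold or per-seed scores plus permutation significance."""

    scores: np.ndarray
    aucs: np.ndarray | None = None
    chosen_params: list = field(default_factory=list)
    null_scores: np.ndarray | None = None
    p_raw: float | None = None
    p_bonferroni: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd_score(self) -> float:
        return float(np.std(self.scores))

    def to_dict(self) -> dict:
        return {
            "scores": np.asarray(self.scores).tolist(),
            "mean_score": self.mean_score,
            "sd_score": self.sd_score,
            "aucs": None if self.aucs is None else np.asarray(self.aucs).tolist(),
            "chosen_params": self.chosen_params,
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
            "metadata": self.metadata,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


@dataclass
class FittedPipeline:
    """One trained correction + preprocessing + classifier chain.

    Every fitted parameter is a pure function of the training rows given to
    :func:`fit_pipeline`; applying the pipeline to new rows reuses them
    unchanged.
    """

    family: str
    params: dict
    correction: str
    model: object
    standardizer: Standardizer
    regression: RegressionParams | None = None
    resample_plan: ResamplePlan | None = None
    seed: int = 0

    def transform(self, X: np.ndarray, C: ConfoundFrame | None) -> np.ndarray:
        if self.regression is not None:
            X = apply_confound_regressor(self.regression, X, C)
        return apply_standardizer(self.standardizer, X)

    def predict(self, X: np.ndarray, C: ConfoundFrame | None = None) -> np.ndarray:
        return self.model.predict(self.transform(X, C))

    def scores(self, X: np.ndarray, C: ConfoundFrame | None = None) -> np.ndarray:
        return decision_scores(self.model, self.transform(X, C))


def fit_pipeline(
    family: str,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    C: ConfoundFrame | None,
    correction: str = "none",
    seed: int = 0,
    strata_by: str = "joint",
) -> FittedPipeline:
    """Fit correction -> standardization -> classifier on training rows only.

    Counterbalancing (if active) resamples the rows first; standardization is
    fitted on the resampled set, since that is the data the model sees.
    Confound regression and counterbalancing are alternative modes, never
    combined.
    """
    if correction not in CORRECTION_MODES:
        raise ValueError(f"correction must be one of {CORRECTION_MODES}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    plan = None
    regression = None
    if correction in ("under", "over"):
        plan = counterbalance(y, C, mode=correction, seed=seed, strata_by=strata_by)
        X, y, C = X[plan.indices], y[plan.indices], C.subset(plan.indices)
    elif correction == "regression":
        regression = fit_confound_regressor(X, C)
        X = apply_confound_regressor(regression, X, C)
    if np.unique(y).size < 2:
        raise ValueError("degenerate training labels after correction")
    std = fit_standardizer(X)
    Z = apply_standardizer(std, X)
    model = make_estimator(family, params, seed=seed, n_classes=int(np.unique(y).size))
    model.fit(Z, y)
    return FittedPipeline(
        family=family,
        params=dict(params),
        correction=correction,
        model=model,
        standardizer=std,
        regression=regression,
        resample_plan=plan,
        seed=seed,
    )


def split_explore_holdout(
    indices: np.ndarray,
    labels: np.ndarray,
    C: ConfoundFrame | None,
    plan: CVPlan,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive explore/holdout split of the given indices.

    Stratified on the joint (label, sex, site) cell when every cell has at
    least 2 members, else on the label alone.
    """
    indices = np.asarray(indices)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both label classes must be present for the split")
    strat = labels.astype(str)
    if C is not None:
        joint = np.char.add(np.char.add(strat, "|"), C.cells())
        _, counts = np.unique(joint, return_counts=True)
        if counts.min() >= 2:
            strat = joint
    explore, holdout = train_test_split(
        indices,
        test_size=plan.holdout_fraction,
        stratify=strat,
        random_state=plan.seed,
    )
    return np.sort(explore), np.sort(holdout)


def _select_best(grid: Sequence[dict], mean_scores: Sequence[float]) -> int:
    # strict > keeps the earliest grid entry on ties (documented tie-break)
    best, best_score = 0, -np.inf
    for j, s in enumerate(mean_scores):
        if s > best_score:
            best, best_score = j, s
    return best


def nested_cv(
    model_spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    C: ConfoundFrame | None,
    plan: CVPlan,
    correction: str = "none",
) -> EvalResult:
    """Nested cross-validation on the exploration set.

    Outer loop: ``plan.outer_folds`` stratified folds; inner loop: a
    ``plan.inner_folds``-fold grid search scored by balanced accuracy on the
    inner test folds.  The winning combination is refitted on the full outer
    training portion and scored once on the outer test fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    outer = StratifiedKFold(plan.outer_folds, shuffle=True, random_state=plan.seed)
    scores, aucs, chosen = [], [], []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        C_tr = C.subset(tr) if C is not None else None
        grid_scores = np.zeros(len(model_spec.hyper_grid))
        inner = StratifiedKFold(plan.inner_folds, shuffle=True, random_state=plan.seed + 1)
        inner_splits = list(inner.split(X[tr], y[tr]))
        for j, params in enumerate(model_spec.hyper_grid):
            accs = []
            for itr, ite in inner_splits:
                pipe = fit_pipeline(
                    model_spec.family,
                    params,
                    X[tr][itr],
                    y[tr][itr],
                    C_tr.subset(itr) if C_tr is not None else None,
                    correction,
                    seed=model_spec.seed,
                )
                C_ite = C_tr.subset(ite) if C_tr is not None else None
                accs.append(balanced_accuracy(y[tr][ite], pipe.predict(X[tr][ite], C_ite)))
            grid_scores[j] = np.mean(accs)
        best = _select_best(model_spec.hyper_grid, grid_scores)
        params = model_spec.hyper_grid[best]
        pipe = fit_pipeline(
            model_spec.family, params, X[tr], y[tr], C_tr, correction, seed=model_spec.seed
        )
        C_te = C.subset(te) if C is not None else None
        y_pred = pipe.predict(X[te], C_te)
        scores.append(balanced_accuracy(y[te], y_pred))
        if np.unique(y).size == 2:
            aucs.append(auc_roc(y[te], pipe.scores(X[te], C_te)))
        chosen.append(params)
    return EvalResult(
        scores=np.array(scores),
        aucs=np.array(aucs) if aucs else None,
        chosen_params=chosen,
        metadata={"correction": correction, "family": model_spec.family},
    )


def holdout_evaluate(
    family: str,
    params: dict,
    X_explore: np.ndarray,
    y_explore: np.ndarray,
    C_explore: ConfoundFrame | None,
    X_holdout: np.ndarray,
    y_holdout: np.ndarray,
    C_holdout: ConfoundFrame | None,
    n_seeds: int = 7,
    correction: str = "none",
    base_seed: int = 0,
    explore_indices: np.ndarray | None = None,
    holdout_indices: np.ndarray | None = None,
) -> tuple[EvalResult, list[FittedPipeline]]:
    """Generalization test: n_seeds refits on explore, scored on holdout.

    Hyperparameters are frozen from the exploration stage; only the model
    seed and the resampling seed vary across refits.  Returns the result and
    the fitted pipelines (reused for attribution).
    """
    if explore_indices is not None and holdout_indices is not None:
        if np.intersect1d(explore_indices, holdout_indices).size:
            raise ValueError("explore and holdout indices overlap")
    scores, aucs, pipes = [], [], []
    for s in range(n_seeds):
        pipe = fit_pipeline(
            family, params, X_explore, y_explore, C_explore, correction, seed=base_seed + s
        )
        y_pred = pipe.predict(X_holdout, C_holdout)
        scores.append(balanced_accuracy(y_holdout, y_pred))
        aucs.append(auc_roc(y_holdout, pipe.scores(X_holdout, C_holdout)))
        pipes.append(pipe)
    res = EvalResult(
        scores=np.array(scores),
        aucs=np.array(aucs),
        chosen_params=[params] * n_seeds,
        metadata={"correction": correction, "family": family, "n_seeds": n_seeds},
    )
    return res, pipes


def permutation_test(
    evaluate: Callable[[np.ndarray], float],
    y_train: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Train-label-shuffling permutation test for a pipeline score.

    ``evaluate`` must rerun every label-dependent stage of the pipeline
    (resampling, refit) for the training labels it is given and return the
    test score; test labels stay fixed inside it.  Returns
    ``(observed, p_value, null_scores)`` with the add-one estimator
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y_train = np.asarray(y_train)
    observed = float(evaluate(y_train))
    null = np.empty(n_perm)
    for r in range(n_perm):
        null[r] = evaluate(rng.permutation(y_train))
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return observed, float(p), null


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """p * m capped at 1; m defaults to the number of simultaneous analyses."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    return np.minimum(p * m, 1.0)


def leave_one_site_out(
    model_spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    C: ConfoundFrame,
    holdout_site,
    correction: str = "none",
) -> EvalResult:
    """Site-wise generalization: one recruitment site per outer fold.

    The designated site is the holdout; every remaining site serves once as
    the test fold while the others train.  Site cannot be counterbalanced in
    this design (each fold is a single site), so counterbalancing modes
    stratify on sex alone — recorded in the result metadata.  Hyperparameters
    come from ``model_spec.hyper_grid[0]`` unless a grid search result is
    supplied upstream.
    """
    sites = list(C.site_categories)
    if len(sites) < 3:
        raise ValueError("need at least 3 sites for leave-one-site-out")
    if holdout_site not in sites:
        raise ValueError(f"holdout site {holdout_site!r} not present")
    strata_by = "sex" if correction in ("under", "over") else "joint"
    params = model_spec.hyper_grid[0]
    fold_sites = [s for s in sites if s != holdout_site]
    scores, aucs = [], []
    for test_site in fold_sites:
        tr = np.nonzero((C.site != test_site) & (C.site != holdout_site))[0]
        te = np.nonzero(C.site == test_site)[0]
        pipe = fit_pipeline(
            model_spec.family, params, X[tr], y[tr], C.subset(tr), correction,
            seed=model_spec.seed, strata_by=strata_by,
        )
        y_pred = pipe.predict(X[te], C.subset(te))
        scores.append(balanced_accuracy(y[te], y_pred))
        if np.unique(y[te]).size == 2:
            aucs.append(auc_roc(y[te], pipe.scores(X[te], C.subset(te))))
        else:  # a single-class site fold has no ROC
            warnings.warn(f"site {test_site!r}: single-class test fold, AUC skipped", stacklevel=2)
            aucs.append(np.nan)
    # final generalization: train on all non-holdout sites, test on the holdout site
    tr = np.nonzero(C.site != holdout_site)[0]
    te = np.nonzero(C.site == holdout_site)[0]
    pipe = fit_pipeline(
        model_spec.family, params, X[tr], y[tr], C.subset(tr), correction,
        seed=model_spec.seed, strata_by=strata_by,
    )
    holdout_score = balanced_accuracy(y[te], pipe.predict(X[te], C.subset(te)))
    return EvalResult(
        scores=np.array(scores),
        aucs=np.array(aucs),
        chosen_params=[params] * len(fold_sites),
        metadata={
            "fold_sites": [str(s) for s in fold_sites],
            "holdout_site": str(holdout_site),
            "holdout_score": holdout_score,
            "correction": correction,
            "counterbalance_strata": strata_by,
            "note": "site is the CV unit and cannot be counterbalanced; sex only",
        },
    )
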