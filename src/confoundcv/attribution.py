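"""Permutation-based Shapley attribution and stable-feature selection.

Feature importance is measured with interventional Shapley values: the
contribution of feature ``f`` to a prediction is its average marginal effect
over random feature orderings, with absent features replaced by values from
a background sample.  The permutation estimator walks each sampled ordering
forward and backward (an antithetic pair), flipping one feature at a time
from background to target and recording the change in the model's expected
output.  Each pass telescopes, so additivity —

    base_value + sum_f S[s, f] == f(x_s)

— holds exactly for every subject, not just in expectation.  Attributions
are computed on the model's continuous decision scale (margin / log-odds),
where additivity is meaningful.

Importance per feature is the mean absolute attribution over the scored
subjects, S̄_f = (1/N) Σ_s |S[s, f]|.  A feature is *stable* when S̄_f is at
least twice the grand mean S̄ (the average of S̄_f over all features) in at
least six of seven repeated runs — for k runs, in at least ceil(6k/7).
Correlated features can split credit between them, so the stable set is a
conservative, consistency-filtered selection rather than a complete one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import decision_scores

__all__ = [
    "AttributionMatrix",
    "ImportanceSummary",
    "attribute",
    "summarize_importance",
    "effect_direction",
]


@dataclass
class AttributionMatrix:
    """Per-subject, per-feature Shapley values for one model run."""

    values: np.ndarray  # subjects x features
    base_value: float
    run_seed: int

    def check_additivity(self, predictions: np.ndarray, tol: float = 1e-2) -> None:
        """Assert base + row-sum equals the model output for every subject."""
        recon = self.base_value + self.values.sum(axis=1)
        err = np.max(np.abs(recon - predictions))
        if err > tol:
            raise AssertionError(f"additivity violated: max error {err:.3g} > {tol}")


def attribute(
    model,
    background: np.ndarray,
    targets: np.ndarray,
    seed: int = 0,
    n_orderings: int = 1,
) -> AttributionMatrix:
    """Permutation-estimated Shapley values of ``model`` on ``targets``.

    ``model`` is either a fitted classifier (scored on its decision scale)
    or a callable ``f(X) -> scores``.  ``n_orderings`` counts antithetic
    forward/backward pairs per subject; estimator variance shrinks with more
    orderings while additivity is exact at any budget.  Deterministic given
    ``seed``.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("empty background set")
    if background.shape[1] != targets.shape[1]:
        raise ValueError("background and targets must share the feature space")
    if n_orderings < 1:
        raise ValueError("n_orderings must be >= 1")
    predict = model if callable(model) else (lambda A: decision_scores(model, A))

    n_bg, d = background.shape
    n_targets = targets.shape[0]
    rng = np.random.default_rng(seed)
    base_value = float(np.mean(predict(background)))
    values = np.zeros((n_targets, d))

    for s in range(n_targets):
        x = targets[s]
        phi = np.zeros(d)
        for _ in range(n_orderings):
            perm = rng.permutation(d)
            for order in (perm, perm[::-1]):
                # one pass: cumulative replacement background -> target,
                # all d stages stacked into a single model call
                cur = background.copy()
                stack = np.empty((d, n_bg, d))
                for j, f in enumerate(order):
                    cur[:, f] = x[f]
                    stack[j] = cur
                vals = predict(stack.reshape(d * n_bg, d)).reshape(d, n_bg).mean(axis=1)
                expectations = np.concatenate(([base_value], vals))
                phi[order] += np.diff(expectations)
        values[s] = phi / (2 * n_orderings)
    return AttributionMatrix(values=values, base_value=base_value, run_seed=seed)


@dataclass
class ImportanceSummary:
    """Across-run importance statistics and the stable-feature set."""

    per_feature_mean_abs: np.ndarray  # S̄_f averaged over runs
    grand_mean: float  # S̄ of the averaged S̄_f
    per_run_mean_abs: np.ndarray  # runs x features
    qualifying_runs: np.ndarray  # per feature: #runs with S̄_f >= 2 S̄
    required_runs: int
    stable_set: np.ndarray  # sorted feature indices
    direction: dict = field(default_factory=dict)

    def to_frame(self, feature_names=None) -> pd.DataFrame:
        k, p = self.per_run_mean_abs.shape
        names = feature_names if feature_names is not None else [f"f{j}" for j in range(p)]
        df = pd.DataFrame({"feature": names})
        for r in range(k):
            df[f"mean_abs_shap_run{r}"] = self.per_run_mean_abs[r]
        df["mean_abs_shap"] = self.per_feature_mean_abs
        df["qualifying_runs"] = self.qualifying_runs
        df["stable"] = np.isin(np.arange(p), self.stable_set)
        df["direction"] = [self.direction.get(j, "") for j in range(p)]
        return df


def summarize_importance(runs: list[AttributionMatrix]) -> ImportanceSummary:
    """The 2x-grand-mean / 6-of-7-runs stability rule over repeated runs.

    Per run, S̄_f is the mean |attribution| per feature and S̄ its average
    over features; a feature qualifies in that run iff S̄_f >= 2 S̄
    (inclusive).  Stability requires qualification in ceil(6k/7) of k runs.
    """
    if not runs:
        raise ValueError("need at least one attribution run")
    p = runs[0].values.shape[1]
    if any(r.values.shape[1] != p for r in runs):
        raise ValueError("runs have inconsistent feature counts")
    per_run = np.stack([np.mean(np.abs(r.values), axis=0) for r in runs])  # k x p
    grand_per_run = per_run.mean(axis=1, keepdims=True)  # S̄ per run
    qualify = per_run >= 2.0 * grand_per_run
    k = len(runs)
    required = math.ceil(6 * k / 7)
    counts = qualify.sum(axis=0)
    stable = np.nonzero(counts >= required)[0]
    mean_abs = per_run.mean(axis=0)
    return ImportanceSummary(
        per_feature_mean_abs=mean_abs,
        grand_mean=float(mean_abs.mean()),
        per_run_mean_abs=per_run,
        qualifying_runs=counts,
        required_runs=required,
        stable_set=stable,
    )


def effect_direction(
    X_holdout: np.ndarray,
    predictions: np.ndarray,
    stable_set: np.ndarray,
    positive_class=1,
) -> dict[int, str]:
    """Higher- vs lower-than-average feature values among predicted cases.

    For each stable feature: "higher" if its mean among predicted-positive
    subjects exceeds its overall holdout mean, else "lower".  If every
    subject is predicted positive the two means coincide and the comparison
    is undefined (flagged, with a warning).
    """
    X = np.asarray(X_holdout, dtype=float)
    predictions = np.asarray(predictions)
    stable_set = np.asarray(stable_set, dtype=int)
    if stable_set.size == 0:
        raise ValueError("stable_set is empty")
    pos = predictions == positive_class
    if not pos.any():
        raise ValueError("no predicted-positive subjects")
    out: dict[int, str] = {}
    if pos.all():
        warnings.warn(
            "all subjects predicted positive: direction comparison is degenerate",
            stacklevel=2,
        )
        return {int(f): "undefined" for f in stable_set}
    overall = X.mean(axis=0)
    pos_mean = X[pos].mean(axis=0)
    for f in stable_set:
        out[int(f)] = "higher" if pos_mean[f] > overall[f] else "lower"
    return out
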