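"""Same-analysis diagnostic battery for residual confounding.

Five input-output combinations are evaluated with the SAME cross-validation
folds and the SAME classifier family as the main analysis:

====================  =========================================================
``X->y``              the main analysis (features to labels)
``X->c_sex``          is sex still recoverable from the (corrected) features?
``X->c_site``         is site still recoverable from the (corrected) features?
``c_sex->y``          does sex alone still predict the label?
``c_site->y``         does site alone still predict the label?
====================  =========================================================

After a *successful* confound regression the ``X->c`` rows should fall to
chance (the confound signal was removed from X); after *successful*
counterbalancing the ``c->y`` rows should fall to chance (the confound-label
association was removed).  Each row carries a permutation p-value obtained by
shuffling that row's training targets and rerunning the pipeline.

Confounds used as classifier inputs are fed as a full one-hot indicator set
(no category dropped — classifiers have no collinearity problem and should
see every indicator); confounds used as targets are scored with multiclass
balanced accuracy, whose chance level is 1/#classes.

Confound regression never depends on the row's target, so residualized and
standardized inputs are prepared once per fold; counterbalancing depends on
the main-analysis label y, so it is redone per permutation exactly when the
row's target IS y.  For RBF-SVM rows with fixed inputs, the kernel matrix is
precomputed once per fold and reused across all permutation refits; the
fitted models are identical to plain SVC fits.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .confounds import ConfoundFrame, counterbalance, fit_confound_regressor, apply_confound_regressor
from .cv import CVPlan
from .metrics import balanced_accuracy
from .models import ModelSpec, make_estimator
from .preprocessing import apply_standardizer, fit_standardizer

__all__ = ["CHECK_ROWS", "run_same_analysis_checks", "plot_check_table"]

CHECK_ROWS = ("X->y", "X->c_sex", "X->c_site", "c_sex->y", "c_site->y")


def _full_onehot(vec: np.ndarray, categories: Sequence) -> np.ndarray:
    return np.column_stack([(vec == c).astype(float) for c in categories])


def _resolve_gamma(params: dict, Z: np.ndarray) -> float:
    g = params.get("gamma", "scale")
    if g == "scale":
        v = Z.var()
        return 1.0 / (Z.shape[1] * v) if v > 0 else 1.0 / Z.shape[1]
    return float(g)


def _fixed_input_eval(Z_tr, Z_te, t_te, family, params, seed, n_classes):
    """Closure fitting only the classifier; inputs are frozen per fold."""
    if family == "rbf-svm":
        gamma = _resolve_gamma(params, Z_tr)
        K_tr = rbf_kernel(Z_tr, Z_tr, gamma=gamma)
        K_te = rbf_kernel(Z_te, Z_tr, gamma=gamma)
        C_val = params.get("C", 1.0)

        def ev(t_tr):
            base = SVC(kernel="precomputed", C=C_val, random_state=seed)
            est = OneVsRestClassifier(base) if n_classes > 2 else base
            est.fit(K_tr, t_tr)
            return balanced_accuracy(t_te, est.predict(K_te))

        return ev

    def ev(t_tr):
        est = make_estimator(family, params, seed=seed, n_classes=n_classes)
        est.fit(Z_tr, t_tr)
        return balanced_accuracy(t_te, est.predict(Z_te))

    return ev


def _make_fold_eval(
    row: str,
    X: np.ndarray,
    y: np.ndarray,
    C: ConfoundFrame,
    tr: np.ndarray,
    te: np.ndarray,
    t_all: np.ndarray,
    correction: str,
    family: str,
    params: dict,
    seed: int,
    n_classes: int,
):
    """Build ``evaluate(t_train) -> score`` for one fold of one check row."""
    input_is_X = row.startswith("X")
    target_is_y = row.endswith("y")
    t_te = t_all[te]
    C_tr = C.subset(tr)

    if input_is_X:
        X_tr, X_te = X[tr], X[te]
        if correction == "regression":
            reg = fit_confound_regressor(X_tr, C_tr)
            X_tr = apply_confound_regressor(reg, X_tr, C_tr)
            X_te = apply_confound_regressor(reg, X[te], C.subset(te))
        if correction in ("under", "over") and target_is_y:
            # the resample plan depends on the permuted target: rebuild per call
            def ev(t_tr):
                plan = counterbalance(t_tr, C_tr, mode=correction, seed=seed)
                idx = plan.indices
                std = fit_standardizer(X_tr[idx])
                est = make_estimator(family, params, seed=seed, n_classes=n_classes)
                est.fit(apply_standardizer(std, X_tr[idx]), t_tr[idx])
                return balanced_accuracy(t_te, est.predict(apply_standardizer(std, X_te)))

            return ev
        if correction in ("under", "over"):
            # plan depends on y, which permuting this row's target never changes
            plan = counterbalance(y[tr], C_tr, mode=correction, seed=seed)
            idx = plan.indices
            std = fit_standardizer(X_tr[idx])
            Z_tr = apply_standardizer(std, X_tr[idx])
            Z_te = apply_standardizer(std, X_te)
            inner = _fixed_input_eval(Z_tr, Z_te, t_te, family, params, seed, n_classes)
            return lambda t_tr: inner(t_tr[idx])
        std = fit_standardizer(X_tr)
        Z_tr = apply_standardizer(std, X_tr)
        Z_te = apply_standardizer(std, X_te)
        return _fixed_input_eval(Z_tr, Z_te, t_te, family, params, seed, n_classes)

    # confound-as-input rows: full one-hot indicators, unstandardized
    cats = C.sex_categories if "sex" in row else C.site_categories
    vec = C.sex if "sex" in row else C.site
    I_all = _full_onehot(vec, cats)
    I_tr, I_te = I_all[tr], I_all[te]
    if correction in ("under", "over"):
        # target is y here; label-side resampling is redone per permutation
        def ev(t_tr):
            plan = counterbalance(t_tr, C_tr, mode=correction, seed=seed)
            idx = plan.indices
            est = make_estimator(family, params, seed=seed, n_classes=n_classes)
            est.fit(I_tr[idx], t_tr[idx])
            return balanced_accuracy(t_te, est.predict(I_te))

        return ev
    return _fixed_input_eval(I_tr, I_te, t_te, family, params, seed, n_classes)


def run_same_analysis_checks(
    model_spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    C: ConfoundFrame,
    plan: CVPlan | None = None,
    correction: str = "none",
    n_perm: int = 199,
    seed: int = 0,
    params: dict | None = None,
    rows: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run the five-combination battery under one correction technique.

    All rows share the fold partition (stratified on y), so differences
    between rows reflect the input/target swap, not partition noise.  The
    classifier uses one fixed hyperparameter combination — pass the one the
    main analysis selected via ``params`` (default: first grid entry).

    Returns a table with one row per combination: mean and SD of balanced
    accuracy over folds, chance level, permutation p-value, and significance
    flags at 0.05 and 0.01.  ``rows`` restricts the battery to a subset of
    combinations; ``n_perm=0`` skips the permutation test (p is NaN).
    """
    plan = plan or CVPlan()
    params = dict(params or model_spec.hyper_grid[0])
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = list(
        StratifiedKFold(plan.outer_folds, shuffle=True, random_state=plan.seed).split(X, y)
    )
    targets = {"y": y, "c_sex": C.sex, "c_site": C.site}
    if rows is None:
        rows = CHECK_ROWS
    else:
        unknown = set(rows) - set(CHECK_ROWS)
        if unknown:
            raise ValueError(f"unknown check rows {unknown}")
    records = []
    for row in rows:
        t_all = targets[row.split("->")[1]]
        n_classes = int(np.unique(t_all).size)
        evals = []
        for k, (tr, te) in enumerate(folds):
            if np.unique(t_all[tr]).size < n_classes or np.unique(t_all[te]).size < n_classes:
                warnings.warn(f"{row}: fold {k} lacks a target class, skipped", stacklevel=2)
                continue
            ev = _make_fold_eval(
                row, X, y, C, tr, te, t_all, correction, model_spec.family, params,
                model_spec.seed, n_classes,
            )
            evals.append((ev, t_all[tr]))
        if not evals:
            raise ValueError(f"{row}: every fold lacked a target class")

        fold_scores = np.array([ev(t_tr) for ev, t_tr in evals])
        observed = float(fold_scores.mean())
        if n_perm > 0:
            rng = np.random.default_rng(seed)
            null = np.empty(n_perm)
            for r in range(n_perm):
                null[r] = np.mean([ev(rng.permutation(t_tr)) for ev, t_tr in evals])
            p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
        else:
            p = np.nan
        records.append(
            {
                "combination": row,
                "target_classes": n_classes,
                "chance": 1.0 / n_classes,
                "mean_balanced_accuracy": observed,
                "sd_balanced_accuracy": float(fold_scores.std()),
                "n_folds_used": len(evals),
                "p_perm": float(p),
                "significant_05": bool(p < 0.05),
                "significant_01": bool(p < 0.01),
            }
        )
    out = pd.DataFrame(records).set_index("combination")
    out.attrs["correction"] = correction
    out.attrs["n_perm"] = n_perm
    return out


def plot_check_table(table: pd.DataFrame, path=None):
    """Grouped bar chart of the five combinations with significance stars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    xs = np.arange(len(table))
    acc = table["mean_balanced_accuracy"]
    err = table["sd_balanced_accuracy"]
    ax.bar(xs, acc, yerr=err, color="steelblue", alpha=0.85)
    for x, (_, r) in zip(xs, table.iterrows()):
        star = "**" if r["significant_01"] else ("*" if r["significant_05"] else "n.s.")
        ax.text(x, r["mean_balanced_accuracy"] + r["sd_balanced_accuracy"] + 0.02, star,
                ha="center", fontsize=10)
        ax.hlines(r["chance"], x - 0.4, x + 0.4, color="k", ls=":", lw=1)
    ax.set_xticks(xs)
    ax.set_xticklabels(table.index, rotation=20)
    ax.set_ylabel("balanced accuracy")
    ax.set_ylim(0, 1.05)
    ax.set_title(f"confound checks ({table.attrs.get('correction', '?')})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
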