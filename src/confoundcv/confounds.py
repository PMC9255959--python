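"""Confound-correction techniques: regression and counterbalancing.

A confound ``c`` (here: sex and recruitment site, both categorical) opens a
spurious prediction pathway ``X <- c -> y``.  Two families of corrections are
implemented, both fitted on training rows only:

* **Confound regression** — per-feature OLS of X on one-hot confound main
  effects; the residuals are carried forward.  Removes every per-category
  mean shift but, being a linear main-effects model, cannot remove per-site
  variance differences or sex-by-site interaction means.
* **Counterbalancing** — resampling the training rows so the confound's
  distribution is identical across label classes.  Within every joint
  (sex, site) stratum the two classes are equalized, either down to the
  stratum minimum (undersampling, rows dropped) or up to the stratum maximum
  by sampling the minority with replacement (oversampling).  The resampled
  contingency of cell-by-label is exactly independent, so its chi-square
  statistic is identically zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfoundFrame",
    "RegressionParams",
    "ResamplePlan",
    "fit_confound_regressor",
    "apply_confound_regressor",
    "counterbalance",
]


class UnseenCategoryError(ValueError):
    """A confound category at apply time was absent at fit time."""


@dataclass
class ConfoundFrame:
    """Aligned categorical confound vectors with fixed category sets."""

    sex: np.ndarray
    site: np.ndarray
    sex_categories: tuple = ()
    site_categories: tuple = ()

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex)
        self.site = np.asarray(self.site)
        if self.sex.shape != self.site.shape:
            raise ValueError("sex and site must be aligned")
        if not self.sex_categories:
            self.sex_categories = tuple(np.unique(self.sex))
        if not self.site_categories:
            self.site_categories = tuple(np.unique(self.site))

    def __len__(self) -> int:
        return self.sex.size

    def subset(self, idx: np.ndarray) -> "ConfoundFrame":
        """Row subset; the category sets are inherited, not re-derived."""
        return ConfoundFrame(
            self.sex[idx], self.site[idx], self.sex_categories, self.site_categories
        )

    def _check_categories(self) -> None:
        bad_sex = set(np.unique(self.sex)) - set(self.sex_categories)
        bad_site = set(np.unique(self.site)) - set(self.site_categories)
        if bad_sex or bad_site:
            raise UnseenCategoryError(f"unseen categories: sex={bad_sex}, site={bad_site}")

    def cells(self) -> np.ndarray:
        """Joint (sex, site) cell id per row, as strings."""
        return np.char.add(np.char.add(self.sex.astype(str), "|"), self.site.astype(str))

    def design_matrix(self, drop_first: bool = True, intercept: bool = True) -> np.ndarray:
        """One-hot design. Drop-first + intercept for OLS; full one-hot when the
        confounds serve as classifier inputs."""
        self._check_categories()
        cols = []
        if intercept:
            cols.append(np.ones(len(self)))
        for cats, vec in ((self.sex_categories, self.sex), (self.site_categories, self.site)):
            start = 1 if drop_first else 0
            for cat in cats[start:]:
                cols.append((vec == cat).astype(float))
        return np.column_stack(cols)


@dataclass
class RegressionParams:
    """Per-feature OLS coefficients on the one-hot confound design."""

    coefficients: np.ndarray  # design-columns x features
    kept_design_columns: np.ndarray
    sex_categories: tuple
    site_categories: tuple


def fit_confound_regressor(X_train: np.ndarray, C_train: ConfoundFrame) -> RegressionParams:
    """OLS of each feature on [intercept | sex dummies | site dummies].

    Fitted on training rows only.  Confound categories with no training rows
    make the design rank-deficient; their columns are dropped with a warning.
    """
    X = np.asarray(X_train, dtype=float)
    if len(C_train) != X.shape[0]:
        raise ValueError("X_train and C_train must be aligned")
    if np.unique(C_train.cells()).size < 2:
        raise ValueError("need at least 2 distinct confound cells in the training data")
    D = C_train.design_matrix(drop_first=True, intercept=True)
    occupied = (D != 0).any(axis=0)
    if not occupied.all():
        warnings.warn(
            f"dropping {int((~occupied).sum())} empty confound design column(s)", stacklevel=2
        )
    kept = np.nonzero(occupied)[0]
    coef, *_ = np.linalg.lstsq(D[:, kept], X, rcond=None)
    return RegressionParams(
        coefficients=coef,
        kept_design_columns=kept,
        sex_categories=C_train.sex_categories,
        site_categories=C_train.site_categories,
    )


def apply_confound_regressor(p: RegressionParams, X: np.ndarray, C: ConfoundFrame) -> np.ndarray:
    """Residualize X with the train-fitted coefficients (test rows included)."""
    X = np.asarray(X, dtype=float)
    C = ConfoundFrame(C.sex, C.site, p.sex_categories, p.site_categories)
    D = C.design_matrix(drop_first=True, intercept=True)[:, p.kept_design_columns]
    return X - D @ p.coefficients


@dataclass
class ResamplePlan:
    """Training-row index multiset produced by counterbalancing."""

    mode: str  # "under" | "over"
    indices: np.ndarray
    seed: int
    strata_before: dict = field(default_factory=dict)
    strata_after: dict = field(default_factory=dict)
    dropped_strata: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "seed": self.seed,
                "strata_before": {str(k): v for k, v in self.strata_before.items()},
                "strata_after": {str(k): v for k, v in self.strata_after.items()},
                "dropped_strata": [str(s) for s in self.dropped_strata],
                "indices": self.indices.tolist(),
            }
        )


def counterbalance(
    labels: np.ndarray,
    C: ConfoundFrame,
    mode: str,
    seed: int = 0,
    strata_by: str = "joint",
) -> ResamplePlan:
    """Equalize label classes within every confound stratum of the TRAIN set.

    ``strata_by`` is "joint" (sex x site cells, the default), "sex" or "site"
    — the marginal options exist for designs where one confound is the CV
    unit itself (e.g. leave-one-site-out, where site cannot be balanced).

    Undersampling keeps a duplicate-free subset; oversampling keeps every
    original row of each stratum and adds minority-class rows sampled with
    replacement.  Strata where either class is absent are dropped entirely,
    with a warning.  A stratum already balanced contributes each of its rows
    exactly once in either mode.
    """
    labels = np.asarray(labels)
    if mode not in ("under", "over"):
        raise ValueError(f"mode must be 'under' or 'over', got {mode!r}")
    if len(C) != labels.size:
        raise ValueError("labels and confounds must be aligned")
    if strata_by == "joint":
        cells = C.cells()
    elif strata_by == "sex":
        cells = C.sex.astype(str)
    elif strata_by == "site":
        cells = C.site.astype(str)
    else:
        raise ValueError(f"unknown strata_by {strata_by!r}")

    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"counterbalancing expects binary labels, got {classes}")

    chosen: list[np.ndarray] = []
    before: dict = {}
    after: dict = {}
    dropped: list = []
    for cell in np.unique(cells):
        in_cell = cells == cell
        idx0 = np.nonzero(in_cell & (labels == classes[0]))[0]
        idx1 = np.nonzero(in_cell & (labels == classes[1]))[0]
        before[cell] = {str(classes[0]): len(idx0), str(classes[1]): len(idx1)}
        if len(idx0) == 0 or len(idx1) == 0:
            dropped.append(cell)
            continue
        if mode == "under":
            target = min(len(idx0), len(idx1))
            sel0 = idx0 if len(idx0) == target else rng.choice(idx0, target, replace=False)
            sel1 = idx1 if len(idx1) == target else rng.choice(idx1, target, replace=False)
        else:
            target = max(len(idx0), len(idx1))
            sel0 = idx0 if len(idx0) == target else np.concatenate(
                [idx0, rng.choice(idx0, target - len(idx0), replace=True)]
            )
            sel1 = idx1 if len(idx1) == target else np.concatenate(
                [idx1, rng.choice(idx1, target - len(idx1), replace=True)]
            )
        chosen.extend([sel0, sel1])
        after[cell] = {str(classes[0]): len(sel0), str(classes[1]): len(sel1)}

    if not chosen:
        raise ValueError("no stratum contains both label classes")
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} stratum/strata lacking one label class: {dropped}",
            stacklevel=2,
        )
    indices = np.sort(np.concatenate(chosen))
    return ResamplePlan(
        mode=mode,
        indices=indices,
        seed=seed,
        strata_before=before,
        strata_after=after,
        dropped_strata=dropped,
    )
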