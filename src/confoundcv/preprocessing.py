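"""Train-fitted standardization, zero-variance removal, outlier exclusion.

All parameters are pure functions of the rows passed to ``fit``; the test set
can never influence the transform.  Standard deviations use the population
(divide-by-n) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Standardizer", "fit_standardizer", "apply_standardizer", "exclude_outlier_subjects"]


@dataclass
class Standardizer:
    kept_columns: np.ndarray  # indices into the ORIGINAL column space
    means: np.ndarray
    sds: np.ndarray
    n_columns: int  # original column count, for shape checking at apply time

    def to_dict(self) -> dict:
        return {
            "kept_columns": self.kept_columns.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "n_columns": self.n_columns,
        }


def fit_standardizer(X_train: np.ndarray) -> Standardizer:
    """Column means/SDs on training rows only; zero-variance columns dropped."""
    X = np.asarray(X_train, dtype=float)
    if X.size == 0:
        raise ValueError("empty training matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("training matrix must be finite")
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population convention (ddof=0)
    kept = np.nonzero(sds > 0)[0]
    if kept.size == 0:
        raise ValueError("all columns have zero variance on the training data")
    return Standardizer(
        kept_columns=kept, means=means[kept], sds=sds[kept], n_columns=X.shape[1]
    )


def apply_standardizer(s: Standardizer, X: np.ndarray) -> np.ndarray:
    """(x - mean) / sd on the kept columns; output width = len(kept_columns)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != s.n_columns:
        raise ValueError(f"expected {s.n_columns} columns, got {X.shape}")
    return (X[:, s.kept_columns] - s.means) / s.sds


def exclude_outlier_subjects(X_block: np.ndarray, k_sd: float = 3.0) -> np.ndarray:
    """Flag subjects whose block-mean intensity is > k_sd SDs from the cohort mean.

    Applied per feature block (e.g. the DTI-FA columns) at data preparation,
    before any train/test split.  Returns a boolean mask, True = outlier.
    """
    X = np.asarray(X_block, dtype=float)
    if X.ndim != 2:
        raise ValueError("X_block must be 2-D")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects to define the exclusion SD")
    m = X.mean(axis=1)  # per-subject block mean
    center, spread = m.mean(), m.std()
    if spread == 0:
        return np.zeros(X.shape[0], dtype=bool)
    return np.abs(m - center) > k_sd * spread
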