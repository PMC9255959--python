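"""Phenotype labeling: severity binning, moderate exclusion, trajectories.

Misuse phenotypes are derived from per-timepoint scores in four ways that
cover the usual labeling mechanisms in substance-use cohorts: thresholding a
score level into three severity stages, excluding the ambiguous middle group
to form a binary case/control contrast, summarizing the longitudinal
trajectory with a per-subject least-squares line, and clustering several
measures jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "PhenotypeLabels",
    "TrajectoryFit",
    "bin_severity",
    "make_binary_labels",
    "fit_trajectory",
    "combined_phenotype",
]


class DegenerateLabelError(ValueError):
    """Raised when binary labeling leaves one class empty."""


@dataclass
class PhenotypeLabels:
    """Binary case/control labels after excluding moderate misusers.

    ``label`` is defined (0 = safe/control, 1 = heavy/case) only where
    ``included`` is True; moderate subjects are excluded.
    """

    severity: np.ndarray
    label: np.ndarray  # float array, NaN where excluded
    included: np.ndarray
    excluded_count: int

    @property
    def y_included(self) -> np.ndarray:
        """Integer labels restricted to included subjects."""
        return self.label[self.included].astype(int)


def bin_severity(scores: np.ndarray, t_low: float, t_high: float) -> np.ndarray:
    """Three-stage severity from a score: safe / moderate / heavy.

    Bins are half-open: ``score < t_low`` is safe, ``t_low <= score < t_high``
    is moderate, and ``score >= t_high`` is heavy (the upper boundary is
    inclusive on the heavy side).
    """
    if not t_low < t_high:
        raise ValueError(f"require t_low < t_high, got {t_low} >= {t_high}")
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    out = np.full(scores.shape, "moderate", dtype="U8")
    out[scores < t_low] = "safe"
    out[scores >= t_high] = "heavy"
    return out


def make_binary_labels(severity: np.ndarray) -> PhenotypeLabels:
    """Binary labels from severity: heavy = 1, safe = 0, moderate excluded."""
    severity = np.asarray(severity, dtype="U8")
    if severity.size == 0:
        raise ValueError("severity vector is empty")
    included = severity != "moderate"
    label = np.full(severity.shape, np.nan)
    label[severity == "heavy"] = 1.0
    label[severity == "safe"] = 0.0
    n_heavy = int((severity == "heavy").sum())
    n_safe = int((severity == "safe").sum())
    if n_heavy == 0 or n_safe == 0:
        raise DegenerateLabelError(
            f"need both classes after exclusion, got heavy={n_heavy}, safe={n_safe}"
        )
    return PhenotypeLabels(
        severity=severity,
        label=label,
        included=included,
        excluded_count=int((~included).sum()),
    )


@dataclass
class TrajectoryFit:
    """Per-subject least-squares line of score on centered age."""

    intercept: np.ndarray  # value at the mean age
    slope: np.ndarray  # score units per year
    n_obs: np.ndarray  # observations used per subject


def fit_trajectory(scores: np.ndarray, ages: np.ndarray) -> TrajectoryFit:
    """Per-subject OLS line of score on age (age centered at its mean).

    Subjects with fewer than 2 non-missing observations get NaN intercept and
    slope (flagged, not raised).  Missing observations are NaN entries.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != ages.size:
        raise ValueError("scores must be subjects x timepoints matching ages")
    if ages.size < 2 or np.any(np.diff(ages) <= 0):
        raise ValueError("need >= 2 strictly increasing ages")

    t = ages - ages.mean()
    n, _ = scores.shape
    intercept = np.full(n, np.nan)
    slope = np.full(n, np.nan)
    n_obs = np.zeros(n, dtype=int)
    ok = np.isfinite(scores)
    n_obs[:] = ok.sum(axis=1)

    complete = ok.all(axis=1)
    if complete.any():
        # vectorized OLS for fully observed subjects
        sxx = float(t @ t)
        slope[complete] = scores[complete] @ t / sxx
        intercept[complete] = scores[complete].mean(axis=1)
    for i in np.nonzero(~complete & (n_obs >= 2))[0]:
        m = ok[i]
        ti = t[m] - t[m].mean()
        slope[i] = scores[i, m] @ ti / (ti @ ti)
        intercept[i] = scores[i, m].mean() - slope[i] * (t[m].mean())
    return TrajectoryFit(intercept=intercept, slope=slope, n_obs=n_obs)


def combined_phenotype(
    misuse_matrix: np.ndarray,
    k: int = 2,
    seed: int = 0,
    heavy_column: int = -1,
) -> tuple[np.ndarray, int]:
    """Cluster several misuse measures jointly into k groups.

    Columns are standardized internally; the cluster with the highest mean of
    ``heavy_column`` (default: last column, conventionally the binge measure)
    is designated heavy.  Returns ``(cluster_labels, heavy_cluster_id)``.
    """
    M = np.asarray(misuse_matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > M.shape[0]:
        raise ValueError("k cannot exceed the number of subjects")
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (M - M.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(Z)
    sizes = np.bincount(labels, minlength=k)
    if (sizes == 0).any():
        warnings.warn("degenerate clustering: at least one cluster is empty", stacklevel=2)
    heavy_cluster = -1
    best = -np.inf
    for c in range(k):
        if sizes[c] == 0:
            continue
        m = float(M[labels == c, heavy_column].mean())
        if m > best:
            best, heavy_cluster = m, c
    return labels, heavy_cluster
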