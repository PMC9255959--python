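"""Canonical synthetic study conditions for validating the pipeline.

Three desk-scale cohorts, each emulating one regime the evaluation design
has to handle.  Their parameters are fixed here, once, as the package's
reference conditions; tests and the reproduction script build on them.

* :func:`confounded_benchmark_cohort` — strong confounding on every channel:
  sex and site mean shifts on the features, per-site variance scaling, a
  sex-by-site interaction mean, and heavily confounded outcome prevalence
  (heavy-use probability 0.20 for low-risk cells up to 0.70 for males at the
  three high-prevalence sites).  This is the regime in which the correction
  techniques are compared.
* :func:`signal_benchmark_cohort` — the default generator conditions at 100
  features: ~1340 subjects so that ~1000 remain after excluding moderate
  misusers, 20 informative features at a standardized effect of d = 0.5,
  all confound channels at their default (moderate) strengths.
* :func:`null_benchmark_cohort` — no planted effects of any kind; used for
  type-I-error calibration of the permutation machinery.
"""

from __future__ import annotations

import numpy as np

from .cohort import Cohort, CohortConfig, generate_cohort
from .confounds import ConfoundFrame
from .phenotypes import make_binary_labels

__all__ = [
    "confounded_benchmark_cohort",
    "signal_benchmark_cohort",
    "null_benchmark_cohort",
]

HIGH_PREVALENCE_SITES = (0, 1, 2)


def _prevalence_map(n_sites, base, male_excess, site_excess, p_moderate=0.0):
    probs = {}
    for site in range(n_sites):
        for sex in ("female", "male"):
            p_heavy = base
            if sex == "male":
                p_heavy += male_excess
            if site in HIGH_PREVALENCE_SITES:
                p_heavy += site_excess
            probs[(sex, site)] = np.array([1 - p_moderate - p_heavy, p_moderate, p_heavy])
    return probs


def confounded_benchmark_cohort(
    seed: int,
    n_subjects: int = 1000,
    n_features: int = 100,
    n_sites: int = 8,
) -> tuple[np.ndarray, np.ndarray, ConfoundFrame, Cohort]:
    """Strongly confounded two-class cohort (no moderate group).

    Returns ``(X, y, confounds, cohort)`` with every subject included.
    """
    cfg = CohortConfig(
        n_subjects=n_subjects,
        n_sites=n_sites,
        n_features=n_features,
        n_informative=10,
        effect_size_d=0.4,
        sex_shift=0.5,
        site_shift=0.5,
        interaction_scale=0.3,
        site_var_scale=(0.7, 1.4),
        severity_probs_by_cell=_prevalence_map(n_sites, 0.20, 0.25, 0.25),
        seed=seed,
    )
    co = generate_cohort(cfg)
    y = (co.severity == "heavy").astype(int)
    return co.features, y, ConfoundFrame(co.sex, co.site), co


def signal_benchmark_cohort(
    seed: int,
    n_subjects: int = 1340,
    n_features: int = 100,
) -> tuple[np.ndarray, np.ndarray, ConfoundFrame, Cohort]:
    """Default-condition signal cohort after moderate exclusion.

    ~1000 included subjects, 20 informative features at d = 0.5, all
    confound channels on at default strengths.  Returns ``(X, y, confounds,
    cohort)`` restricted to included subjects.
    """
    cfg = CohortConfig(
        n_subjects=n_subjects,
        n_features=n_features,
        n_informative=20,
        effect_size_d=0.5,
        seed=seed,
    )
    co = generate_cohort(cfg)
    labels = make_binary_labels(co.severity)
    inc = labels.included
    return (
        co.features[inc],
        labels.y_included,
        ConfoundFrame(co.sex[inc], co.site[inc]),
        co.subset(inc),
    )


def null_benchmark_cohort(
    seed: int,
    n_subjects: int = 120,
    n_features: int = 10,
    n_sites: int = 2,
) -> tuple[np.ndarray, np.ndarray, ConfoundFrame]:
    """Global-null cohort: no signal, no confound effects, even prevalence."""
    cfg = CohortConfig(
        n_subjects=n_subjects,
        n_sites=n_sites,
        n_features=n_features,
        n_informative=0,
        effect_size_d=0.0,
        sex_shift=0.0,
        site_shift=0.0,
        interaction_scale=0.0,
        site_var_scale=(1.0, 1.0),
        severity_probs_by_cell=_prevalence_map(n_sites, 0.5, 0.0, 0.0),
        seed=seed,
    )
    co = generate_cohort(cfg)
    y = (co.severity == "heavy").astype(int)
    return co.features, y, ConfoundFrame(co.sex, co.site)
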