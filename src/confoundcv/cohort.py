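"""Synthetic multi-site cohort generation.

Real multi-site imaging cohorts couple the feature table to the outcome through
two kinds of pathways: a direct signal (disease-related structure in the
features) and confound pathways, where a demographic variable such as sex or
recruitment site both shifts the features and co-varies with the outcome.
Restricted-access data cannot ship with a package, so this module generates
cohorts with exactly that causal structure — a ground-truth record of every
planted effect included — and every downstream stage of the pipeline is
exercised against them.

The generative model, per subject ``i`` and feature ``f``::

    X[i, f] = mu_f
              + sex_shift  * a_f * 1[sex_i = male]
              + site_shift * b[f, site_i]
              + interaction_scale * g_f * 1[sex_i = male] * h[site_i]
              + d_f * delta(severity_i)
              + eps[i, f],     eps[i, f] ~ N(0, (sigma_f * v[site_i])**2)

where ``a_f``, ``b[f, s]``, ``g_f`` and ``h[s]`` are drawn once per cohort
from standard normals, ``d_f = effect_size_d`` for the ``n_informative``
informative features (``delta`` = 1 for heavy, 1/2 for moderate, 0 for safe)
and 0 elsewhere, and ``v[s]`` is a per-site variance multiplier.  The two
*non-linear* confound channels — per-site variance scaling and a sex-by-site
interaction mean — are deliberately invisible to main-effects confound
regression but detectable by a kernel classifier.

Misuse severity is drawn first, per (sex, site) cell, and both the features
and the longitudinal misuse scores depend on it; this ordering gives exact
ground truth for label-recovery tests.  Scores follow a per-subject line
``alpha_i + beta_i * (t - t0) + noise`` with class-conditional intercepts and
slopes, so heavier users start higher and escalate faster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "generate_xor_cohort",
    "cohort_summary",
    "save_cohort",
    "load_cohort",
]

SEVERITIES = ("safe", "moderate", "heavy")
#: mean-shift multiplier applied to informative features per severity class
SEVERITY_DELTA = {"safe": 0.0, "moderate": 0.5, "heavy": 1.0}


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


def _default_site_probs(n_sites: int) -> np.ndarray:
    # unequal site sizes, largest ~2x the smallest, like a multi-centre study
    w = np.linspace(2.0, 1.0, n_sites)
    return w / w.sum()


def _default_severity_probs(
    n_sites: int, high_sites: Sequence[int] = (0, 1, 2)
) -> dict[tuple[str, int], np.ndarray]:
    """Heavier-misuse prevalence for males and for a few 'high' sites.

    The exact per-cell rates of any real cohort are free parameters here; the
    defaults only reproduce the qualitative pattern (male > female prevalence
    at most sites, a cluster of high-prevalence sites) that makes sex and site
    genuine confounds.
    """
    probs: dict[tuple[str, int], np.ndarray] = {}
    for site in range(n_sites):
        for sex in ("female", "male"):
            p_heavy = 0.20
            if sex == "male":
                p_heavy += 0.10
            if site in high_sites:
                p_heavy += 0.10
            p_mod = 0.25
            probs[(sex, site)] = np.array([1.0 - p_mod - p_heavy, p_mod, p_heavy])
    return probs


def _default_trajectories() -> dict[str, dict[str, float]]:
    # intercept at age 14 and slope in score units / year, by severity class
    return {
        "safe": {"intercept": 0.5, "intercept_sd": 0.5, "slope": 0.10, "slope_sd": 0.05},
        "moderate": {"intercept": 2.5, "intercept_sd": 0.5, "slope": 0.35, "slope_sd": 0.05},
        "heavy": {"intercept": 4.5, "intercept_sd": 0.5, "slope": 0.60, "slope_sd": 0.05},
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study conditions this pipeline targets: ~1400
    adolescents over 8 unequal recruitment sites, 719 structural features in
    a 656-wide T1w block and a 63-wide DTI-FA block, sex- and site-dependent
    misuse prevalence, linear and non-linear confound channels, and a small
    set of genuinely informative features.
    """

    n_subjects: int = 1400
    n_sites: int = 8
    site_probs: np.ndarray | None = None
    p_male_by_site: np.ndarray | None = None
    severity_probs_by_cell: Mapping[tuple[str, int], np.ndarray] | None = None
    n_features: int = 719
    t1w_features: int = 656
    n_informative: int = 20
    effect_size_d: float = 0.5
    sex_shift: float = 0.3
    site_shift: float = 0.3
    site_var_scale: tuple[float, float] = (0.7, 1.4)
    interaction_scale: float = 0.2
    timepoints: tuple[float, ...] = (14.0, 16.0, 19.0, 22.0)
    trajectory_params: dict[str, dict[str, float]] = field(default_factory=_default_trajectories)
    score_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_sites <= 0 or self.n_features <= 0:
            raise ConfigError("counts must be positive")
        if self.site_probs is None:
            self.site_probs = _default_site_probs(self.n_sites)
        self.site_probs = np.asarray(self.site_probs, dtype=float)
        if self.p_male_by_site is None:
            self.p_male_by_site = np.full(self.n_sites, 0.5)
        self.p_male_by_site = np.asarray(self.p_male_by_site, dtype=float)
        if self.severity_probs_by_cell is None:
            self.severity_probs_by_cell = _default_severity_probs(self.n_sites)
        if self.t1w_features > self.n_features:
            # keep the block split meaningful for small feature counts
            self.t1w_features = int(round(self.n_features * 656 / 719))
        self._validate()

    def _validate(self) -> None:
        if len(self.site_probs) != self.n_sites:
            raise ConfigError("site_probs length must equal n_sites")
        if abs(self.site_probs.sum() - 1.0) > 1e-12 or (self.site_probs < 0).any():
            raise ConfigError("site_probs must be a probability vector summing to 1")
        if ((self.p_male_by_site < 0) | (self.p_male_by_site > 1)).any():
            raise ConfigError("p_male_by_site entries must lie in [0, 1]")
        for cell, p in self.severity_probs_by_cell.items():
            p = np.asarray(p, dtype=float)
            if len(p) != 3 or abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
                raise ConfigError(f"severity probabilities for cell {cell} must be a 3-vector summing to 1")
        if self.n_informative > self.n_features:
            raise ConfigError("n_informative cannot exceed n_features")
        lo, hi = self.site_var_scale
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ConfigError("site_var_scale multipliers must be strictly positive with lo <= hi")
        if len(self.timepoints) < 1 or np.any(np.diff(self.timepoints) <= 0):
            raise ConfigError("timepoints must be strictly increasing")


@dataclass
class Cohort:
    """A generated cohort plus the ground truth used to generate it."""

    features: np.ndarray  # n_subjects x n_features
    feature_names: list[str]
    sex: np.ndarray  # of {"female", "male"}
    site: np.ndarray  # of int site ids
    severity: np.ndarray  # of {"safe", "moderate", "heavy"}
    scores: np.ndarray  # n_subjects x n_timepoints
    timepoints: np.ndarray
    truth: dict

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def block_columns(self, block: str) -> np.ndarray:
        """Column indices of a feature block ('t1w' or 'dti')."""
        prefix = block + "_"
        idx = [j for j, name in enumerate(self.feature_names) if name.startswith(prefix)]
        if not idx:
            raise KeyError(f"no features in block {block!r}")
        return np.asarray(idx)

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row-subset the cohort (boolean mask or integer indices)."""
        return Cohort(
            features=self.features[mask],
            feature_names=self.feature_names,
            sex=self.sex[mask],
            site=self.site[mask],
            severity=self.severity[mask],
            scores=self.scores[mask],
            timepoints=self.timepoints,
            truth=self.truth,
        )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a cohort from the generative model described in the module docstring.

    Identical config + seed gives a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_features

    site = rng.choice(config.n_sites, size=n, p=config.site_probs)
    male = rng.random(n) < config.p_male_by_site[site]
    sex = np.where(male, "male", "female")

    severity = np.empty(n, dtype=object)
    for i in range(n):
        probs = np.asarray(config.severity_probs_by_cell[(sex[i], int(site[i]))], dtype=float)
        severity[i] = SEVERITIES[rng.choice(3, p=probs)]
    severity = severity.astype("U8")

    # per-cohort effect parameters, drawn once
    a = rng.standard_normal(p)                      # sex main effect direction
    b = rng.standard_normal((p, config.n_sites))    # site mean offsets
    g = rng.standard_normal(p)                      # sex x site interaction direction
    h = rng.standard_normal(config.n_sites)         # site loading of the interaction
    lo, hi = config.site_var_scale
    v = rng.uniform(lo, hi, size=config.n_sites)    # per-site noise-sd multiplier
    sigma = np.ones(p)
    mu = np.zeros(p)

    informative = rng.choice(p, size=config.n_informative, replace=False)
    d = np.zeros(p)
    d[informative] = config.effect_size_d

    delta = np.array([SEVERITY_DELTA[s] for s in severity])
    X = (
        mu
        + config.sex_shift * np.outer(male, a)
        + config.site_shift * b[:, site].T
        + config.interaction_scale * np.outer(male * h[site], g)
        + np.outer(delta, d)
        + rng.standard_normal((n, p)) * (sigma * v[site][:, None])
    )

    # longitudinal misuse scores: class-conditional line + observation noise
    t = np.asarray(config.timepoints)
    t_rel = t - t[0]
    alpha = np.empty(n)
    beta = np.empty(n)
    for cls in SEVERITIES:
        m = severity == cls
        tp = config.trajectory_params[cls]
        alpha[m] = tp["intercept"] + tp["intercept_sd"] * rng.standard_normal(m.sum())
        beta[m] = tp["slope"] + tp["slope_sd"] * rng.standard_normal(m.sum())
    scores = alpha[:, None] + beta[:, None] * t_rel[None, :]
    scores += config.score_noise_sd * rng.standard_normal(scores.shape)

    # severity-recovery thresholds at the final timepoint: midpoints between
    # the class-conditional means of the generating trajectories
    final = t_rel[-1]
    class_mean = {
        cls: config.trajectory_params[cls]["intercept"]
        + config.trajectory_params[cls]["slope"] * final
        for cls in SEVERITIES
    }
    t_low = 0.5 * (class_mean["safe"] + class_mean["moderate"])
    t_high = 0.5 * (class_mean["moderate"] + class_mean["heavy"])

    n_t1w = min(config.t1w_features, p)
    feature_names = [f"t1w_{j:04d}" for j in range(n_t1w)] + [
        f"dti_{j:04d}" for j in range(p - n_t1w)
    ]

    truth = {
        "informative": sorted(int(j) for j in informative),
        "effect_size_d": config.effect_size_d,
        "sex_shift": config.sex_shift,
        "site_shift": config.site_shift,
        "interaction_scale": config.interaction_scale,
        "site_var_multipliers": v.tolist(),
        "site_interaction_loading": h.tolist(),
        "final_score_thresholds": {"t_low": float(t_low), "t_high": float(t_high)},
        "seed": config.seed,
    }

    return Cohort(
        features=X,
        feature_names=feature_names,
        sex=sex,
        site=site,
        severity=severity,
        scores=scores,
        timepoints=t,
        truth=truth,
    )


def generate_xor_cohort(
    n_subjects: int = 1000,
    n_features: int = 50,
    n_pairs: int = 2,
    scale: float = 1.0,
    label_noise: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A purely interaction-driven (XOR-style) classification problem.

    Each informative pair contributes ``sign(x_a) * sign(x_b)`` to the label
    vote, so each feature is marginally uninformative: linear models sit at
    chance while kernel and tree ensembles can learn the mapping.  Used to
    benchmark the non-linear vs linear model families.

    Returns ``(X, y)`` with y in {0, 1}.
    """
    if 2 * n_pairs > n_features:
        raise ConfigError("need at least 2*n_pairs features")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_subjects, n_features)) * scale
    vote = np.zeros(n_subjects)
    for k in range(n_pairs):
        vote += np.sign(X[:, 2 * k]) * np.sign(X[:, 2 * k + 1])
    y = (vote > 0).astype(int)
    ties = vote == 0
    y[ties] = rng.integers(0, 2, size=ties.sum())
    flip = rng.random(n_subjects) < label_noise
    y[flip] = 1 - y[flip]
    return X, y


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-(sex, site) cell counts and heavy-severity proportions.

    The table mirrors the prevalence diagram of a multi-site study: one row
    per cell with the number of subjects and the fraction in the heavy class.
    """
    if cohort.n_subjects == 0:
        raise ValueError("empty cohort")
    df = pd.DataFrame({"sex": cohort.sex, "site": cohort.site, "severity": cohort.severity})
    rows = []
    for (sex, site), grp in df.groupby(["sex", "site"], sort=True):
        rows.append(
            {
                "sex": sex,
                "site": int(site),
                "n": len(grp),
                "n_heavy": int((grp["severity"] == "heavy").sum()),
                "prop_heavy": float((grp["severity"] == "heavy").mean()),
            }
        )
    out = pd.DataFrame(rows)
    assert out["n"].sum() == cohort.n_subjects
    return out


def save_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write features.csv, confounds.csv, phenotype.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = [f"sub-{i:05d}" for i in range(cohort.n_subjects)]

    feat = pd.DataFrame(cohort.features, columns=cohort.feature_names)
    feat.insert(0, "subject_id", sid)
    feat.to_csv(outdir / "features.csv", index=False)

    conf = pd.DataFrame({"subject_id": sid, "sex": cohort.sex, "site": cohort.site})
    conf.to_csv(outdir / "confounds.csv", index=False)

    pheno = pd.DataFrame(
        cohort.scores, columns=[f"score_age{t:g}" for t in cohort.timepoints]
    )
    pheno.insert(0, "subject_id", sid)
    pheno.insert(1, "severity", cohort.severity)
    pheno.to_csv(outdir / "phenotype.csv", index=False)

    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2)


def load_cohort(indir: str | Path) -> Cohort:
    """Read a cohort written by :func:`save_cohort`."""
    indir = Path(indir)
    feat = pd.read_csv(indir / "features.csv")
    conf = pd.read_csv(indir / "confounds.csv")
    pheno = pd.read_csv(indir / "phenotype.csv")
    truth_path = indir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}

    feature_names = [c for c in feat.columns if c != "subject_id"]
    score_cols = [c for c in pheno.columns if c.startswith("score_age")]
    timepoints = np.array([float(c.removeprefix("score_age")) for c in score_cols])
    return Cohort(
        features=feat[feature_names].to_numpy(float),
        feature_names=feature_names,
        sex=conf["sex"].to_numpy(str),
        site=conf["site"].to_numpy(int),
        severity=pheno["severity"].to_numpy(str) if "severity" in pheno else np.array([]),
        scores=pheno[score_cols].to_numpy(float),
        timepoints=timepoints,
        truth=truth,
    )
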