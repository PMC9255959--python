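# Methods

`confoundcv` implements a confound-aware evaluation design for relating a
subjects-by-features table (the motivating case: structural brain
morphometrics from T1-weighted MRI and DTI fractional anisotropy, pooled
across recruitment sites) to a binary phenotype (the motivating case:
adolescent alcohol misuse, heavy misusers vs safe users after excluding the
moderate middle group). This note records the model, the design choices that
were genuinely open, the numerical conventions, and what the synthetic
validation does and does not establish.

## The confounding problem

A confound `c` (here sex and recruitment site, both categorical) is a
variable that correlates with the outcome `y` and is recoverable from the
input features `X`. It opens a spurious pathway `X <- c -> y`: a classifier
can reach significant accuracy by reading the confound out of the features
and exploiting the confound–outcome association, without ever touching the
signal of interest. Two corrections are implemented, both fitted strictly on
training rows:

- **Confound regression** removes the confound's footprint in `X`: each
  feature is regressed on `[intercept | sex dummies | site dummies]`
  (drop-first one-hot) by OLS, and residuals are carried forward. This
  removes *every per-category mean shift* but, being a linear main-effects
  model, cannot remove per-category variance differences or sex-by-site
  interaction means.
- **Counterbalancing** removes the confound–outcome association instead:
  the training rows are resampled so that within every joint (sex, site)
  stratum the two label classes are equal — down to the stratum minimum
  (undersampling) or up to the stratum maximum by sampling the minority with
  replacement (oversampling). Balancing the joint cell guarantees both
  marginals and makes the resampled cell-by-label contingency exactly
  independent: its chi-square statistic is identically zero, which the tests
  assert as an exact invariant. Strata missing one class entirely are
  dropped with a warning rather than imputed.

Whether to balance the joint cell or each confound marginally was an open
choice; the joint cell was chosen because it is the only scheme that makes
the independence invariant exact and it implies both marginals. Equalizing
the classes within each stratum also equalizes them globally, which is
acceptable because all scoring uses balanced accuracy.

## The diagnostic battery

Whether a correction *worked* is checked empirically, with the same model
family and the same cross-validation folds as the main analysis, on five
input-output combinations: `X->y`, `X->c_sex`, `X->c_site`, `c_sex->y`,
`c_site->y`. A successful confound regression drives `X->c` to chance; a
successful counterbalancing drives `c->y` to chance. Confounds used as
inputs are fed as a full (no category dropped) one-hot block — classifiers
have no collinearity constraint and should see every indicator; confounds
used as targets are scored with multiclass balanced accuracy (mean per-class
recall, chance `1/#classes`), reduced one-vs-rest for the SVM families and
natively multiclass elsewhere. AUC is reported only for the binary main
task.

One structural subtlety: when the row's *input* is a two-valued variable
(the `c_sex->y` row), a classifier refitted on permuted labels collapses to
one of the two complementary labelings at random, so the permutation null
contains the observed score with probability about `2^-k` over `k` folds.
Significance on these rows therefore needs the full 7-fold design; with
fewer folds the test is valid but underpowered.

## Two-stage evaluation

The data are split 80/20 into an exploration set and a holdout, stratified
on the joint (label, sex, site) cell when every cell has at least two
members, else on the label alone. All selection — hyperparameters through a
7-outer / 5-inner nested cross-validation scored by balanced accuracy, and
any comparison across model families or phenotype definitions — happens on
the exploration set. Hyperparameter ties break by grid order. The
generalization test then freezes the modal hyperparameter choice, retrains
on the full exploration set seven times varying only the model and
resampling seeds, and scores each refit once on the holdout; whether the
holdout retraining should re-run the hyperparameter search was ambiguous,
and freezing was chosen so that the holdout can never influence any
selection.

Within every fold the order of operations is: counterbalancing resample (if
active) → confound regression (if active; the two are alternative modes) →
standardization → classifier fit. Standardization uses the population
(divide-by-n) SD, drops zero-variance columns, and is fitted *after*
resampling because the resampled set is what the model sees — whether to fit
it before or after resampling was open, and the choice is recorded in the
run metadata. Subject-level outlier exclusion (block-mean more than 3 SD
from the cohort block-mean, applied per feature block) happens once at data
preparation, before any split.

Significance uses the train-shuffling permutation test: the whole pipeline
is rerun with permuted *training* labels while test labels stay fixed, and
`p = (1 + #{null >= observed}) / (n_perm + 1)` (add-one estimator: unbiased
direction, never zero). Implementation note: stages that cannot depend on
the labels (confound regression, standardization when no resampling is
active) are prepared once per fold and reused across permutations — the
results are mathematically identical to full refits, only faster. When
several analyses are run on the same subjects, Bonferroni correction
multiplies p by the number of simultaneous analyses, capped at 1.

Leave-one-site-out mode replaces the random folds: one designated site is
the holdout, each remaining site is one test fold. Site cannot be
counterbalanced in this design (each fold *is* a site), so only sex is; the
restriction is recorded in the result metadata.

## Model families

Four classifier families: logistic regression, linear SVM (liblinear), RBF
kernel SVM, and gradient boosting (XGBoost). The default tuning grids are
modest: four log-spaced regularization strengths for the linear families, a
3x3 (C, kernel width) grid for the RBF kernel, and a 2x2x2 (trees, depth,
learning rate) grid for boosting. On a purely interaction-driven benchmark
(labels from XOR of feature-sign pairs, marginally uninformative features)
the two non-linear families beat both linear families — the expected
ordering when the signal is not additive.

## Shapley attribution and stable features

Feature importance uses interventional Shapley values estimated by the
permutation method: for each scored subject, sampled feature orderings are
walked forward and backward (antithetic pairs), flipping one feature at a
time from a background sample to the subject's values and accumulating the
change in the model's expected output. Each pass telescopes, so the
additivity identity `base + sum_f S[s,f] = f(x_s)` holds exactly at any
sampling budget; estimator noise affects only how credit is distributed.
Attributions are computed on the model's continuous decision scale (margin /
log-odds), where additivity is meaningful — the probability scale would
break it. The estimator is validated against exhaustive `2^d` coalition
enumeration at `d = 6` (agreement within 0.02 per feature).

Per run, `S̄_f` is the mean |attribution| per feature and `S̄` its average
over features. A feature is **stable** when `S̄_f >= 2 S̄` (read
inclusively) in at least 6 of the 7 runs (`ceil(6k/7)` for `k` runs).
Correlated features split credit, so the stable set is conservative; on the
reference signal cohort its precision against the planted informative
features is required to be at least 0.5, not 1.0. Direction of effect
("higher/lower than average in predicted cases") compares each stable
feature's mean among predicted-positive holdout subjects to its overall
holdout mean; if every subject is predicted positive the comparison is
flagged undefined. The background set is training rows drawn with a fixed
seed; background size, target count and ordering count are configurable
(the scale of `S̄_f` depends on the model's decision scale and is only
compared within a run, so the 2x-grand-mean threshold is scale-free).

## The synthetic cohort generator

Per subject `i` and feature `f`:

```
X[i,f] = mu_f + sex_shift * a_f * [male_i]
       + site_shift * b[f, site_i]
       + interaction_scale * g_f * [male_i] * h[site_i]
       + d_f * delta(severity_i) + eps,   eps ~ N(0, (sigma_f * v[site_i])^2)
```

with `a, b, g, h` drawn once per cohort, `d_f` equal to a configured Cohen's
d for the informative features (`delta` = 1 heavy, 1/2 moderate, 0 safe) and
0 otherwise, and `v[site]` a per-site noise-SD multiplier. Severity is drawn
first, per (sex, site) cell, and features and longitudinal scores depend on
it — this ordering gives exact ground truth for recovery tests. Misuse
scores follow per-subject lines with class-conditional intercepts and slopes
over ages 14/16/19/22, so thresholding the final score, thresholding the
slope, or clustering both reproduce the generated classes up to noise.

The two non-linear confound channels (per-site variance scaling,
sex-by-site interaction means) exist precisely because one-hot main-effects
regression cannot remove them while an RBF classifier can still exploit
them: they are what makes the "regression blinds linear but not kernel
models" contrast reproducible on synthetic data.

Default prevalences make males and three "high" sites heavier-using —
qualitatively the pattern of real multi-site adolescent cohorts; the exact
per-cell rates of any restricted-access cohort are not public and the
defaults must not be read as estimates of them. Severity bins are half-open
(`[t_low, t_high)`, heavy inclusive at `t_high`) and the thresholds are
configuration values. Growth phenotypes use per-subject OLS lines rather
than latent growth curve models: the pipeline only consumes a per-subject
trajectory summary, and the OLS line is exact, fast and assumption-light.

What the generator does *not* emulate: raw image acquisition and feature
extraction, missing data (cohorts are complete), longitudinal feature
matrices (features are cross-sectional per analysis), continuous confounds
(age, intracranial volume), questionnaire-item structure, and realistic
feature correlation (features are independent given the planted effects).
Passing tests therefore establish that the *pipeline machinery* behaves as
designed under known ground truth — not that any particular real-data result
is correct.

## Reference study conditions and problem sizes

Validation runs at desk scale, chosen once:

- **Confounded benchmark** (technique comparison): n = 1000, 8 sites, 100
  features (10 informative at d = 0.4), sex/site shifts 0.5, interaction
  0.3, site-variance multipliers 0.7–1.4, heavy-use prevalence 0.20 up to
  0.70 across cells; seeds 0–9; 199 permutations; 7-fold checks.
- **Signal benchmark** (recovery): generator defaults at 100 features
  (90 t1w + 63-scaled dti block), ~1340 subjects so ~1000 remain after
  moderate exclusion, 20 informative at d = 0.5; explore ~790 / holdout
  ~198; 7 holdout retrainings; Shapley on 64 holdout subjects against a
  32-row background, one antithetic ordering pair per subject.
- **Null benchmark** (calibration): n = 120, 10 features, no effects; 200
  replicate pipelines at 199 permutations; type-I error at nominal 0.05
  required within [0.01, 0.10] and p-values KS-uniform at alpha 0.01.
- **Interaction benchmark** (family ordering): n = 800, 12 features, 2 XOR
  pairs, 5% label noise.

The full-scale configuration (719 features, 656 + 63 blocks, n = 1400) is
the generator default and runs the same code; the desk-scale sizes keep the
complete validation suite in the tens of minutes.

## Numerical conventions and degenerate inputs

Population SD throughout standardization (makes the two-point example
exact). Zero-variance columns are dropped at fit and their removal carried
to apply. Unseen confound categories at apply time are an error; confound
categories empty at fit time drop their design column with a warning. A
stratum with one label class absent is dropped from counterbalancing with a
warning; if no stratum has both classes, the resampling errors out. Binary
labeling with either class empty raises. Trajectory fits need two
observations per subject; subjects with fewer are flagged NaN, not raised.
Outlier exclusion needs at least 3 subjects. k-means phenotypes require
k >= 2 and warn on empty clusters; the cluster with the highest mean of the
designated (by default last, conventionally binge) measure is labeled heavy.

## Known limitations

Confound regression here is main-effects linear only, by design — that
limitation is the point of the diagnostic battery. Counterbalancing supports
categorical confounds only. The Shapley estimator treats features as
independent when intervening (background replacement), and correlated
features dilute each other's importance; grouped permutation of correlated
features is out of scope. Oversampling duplicates minority rows, which can
overstate effective sample size for variance estimates — scores are reported
per fold/seed with spread rather than pooled. The stable-feature rule is a
consistency filter, not an inference procedure: it controls no error rate.
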