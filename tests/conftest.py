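import numpy as np
import pytest

from confoundcv import (
    CohortConfig,
    ConfoundFrame,
    generate_cohort,
    make_binary_labels,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 500-subject, 40-feature cohort with all confound channels active."""
    cfg = CohortConfig(
        n_subjects=500,
        n_features=40,
        n_informative=8,
        effect_size_d=0.6,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def labeled_data(small_cohort):
    """(X, y, ConfoundFrame) restricted to included (non-moderate) subjects."""
    labels = make_binary_labels(small_cohort.severity)
    inc = labels.included
    X = small_cohort.features[inc]
    y = labels.y_included
    C = ConfoundFrame(small_cohort.sex[inc], small_cohort.site[inc])
    return X, y, C


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
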