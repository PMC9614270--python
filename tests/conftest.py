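import warnings

import numpy as np
import pytest

from podeeg import (
    CohortSpec,
    DeliriumRiskModel,
    PipelineConfig,
    extract_cohort_features,
    simulate_cohort,
)


def random_spd(rng: np.random.Generator, dim: int, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random SPD matrix."""
    a = rng.normal(size=(dim, dim))
    return scale * (a @ a.T + dim * np.eye(dim))


@pytest.fixture(scope="session")
def fast_config():
    """Reduced ensemble/forest sizes so unit tests stay quick; every
    structural parameter keeps its default."""
    return PipelineConfig(n_estimators=5, n_trees=100)


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(
        n_patients=18,
        pod_prevalence=0.35,
        duration_range_min=(20.0, 24.0),
        seed=11,
    )
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort, fast_config):
    _, patients = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feats = extract_cohort_features(patients, fast_config)
    assert feats.labels.nunique() == 2
    return feats


@pytest.fixture(scope="session")
def fitted_results(small_features, fast_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return DeliriumRiskModel(small_features, fast_config).fit(seed=3)
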