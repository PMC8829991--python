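import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import osteoscreen as osc
from osteoscreen.feature_table import FeatureMatrix

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject default-effect cohort with 2 replicate segmentations."""
    return osc.generate_cohort(osc.CohortConfig(n_subjects=40, seed=7, n_replicates=2))


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return small_cohort.feature_matrix()


@pytest.fixture(scope="session")
def replicate_frame(small_cohort):
    """Replicate image-feature extractions of the small cohort (ICC input)."""
    return small_cohort.replicate_features()


def make_matrix(X: pd.DataFrame, y, categories=None, scales=None,
                voltage=None) -> FeatureMatrix:
    """Assemble a FeatureMatrix from a plain table (test helper)."""
    categories = categories or {}
    scales = scales or {}
    meta = pd.DataFrame({
        "category": [categories.get(c, "laboratory") for c in X.columns],
        "scale": [scales.get(c, "numeric") for c in X.columns],
        "layers": [frozenset({1, 2, 3}) for _ in X.columns],
        "levels": [None for _ in X.columns],
    }, index=pd.Index(X.columns, name="name"))
    return FeatureMatrix(
        X=X.copy(),
        y=pd.Series(np.asarray(y), index=X.index, name="label"),
        meta=meta,
        tube_voltage=None if voltage is None
        else pd.Series(np.asarray(voltage), index=X.index, name="tube_voltage"),
    )
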