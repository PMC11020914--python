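import numpy as np
import pandas as pd
import pytest

import hfclust as h
from hfclust import preprocessing as pp


@pytest.fixture(scope="session")
def feature_columns():
    spec = h.default_cohort_spec(n_patients=10, seed=0)
    continuous = ["age"] + list(spec.lab_specs)
    binary = ["gender"] + list(spec.comorbidity_names)
    return continuous, binary


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient default-condition cohort shared across read-only tests."""
    return h.simulate_cohort(h.default_cohort_spec(n_patients=400, seed=7))


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort, feature_columns):
    continuous, binary = feature_columns
    return pp.preprocess(small_cohort.patients, continuous, binary, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_mixed_table(rng, n=20, n_interval=3, n_categorical=3):
    """A random mixed-type FeatureMatrix for Gower/FAMD oracle checks."""
    cols = {}
    for j in range(n_interval):
        cols[f"num{j}"] = rng.normal(size=n) * rng.uniform(0.5, 5)
    for j in range(n_categorical):
        cols[f"bin{j}"] = rng.integers(0, 2, size=n).astype(float)
    df = pd.DataFrame(cols)
    return pp.FeatureMatrix.from_cohort(
        df, [f"num{j}" for j in range(n_interval)],
        [f"bin{j}" for j in range(n_categorical)],
    )
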