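import numpy as np
import pandas as pd
import pytest

from pgaselect import (
    ClassifierSpec,
    EFIConfig,
    FeatureSchema,
    FeatureSpec,
    FeatureTable,
    SyntheticConfig,
    planted_subset_cohort,
)


@pytest.fixture
def toy_schema() -> FeatureSchema:
    """Two administrative features, one derived, two deficits."""
    specs = {
        "a1": FeatureSpec("a1", "low", "ordinal(3)", "administrative"),
        "a2": FeatureSpec("a2", "low", "ordinal(3)", "administrative"),
        "d": FeatureSpec("d", "low", "binary", "derived", definition="max(a1 >= 2, a2 >= 2)"),
        "def_01": FeatureSpec("def_01", "high", "binary", "deficit"),
        "def_02": FeatureSpec("def_02", "high", "binary", "deficit"),
    }
    return FeatureSchema(
        features=specs,
        efi=EFIConfig(deficit_names=("def_01", "def_02", "d"), threshold=0.21),
    )


@pytest.fixture
def toy_table() -> FeatureTable:
    values = pd.DataFrame(
        {
            "a1": [2, 0, np.nan, 1],
            "a2": [0, 2, 1, 0],
            "def_01": [1, 0, 1, 0],
            "def_02": [1, 1, 0, 0],
        },
        index=["r1", "r2", "r3", "r4"],
    )
    return FeatureTable(values=values, label=pd.Series([1, 1, 0, 0], index=values.index))


def separable_toy(n_per_class: int = 50, seed: int = 0):
    """1-D linearly separable problem: y = 1[x > 0]."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.uniform(0.5, 2.0, n_per_class), rng.uniform(-2.0, -0.5, n_per_class)])
    y = (x > 0).astype(int)
    X = pd.DataFrame({"x": x})
    return X, y


@pytest.fixture(params=["logistic_regression", "svm", "decision_tree", "random_forest"])
def classifier_spec(request) -> ClassifierSpec:
    return ClassifierSpec(kind=request.param, seed=7)


@pytest.fixture(scope="session")
def small_planted_cohort():
    """300 records, 10 candidate deficits, 3 informative — for GA tests."""
    return planted_subset_cohort(
        3,
        SyntheticConfig(
            n_records=300,
            n_deficits=10,
            n_admin=0,
            n_derived=0,
            n_high_missing_admin=0,
            target_prevalence=0.5,
            seed=42,
        ),
    )
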