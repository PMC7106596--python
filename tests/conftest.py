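import numpy as np
import pytest

from qsprblend import DescriptorTable, Level0Spec, SyntheticSpec, generate_classification, generate_regression

# small, fast hyperparameters used throughout the unit tests
FAST = {"n_estimators": 20}


def fast_specs(task, random_state=0):
    from qsprblend.level0 import KINDS

    return [
        Level0Spec(kind=k, hyperparameters=dict(FAST), random_state=random_state, task=task)
        for k in KINDS
    ]


@pytest.fixture(scope="session")
def reg_table():
    """Small regression table with 3 planted features out of 12."""
    spec = SyntheticSpec(
        n_samples=150, n_features=12, n_informative=3, noise_sd=0.3,
        nonlinearity="none", seed=11,
    )
    table, informative = generate_regression(spec)
    return table, informative


@pytest.fixture(scope="session")
def clf_table():
    """Small imbalanced classification table (73% positives)."""
    spec = SyntheticSpec(
        n_samples=200, n_features=12, n_informative=3, noise_sd=0.3,
        nonlinearity="none", seed=7,
    )
    table, informative = generate_classification(spec)
    return table, informative


@pytest.fixture
def tiny_csv(tmp_path):
    path = tmp_path / "tiny.csv"
    path.write_text(
        "sample_id,f1,f2,y\n"
        "s1,0.5,1.0,2.0\n"
        "s2,-0.5,2.0,3.0\n"
    )
    return path
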