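import numpy as np
import pandas as pd
import pytest

from danpmv import fixtures
from danpmv.framework import EvaluationFramework


@pytest.fixture(scope="session")
def study_framework():
    return fixtures.load_study_framework()


@pytest.fixture(scope="session")
def published_weights(study_framework):
    return fixtures.load_published_weights(study_framework)


@pytest.fixture(scope="session")
def published_performances():
    return fixtures.load_published_performances()


@pytest.fixture(scope="session")
def published_table():
    return fixtures.load_published_table()


@pytest.fixture
def toy_framework():
    """2 dimensions x 2 criteria, the smallest valid framework."""
    return EvaluationFramework.from_dict(
        {
            "dimensions": [{"code": "G1", "name": "one"}, {"code": "G2", "name": "two"}],
            "criteria": [
                {"code": "a1", "dimension": "G1"},
                {"code": "a2", "dimension": "G1"},
                {"code": "b1", "dimension": "G2"},
                {"code": "b2", "dimension": "G2"},
            ],
        }
    )


def random_total_influence(framework, rng):
    """Strictly positive random T indexed like the framework (test helper)."""
    codes = framework.criterion_codes
    n = len(codes)
    return pd.DataFrame(
        rng.uniform(0.05, 1.0, size=(n, n)), index=codes, columns=codes
    )
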