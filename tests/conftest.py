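import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pairdx.io import ExpressionMatrix
from pairdx.presets import recovery_synthetic_config, small_synthetic_config
from pairdx.simulate import generate_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def tiny_expr():
    """Hand-written 3-gene x 3-sample matrix with known pair orderings."""
    values = pd.DataFrame(
        [[5.0, 1.0, 2.0], [3.0, 4.0, 2.0], [1.0, 2.0, 9.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(values, cohort_id="tiny")


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_synthetic_config(seed=3))


@pytest.fixture(scope="session")
def recovery_study():
    return generate_study(recovery_synthetic_config(seed=1))


def random_expression(rng, n_genes=8, n_samples=5, cohort_id="rand"):
    genes = [f"G{i:03d}" for i in range(1, n_genes + 1)]
    samples = [f"s{i:02d}" for i in range(1, n_samples + 1)]
    values = pd.DataFrame(
        rng.normal(8, 2, size=(n_genes, n_samples)), index=genes, columns=samples
    )
    return ExpressionMatrix(values, cohort_id=cohort_id)
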