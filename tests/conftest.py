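import numpy as np
import pandas as pd
import pytest

from lncdys.expression_data import ExpressionMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples (2 cancer / 2 normal)."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 0.5, 1.0, 1.5], [10.0, 20.0, 5.0, 5.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    group = pd.Series(
        ["cancer", "cancer", "normal", "normal"],
        index=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values=values, group=group)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    from lncdys.synthetic_cohort import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(seed=7))
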