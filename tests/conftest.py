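import numpy as np
import pandas as pd
import pytest

from varstrat.models import CohortTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_cohort(rng):
    """Balanced two-group cohort with a PC covariate, a polymorphic dosage
    column 'g', and genuinely different group variances."""
    n1 = n2 = 400
    pc = np.concatenate([rng.normal(2, 1, n1), rng.normal(-2, 1, n2)])
    g = np.concatenate([rng.binomial(2, 0.1, n1), rng.binomial(2, 0.4, n2)]).astype(float)
    eps = np.concatenate([rng.normal(0, np.sqrt(3.0), n1), rng.normal(0, np.sqrt(1.5), n2)])
    y = np.r_[np.ones(n1), 2 * np.ones(n2)] + pc + eps
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n1 + n2)],
            "group_id": ["a"] * n1 + ["b"] * n2,
            "y": y,
            "pc": pc,
            "g": g,
        }
    )
    return CohortTable(df, dosage_cols=("g",))
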