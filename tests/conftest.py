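import numpy as np
import pandas as pd
import pytest

from idpn import (
    PipelineConfig,
    default_cohort_spec,
    generate_cohort,
    run_pipeline,
)
from idpn.features import FEATURE_NAMES, FLAG_COL, ID_COL, SEVERITY_COL


def make_feature_table(X, ids=None, flags=None, severities=None):
    """Wrap a respondents x 17 matrix in the canonical feature-table schema."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    table = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    table.insert(0, ID_COL, ids if ids is not None else [f"R{i:04d}" for i in range(n)])
    table[FLAG_COL] = flags if flags is not None else False
    table[SEVERITY_COL] = severities if severities is not None else 0
    return table


@pytest.fixture(scope="session")
def default_cohort():
    """One draw of the default two-subtype scenario."""
    return generate_cohort(default_cohort_spec(), seed=0)


@pytest.fixture(scope="session")
def default_pipeline(default_cohort):
    table, _ = default_cohort
    return run_pipeline(table, PipelineConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
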