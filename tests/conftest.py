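import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from jaderpv.terminology import load_drug_dictionary, load_event_dictionary

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def drug_dict():
    return load_drug_dictionary()


@pytest.fixture(scope="session")
def event_dict():
    return load_event_dictionary()


@pytest.fixture(scope="session")
def forty_row_design():
    """Fixed 40-row, two-predictor design for oracle comparisons.

    Every (x1, x2) pattern contains both outcome classes, so the
    likelihood has a unique interior maximum.
    """
    from jaderpv.logistic import DesignMatrix
    import pandas as pd

    x1 = [0] * 20 + [1] * 20
    x2 = [0, 1] * 20
    y = [0, 0, 1, 0, 0, 1, 0, 0, 0, 1,
         0, 1, 0, 0, 1, 0, 0, 0, 1, 0,
         1, 1, 0, 1, 1, 1, 0, 1, 1, 1,
         0, 1, 1, 1, 0, 1, 1, 0, 1, 1]
    X = DesignMatrix(np.array(y), pd.DataFrame({"x1": x1, "x2": x2}))
    return X
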