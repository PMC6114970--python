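import numpy as np
import pandas as pd
import pytest

import metabopanel as mp
from metabopanel.panel import SampleTable


@pytest.fixture(scope="session")
def schema():
    return mp.default_schema()


@pytest.fixture(scope="session")
def catalog(schema):
    return mp.build_default_catalog(schema)


@pytest.fixture(scope="session")
def gen_config():
    return mp.default_config()


@pytest.fixture(scope="session")
def case_control_table(gen_config):
    """Small synthetic exploratory-style cohort: 31 controls, 59 cases."""
    ctrl = mp.simulate_cohort(gen_config, "control", 31, seed=11)
    case = mp.simulate_cohort(gen_config, "case", 59, seed=12)
    return SampleTable(
        data=pd.concat([ctrl.data, case.data]),
        group=pd.concat([ctrl.group, case.group]),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
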