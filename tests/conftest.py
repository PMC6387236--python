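import numpy as np
import pytest

import seatpose as sp
from seatpose import datasets, simulate


@pytest.fixture(scope="session")
def schedule():
    return sp.default_schedule()


@pytest.fixture(scope="session")
def table_ti12():
    return datasets.cohort_ti1_ti2()


@pytest.fixture(scope="session")
def table_ti23():
    return datasets.cohort_ti2_ti3()


@pytest.fixture(scope="session")
def fixture_cohort(table_ti12, table_ti23):
    return simulate.generate_fixture_cohort(table_ti12, table_ti23)


@pytest.fixture(scope="session")
def noiseless_model():
    return sp.SensorModel.draw(np.random.default_rng(7)).noiseless()


@pytest.fixture()
def simple_model():
    return sp.SensorModel(
        v_zero=np.full(8, 3.0), v_maxload=np.full(8, 1.0), noise_sd=0.0
    )
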