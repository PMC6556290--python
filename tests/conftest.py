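import numpy as np
import pytest

from esccsim import (ModelParameters, default_bounds, default_life_table,
                     run_cohort)


@pytest.fixture(scope="session")
def table1():
    return ModelParameters.table1()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def table1_trajectory(table1, life_table):
    return run_cohort(table1, life_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_parameters(rng, n=1):
    """Parameter sets drawn uniformly from the calibration bounds."""
    bounds = default_bounds()
    base = ModelParameters.table1()
    vectors = bounds.sample(rng, n)
    return [base.with_vector(v, bounds.names) for v in vectors]
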