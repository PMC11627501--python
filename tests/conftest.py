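import numpy as np
import pandas as pd
import pytest

import xbrainage as xb


@pytest.fixture(scope="session")
def schema():
    return xb.build_default_schema()


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: full 260-feature schema, reduced sample sizes."""
    return xb.SimConfig(n_human=80, n_macaque=60, rng_seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return xb.simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """One study at the full cohort shape (370 humans, 181 macaques)."""
    return xb.simulate_study(xb.SimConfig(rng_seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def human_tables(default_study):
    cohort, features, behaviors, truth = default_study
    hum = cohort.index[cohort["species"] == "human"]
    return cohort.loc[hum], features.loc[hum], behaviors, truth


@pytest.fixture(scope="session")
def macaque_tables(default_study):
    cohort, features, _, truth = default_study
    mac = cohort.index[cohort["species"] == "macaque"]
    return cohort.loc[mac], features.loc[mac], truth
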