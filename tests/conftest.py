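import numpy as np
import pandas as pd
import pytest

import stresscombo as sc


@pytest.fixture(scope="session")
def default_pots() -> pd.DataFrame:
    """Raw pot table of the reference scenario (3x3x10, seed 7)."""
    return sc.simulate_raw_experiment(sc.default_scenario(seed=7))


@pytest.fixture(scope="session")
def trait_table(default_pots) -> pd.DataFrame:
    return sc.add_treatment_column(sc.derive_all(default_pots))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240524)
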