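import numpy as np
import pandas as pd
import pytest

from graftmatch import default_config, generate_registry, prematch_config


@pytest.fixture(scope="session")
def small_registry() -> pd.DataFrame:
    """Table-calibrated registry, 60 treated / 600 controls."""
    return generate_registry(default_config(n_treated=60, n_control=600, rng_seed=7))


@pytest.fixture(scope="session")
def medium_registry() -> pd.DataFrame:
    """Table-calibrated registry, 300 treated / 3000 controls."""
    return generate_registry(default_config(n_treated=300, n_control=3000, rng_seed=11))


@pytest.fixture(scope="session")
def imbalanced_registry() -> pd.DataFrame:
    """Raw pre-match preset: every matching covariate shifted between arms."""
    return generate_registry(prematch_config(n_treated=200, n_control=2000, rng_seed=13, missing_rate=0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
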