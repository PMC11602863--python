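import numpy as np
import pandas as pd
import pytest

from phsorb.io import DEFAULT_HERBICIDES
from phsorb.synthetic_data import DEFAULT_TRUTH, GeneratorConfig, generate_soils, simulate_kd


@pytest.fixture(scope="session")
def herbicides():
    return DEFAULT_HERBICIDES


@pytest.fixture(scope="session")
def soils18():
    """The default 18-sample (6 profiles x 3 horizons) synthetic soil set."""
    return generate_soils(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def kd_noise_free(soils18, herbicides):
    """Exact forward Kd values for every herbicide on the 18-soil set."""
    return {
        name: simulate_kd(soils18, herb, DEFAULT_TRUTH, noise_cv=0.0)
        for name, herb in herbicides.items()
    }


@pytest.fixture(scope="session")
def kd_noisy(soils18, herbicides):
    """Kd with 5% multiplicative noise, one independent stream per herbicide."""
    return {
        name: simulate_kd(soils18, herb, DEFAULT_TRUTH, noise_cv=0.05, seed=100 + i)
        for i, (name, herb) in enumerate(herbicides.items())
    }
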