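import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# reference parameter sets: one fitted-coefficient row per drying model at
# 80 C / 23 % initial moisture, used as generating values in recovery tests
DRYING_PARAMS_80C = {
    "newton": {"k": 0.4636},
    "page": {"k": 0.29353, "n": 1.61707},
    "page_modified": {"k": 0.46859, "n": 1.61707},
    "henderson_pabis": {"a": 1.06498, "k": 0.48895},
    "logarithmic": {"a": 11.1689, "k": 0.02482, "c": -10.1896},
    "two_terms": {"a": 0.532496, "k0": 0.498886, "b": 0.532496, "k1": 0.49886},
    "two_exponential_terms": {"a": 1.93807, "k": 0.72679},
    "wang_singh": {"a": -0.2849, "b": 0.002680},
    "henderson_pabis_modified": {
        "a": 0.354997, "k": 0.498886, "b": 0.354997,
        "k0": 0.198886, "c": 0.354997, "k1": 0.498886,
    },
    "midilli": {"a": 0.990558, "k": 0.023506, "n": 0.000019, "b": -0.264911},
    "diffusion_approximation": {"a": 0.54171, "k": 0.464301, "b": 1.0},
}

SHRINKAGE_PARAMS_80C = {
    "bala_woods": {"a": 0.94693, "b": -17.9467},
    "lang_sokhansanj": {"a": 2.31625, "beta1": 1.21561},
    "rahman": {"a": 0.27142, "beta2": 1.1723},
    "correa": {"a": 0.70713, "b": 1.05963},
    "line": {"a": 2.51031, "b": -1.16293},
    "exponential": {"a": 0.72095, "b": 1.21226},
}


@pytest.fixture
def time_grid():
    return np.arange(0.0, 2.51, 0.25)


@pytest.fixture
def moisture_grid():
    return np.linspace(0.23, 0.11, 12)
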