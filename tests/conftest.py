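import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: typical nuclear parameters used across the equilibrium studies
D_FIG2 = math.sqrt(50.0)
V_NUCLEUS = (1e3 / 0.34) ** 3  # 1 um^3 in bp^3


@pytest.fixture(scope="session")
def fig2_energy():
    from idrsearch.equilibrium import EnergyModel

    return EnergyModel(E_B=10.0, E_DBD=15.0, V1=1.0, V=V_NUCLEUS)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
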