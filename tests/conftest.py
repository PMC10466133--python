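import numpy as np
import pytest

from tcisim.pk import PKParameters
from tcisim.population import PopulationModel
from tcisim.scenarios import propofol_reference_population


@pytest.fixture(scope="session")
def ref_params() -> PKParameters:
    """Reference-adult propofol structural parameters."""
    return PKParameters(CL=2.10, V1=6.28, V2=25.5, V3=273.0, Q2=1.75, Q3=1.11, ke0=0.146)


@pytest.fixture(scope="session")
def ref_population() -> PopulationModel:
    return propofol_reference_population()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_pk_parameters(rng: np.random.Generator) -> PKParameters:
    """Physiologically plausible random parameter set (log-uniform ranges)."""
    lu = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return PKParameters(
        CL=lu(0.5, 4.0),
        V1=lu(2.0, 20.0),
        V2=lu(5.0, 60.0),
        V3=lu(50.0, 500.0),
        Q2=lu(0.5, 4.0),
        Q3=lu(0.3, 3.0),
        ke0=lu(0.05, 1.0),
    )
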