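import numpy as np
import pytest

from pulsetemp.geometry import (NumericsConfig, PhantomGeometry,
                                ProbeGeometry, standard_conditions)
from pulsetemp.mesh import build_phantom_mesh
from pulsetemp.phantom import run_treatment


@pytest.fixture(scope="session")
def probe():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def phantom():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def default_mesh(probe, phantom):
    return build_phantom_mesh(probe, phantom, NumericsConfig())


@pytest.fixture(scope="session")
def coarse_numerics():
    """Fast, coarse discretization for short unit-test simulations."""
    return NumericsConfig(fine_spacing=1e-3, coarse_spacing=4e-3)


@pytest.fixture(scope="session")
def test_traces(default_mesh, probe, phantom):
    """Noise-free default-grid traces of the four treatment groups."""
    return {name: run_treatment(cond, probe, phantom, NumericsConfig(),
                                mesh=default_mesh)
            for name, cond in standard_conditions().items()}
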