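import numpy as np
import pytest

from sorsq.spectra import WavenumberGrid, who_base
from sorsq.simulate import default_containers


@pytest.fixture(scope="session")
def grid():
    """Full-resolution instrument grid (1 cm^-1 spacing)."""
    return WavenumberGrid()


@pytest.fixture(scope="session")
def coarse_grid():
    """2 cm^-1 grid used where sub-grid accuracy is not under test."""
    return WavenumberGrid(200.0, 1800.0, 801)


@pytest.fixture(scope="session")
def containers():
    return default_containers()


@pytest.fixture(scope="session")
def container_map(containers):
    return {c.container_id: c for c in containers}


@pytest.fixture
def ethanol80():
    return who_base("ethanol")
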