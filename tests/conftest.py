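import pytest

from mhcapsim import ParameterSet

BASE_GRID = (50.0, 100.0, 150.0, 200.0, 250.0)


@pytest.fixture
def base_params() -> ParameterSet:
    """The base-case calibration: q0=60, delta_d=+27 (20-35), delta_c=30%
    (20%-40%), reference proxy 150 CAD/service."""
    return ParameterSet()


@pytest.fixture
def base_grid():
    return BASE_GRID
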