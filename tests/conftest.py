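import numpy as np
import pytest

from nfkbcoupling import (
    DelayScanSpec,
    ModelParameters,
    StimulusProgram,
    scan_combinatorial,
    scan_single_delay,
    simulate,
    steady_state,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def basal_state(params):
    return steady_state(params)


@pytest.fixture(scope="session")
def nominal_traj(params):
    """Calibrated TNF-step run at the nominal delays (120, 90) min."""
    return simulate(params, StimulusProgram(), 600.0, 1.0)


@pytest.fixture(scope="session")
def nominal_rise(nominal_traj):
    p52 = nominal_traj.value("p52")
    return float(p52[-1] - p52[0])


@pytest.fixture(scope="session")
def traf1_scan(params):
    """42-run TRAF1-axis scan (41 lattice points + nominal baseline)."""
    return scan_single_delay(params, DelayScanSpec(axes="traf1_only"))


@pytest.fixture(scope="session")
def nfkb2_scan(params):
    return scan_single_delay(params, DelayScanSpec(axes="nfkb2_only"))


@pytest.fixture(scope="session")
def combinatorial_scan(params):
    """Full 41 x 41 combinatorial scan (1681 runs)."""
    return scan_combinatorial(params, DelayScanSpec(axes="both"))


def per_species_rel_error(a: np.ndarray, b: np.ndarray) -> float:
    """Max |a-b| normalised by each species' own dynamic range in b."""
    scale = np.abs(b).max(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return float(np.max(np.abs(a - b) / scale))
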