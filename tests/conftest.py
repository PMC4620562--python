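import numpy as np
import pytest

from evbscan.evb_core import DiabaticSurface, EVBSystem, HarmonicWell, StiffnessProfile
from evbscan.sampling import SamplingProtocol
from evbscan.surrogate import build_packaged, packaged_fixtures


def harmonic_system(curvature=40.0, n_bath=2):
    """Effectively single-state reference system: degenerate wells, H12 = 0."""
    bath = StiffnessProfile(log_k0=np.log(30.0))
    states = (
        DiabaticSurface(HarmonicWell(curvature, 0.0), bath, alpha=0.0),
        DiabaticSurface(HarmonicWell(curvature, 0.0), bath, alpha=0.0),
    )
    return EVBSystem(states=states, coupling_h12=0.0, n_bath=n_bath)


@pytest.fixture(scope="session")
def fixtures_by_name():
    """All six packaged fixtures, built once per session."""
    return {fx.name: fx for fx in packaged_fixtures()}


@pytest.fixture(scope="session")
def oh_attack_ribosome(fixtures_by_name):
    return fixtures_by_name["oh_attack_ribosome"]


@pytest.fixture(scope="session")
def pt_water(fixtures_by_name):
    return fixtures_by_name["pt_water"]


@pytest.fixture(scope="session")
def short_protocol():
    """Reduced-length protocol for unit tests of the sampling machinery."""
    return SamplingProtocol(
        steps_sample_per_window=20_000,
        steps_equil_per_window=1_000,
        steps_post_heating=4_000,
        steps_per_heating_stage=1_000,
        seed=1234,
    )
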