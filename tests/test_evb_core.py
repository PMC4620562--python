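"""Unit and property tests of the two-state EVB energy model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evbscan.evb_core import (
    DiabaticSurface,
    EVBSystem,
    HarmonicWell,
    StiffnessProfile,
    ground_state_energy,
    ground_state_force,
    mapping_potential,
)

energies = st.floats(-50.0, 50.0)
couplings = st.floats(0.0, 20.0)


@pytest.mark.parametrize(
    "eps1, eps2, h12, expected",
    [
        (10.0, 10.0, 2.0, 8.0),      # degenerate states: E - H12
        (0.0, 20.0, 0.0, 0.0),       # zero coupling: min of the diabats
        (3.0, 7.0, 1.5, 2.5),        # hand evaluation: 5 - sqrt(16+9)/2
    ],
)
def test_ground_state_energy_closed_form(eps1, eps2, h12, expected):
    assert ground_state_energy(eps1, eps2, h12) == pytest.approx(expected, abs=1e-12)


@given(eps1=energies, eps2=energies, h12=couplings)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_ground_state_matches_eigensolver_and_is_symmetric(eps1, eps2, h12):
    """The closed form equals the lowest eigenvalue of [[e1, h], [h, e2]]."""
    ref = float(np.linalg.eigvalsh(np.array([[eps1, h12], [h12, eps2]]))[0])
    val = ground_state_energy(eps1, eps2, h12)
    assert val == pytest.approx(ref, abs=1e-9)
    assert val == pytest.approx(ground_state_energy(eps2, eps1, h12), abs=1e-12)
    assert val <= min(eps1, eps2) + 1e-12


@given(eps1=energies, eps2=energies, h1=couplings, h2=couplings)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_ground_state_monotone_nonincreasing_in_coupling(eps1, eps2, h1, h2):
    lo, hi = sorted((h1, h2))
    assert ground_state_energy(eps1, eps2, hi) <= ground_state_energy(eps1, eps2, lo) + 1e-12


def test_ground_state_rejects_bad_input():
    with pytest.raises(ValueError):
        ground_state_energy(np.nan, 1.0, 0.5)
    with pytest.raises(ValueError):
        ground_state_energy(1.0, 1.0, -0.1)


@pytest.mark.parametrize(
    "lam, expected", [(0.0, 2.0), (1.0, 6.0), (0.5, 4.0)]
)
def test_mapping_potential_endpoints_and_midpoint(lam, expected):
    assert mapping_potential(2.0, 6.0, lam) == expected


def test_mapping_potential_rejects_lambda_outside_unit_interval():
    with pytest.raises(ValueError):
        mapping_potential(0.0, 1.0, -0.01)
    with pytest.raises(ValueError):
        mapping_potential(0.0, 1.0, 1.01)


def _toy_system(h12=3.0, alpha=1.5, n_bath=2, g_ts=-0.4):
    bath = StiffnessProfile(log_k0=np.log(30.0), nodes_g=(0.0, g_ts, 0.1))
    states = (
        DiabaticSurface(HarmonicWell(40.0, -1.0), bath, alpha=0.0),
        DiabaticSurface(HarmonicWell(40.0, 1.0), bath, alpha=alpha),
    )
    return EVBSystem(states=states, coupling_h12=h12, n_bath=n_bath)


def test_force_matches_central_difference():
    system = _toy_system()
    rng = np.random.default_rng(7)
    h = 1e-5
    for _ in range(20):
        coords = np.concatenate([rng.uniform(-1.5, 1.5, 1), rng.normal(0, 0.2, 2)])
        force = ground_state_force(system, coords)
        for i in range(len(coords)):
            up, dn = coords.copy(), coords.copy()
            up[i] += h
            dn[i] -= h
            def energy(c):
                e1, e2 = system.diabatic_energies(c[0])
                from evbscan.evb_core import ground_state_energy as g
                return g(e1, e2, system.coupling_h12) + system.bath_energy(c[0], c[1:])
            fd = -(energy(up) - energy(dn)) / (2 * h)
            assert force[i] == pytest.approx(fd, abs=1e-6)


def test_force_zero_coupling_follows_lower_diabat():
    system = _toy_system(h12=0.0, alpha=30.0, n_bath=0)
    x = -0.8  # state 1 strictly lower here
    force = ground_state_force(system, np.array([x]))
    assert force[0] == pytest.approx(-system.states[0].solute_gradient(x), abs=1e-10)


def test_force_vanishes_at_symmetric_crossing():
    system = _toy_system(alpha=0.0, n_bath=0)
    force = ground_state_force(system, np.array([0.0]))
    assert force[0] == pytest.approx(0.0, abs=1e-10)


def test_force_rejects_out_of_domain():
    system = _toy_system()
    with pytest.raises(ValueError):
        ground_state_force(system, np.array([5.0, 0.0, 0.0]))


def test_yaml_round_trip_lossless(tmp_path):
    system = _toy_system(h12=np.pi, alpha=1 / 3)
    path = tmp_path / "system.yaml"
    system.to_yaml(path)
    back = EVBSystem.from_yaml(path)
    assert back.coupling_h12 == pytest.approx(system.coupling_h12, rel=1e-12)
    assert back.states[1].alpha == pytest.approx(system.states[1].alpha, rel=1e-12)
    grid = np.linspace(-2, 2, 41)
    np.testing.assert_allclose(back.ground_energy(grid), system.ground_energy(grid), rtol=1e-12)


def test_system_validation():
    bath1 = StiffnessProfile(log_k0=1.0)
    bath2 = StiffnessProfile(log_k0=2.0)
    s1 = DiabaticSurface(HarmonicWell(40.0, -1.0), bath1)
    s2 = DiabaticSurface(HarmonicWell(40.0, 1.0), bath2)
    with pytest.raises(ValueError, match="shared"):
        EVBSystem(states=(s1, s2), coupling_h12=1.0, n_bath=2)
    with pytest.raises(ValueError, match="h12"):
        EVBSystem(states=(s1, DiabaticSurface(HarmonicWell(40.0, 1.0), bath1)), coupling_h12=-1.0)
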