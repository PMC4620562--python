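"""Boltzmann fidelity and determinism of the Langevin/FEP sampler."""

import numpy as np
import pytest
from scipy import stats

from evbscan.constants import KB
from evbscan.evb_core import DiabaticSurface, EVBSystem, HarmonicWell, StiffnessProfile
from evbscan.oracle import mapping_density
from evbscan.sampling import (
    SamplingProtocol,
    equilibrate,
    initialize_velocities,
    run_fep_windows,
)


from conftest import harmonic_system as _harmonic_system


def test_maxwell_velocities_satisfy_equipartition():
    """1e5 draws at 300 K, m=1: mean KE per dof = 0.5 kB T within 1%."""
    v = initialize_velocities(np.ones(100_000), 300.0, seed=5)
    ke = 0.5 * np.mean(v**2)
    assert ke == pytest.approx(0.5 * KB * 300.0, rel=0.01)


def test_maxwell_velocities_deterministic_and_scaled():
    a = initialize_velocities(np.ones(64), 300.0, seed=9)
    b = initialize_velocities(np.ones(64), 300.0, seed=9)
    np.testing.assert_array_equal(a, b)
    cold = initialize_velocities(np.ones(64), 1.0, seed=9)
    np.testing.assert_allclose(cold, a / np.sqrt(300.0), rtol=1e-12)
    with pytest.raises(ValueError):
        initialize_velocities(np.ones(4), -5.0, seed=0)
    with pytest.raises(ValueError):
        initialize_velocities(np.zeros(4), 300.0, seed=0)


def test_equilibrated_harmonic_variance_matches_gaussian(short_protocol):
    """Post-equilibration sampling of a harmonic well: var(x) = kB T / k."""
    system = _harmonic_system(curvature=40.0)
    state = equilibrate(system, short_protocol, 300.0, replicate_id=0)
    windows = run_fep_windows(system, short_protocol, 300.0, 0, state=state)
    xs = np.concatenate([w.x for w in windows])  # all windows identical here
    # ~4e4 samples at ~10 strides per correlation time: sd(var)/var ~ 3%
    assert np.var(xs) == pytest.approx(KB * 300.0 / 40.0, rel=0.09)
    assert len(xs) >= 10_000


def test_window_sampling_matches_quadrature_marginal(oh_attack_ribosome, short_protocol):
    """KS test of the sampled x-marginal against the exact mapping density.

    Checked at the endpoints and the central window; samples are thinned to
    roughly independent points before the test.
    """
    system = oh_attack_ribosome.system
    windows = run_fep_windows(system, short_protocol, 300.0, 3)
    for m in (0, 10, 20):
        w = windows[m]
        xs_grid, _, cdf = mapping_density(system, w.lam, 300.0)
        thin = w.x[::10]  # stride 10 already; ~1 correlation time apart x10
        def cdf_fn(v):
            return np.interp(v, xs_grid, cdf)
        res = stats.ks_1samp(thin, cdf_fn)
        assert res.pvalue > 0.01, f"window {m}: KS p = {res.pvalue}"


def test_two_replicates_same_stationary_distribution(oh_attack_ribosome, short_protocol):
    system = oh_attack_ribosome.system
    w0 = run_fep_windows(system, short_protocol, 300.0, 0)[0]
    w1 = run_fep_windows(system, short_protocol, 300.0, 1)[0]
    assert not np.array_equal(w0.x, w1.x)  # different trajectories
    res = stats.ks_2samp(w0.x[::10], w1.x[::10])
    assert res.pvalue > 0.01


def test_window_count_and_bitwise_determinism(oh_attack_ribosome, short_protocol):
    system = oh_attack_ribosome.system
    a = run_fep_windows(system, short_protocol, 295.0, 2)
    b = run_fep_windows(system, short_protocol, 295.0, 2)
    assert len(a) == short_protocol.n_windows == 21
    for wa, wb in zip(a, b):
        np.testing.assert_array_equal(wa.x, wb.x)
        np.testing.assert_array_equal(wa.e_ground, wb.e_ground)
    assert a[0].seed_used == b[0].seed_used


def test_mean_potential_energy_matches_quadrature(oh_attack_ribosome, short_protocol):
    """Long-run mean mapping energy agrees with the quadrature average."""
    system = oh_attack_ribosome.system
    w = run_fep_windows(system, short_protocol, 300.0, 5)[10]
    xs, pdf, _ = mapping_density(system, w.lam, 300.0)
    e1, e2 = system.diabatic_energies(xs)
    u = (1.0 - w.lam) * e1 + w.lam * e2
    # solute part only: subtract the bath energy implied by equipartition
    u_mean_expected = np.trapezoid(u * pdf, xs)
    bath_mean = 0.5 * system.n_bath * KB * 300.0  # harmonic bath potential energy
    u_sampled = np.mean(w.e_map) - bath_mean
    # the bath contributes sd ~ kT sqrt(n/2) ~ 1.5 kcal/mol per sample;
    # with ~200 effective samples the mean carries ~0.1, so allow ~3 sigma
    assert u_sampled == pytest.approx(u_mean_expected, abs=0.35)


def test_heating_schedule_ends_at_target_with_released_restraint():
    proto = SamplingProtocol()
    schedule = proto.heating_schedule(305.0)
    assert schedule[0][0] == 1.0
    assert schedule[-1] == (305.0, 0.0)  # fully released at the final stage
    assert len(schedule) == proto.heating_stages


def test_unstable_time_step_is_rejected(oh_attack_ribosome):
    proto = SamplingProtocol(dt=0.2)
    with pytest.raises(ValueError, match="unstable"):
        proto.validate_for(oh_attack_ribosome.system)
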