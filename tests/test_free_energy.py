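"""Tests of FEP increments, profile assembly, and replicate statistics."""

import numpy as np
import pytest

from evbscan._extrema import NoBarrierError
from evbscan.free_energy import (
    BarrierResult,
    FreeEnergyProfile,
    assemble_profile,
    average_replicates,
    barrier_and_reaction,
    fep_chain,
    fep_increment,
)
from evbscan.oracle import exact_barrier, exact_pmf
from evbscan.sampling import WindowSamples, run_fep_windows


@pytest.fixture(scope="module")
def ribosome_windows(oh_attack_ribosome, short_protocol):
    return run_fep_windows(oh_attack_ribosome.system, short_protocol, 300.0, 0)


def _toy_window(lam, eps1, eps2, temperature=300.0):
    eps1 = np.asarray(eps1, float)
    eps2 = np.asarray(eps2, float)
    return WindowSamples(
        lam=lam, temperature=temperature, replicate_id=0, seed_used=0,
        x=np.zeros_like(eps1), eps1=eps1, eps2=eps2,
        e_ground=np.minimum(eps1, eps2),
        e_map=(1 - lam) * eps1 + lam * eps2,
    )


def test_identity_perturbation_is_exactly_zero():
    w = _toy_window(0.3, [1.0, 5.0, -2.0], [4.0, 0.0, 3.0])
    assert fep_increment(w, 0.3) == 0.0


def test_increment_guards_against_overflow():
    w = _toy_window(0.0, [0.0, 0.0], [5000.0, 5000.0])
    val = fep_increment(w, 1.0)
    assert np.isfinite(val)
    assert val == pytest.approx(5000.0, rel=1e-9)


def test_fep_sum_matches_closed_form_free_energy(oh_attack_ribosome, short_protocol):
    """The chained FEP estimate of dF(state 1 -> state 2) has a closed form.

    For equal-curvature diabats the two endpoint partition functions are
    identical Gaussians, so dF is exactly the offset difference
    (alpha2 + well-2 offset) - (alpha1 + well-1 offset); the bath cancels.
    """
    system = oh_attack_ribosome.system
    s1, s2 = system.states
    exact = (s2.solute.offset + s2.alpha) - (s1.solute.offset + s1.alpha)
    windows = run_fep_windows(system, short_protocol, 300.0, 7)
    total = fep_chain(windows)[-1]
    assert total == pytest.approx(exact, abs=0.1)


def test_forward_reverse_cycle_closure(ribosome_windows):
    fwd = fep_chain(ribosome_windows, direction="forward")
    rev = fep_chain(ribosome_windows, direction="reverse")
    # short sampling: generous but bounded estimator discrepancy
    assert abs(fwd[-1] - rev[-1]) < 0.6
    bid = fep_chain(ribosome_windows)
    assert np.allclose(bid, 0.5 * (fwd + rev))


def test_profile_matches_oracle_pmf_on_populated_bins(oh_attack_ribosome, short_protocol):
    """Sampled profile vs exact gap-space PMF, bin-wise, where counts >= 50."""
    system = oh_attack_ribosome.system
    reps = []
    for rep in range(3):
        windows = run_fep_windows(system, short_protocol, 300.0, rep)
        reps.append(assemble_profile(windows))
    op = exact_pmf(system, 300.0, 4001)
    order = np.argsort(op.gap)
    for prof in reps:
        mask = prof.usable & (prof.counts >= 50)
        oracle = np.interp(prof.bin_centers[mask], op.gap[order], op.pmf_gap[order])
        diff = prof.dG[mask] - oracle
        diff -= diff.mean()  # anchors differ by a constant
        # replicate-level noise at this sampling length is ~0.05-0.1 kcal/mol
        assert np.max(np.abs(diff)) < 0.45


def test_profile_error_decreases_with_sampling_length(oh_attack_ribosome, short_protocol):
    """Convergence toward the oracle as steps/window grow (two lengths)."""
    from dataclasses import replace

    system = oh_attack_ribosome.system
    op = exact_pmf(system, 300.0, 4001)
    order = np.argsort(op.gap)

    def rms_error(protocol, reps=2):
        errs = []
        for rep in range(reps):
            prof = assemble_profile(run_fep_windows(system, protocol, 300.0, rep))
            mask = prof.usable & (prof.counts >= 50)
            oracle = np.interp(prof.bin_centers[mask], op.gap[order], op.pmf_gap[order])
            diff = prof.dG[mask] - oracle
            errs.append(np.sqrt(np.mean((diff - diff.mean()) ** 2)))
        return np.mean(errs)

    short = replace(short_protocol, steps_sample_per_window=4_000)
    longer = replace(short_protocol, steps_sample_per_window=40_000)
    assert rms_error(longer) < rms_error(short)


def test_assembled_profile_invariant_under_diabat_shift(oh_attack_ribosome, short_protocol):
    """Shifting both diabats by a constant moves nothing physical."""
    system = oh_attack_ribosome.system
    windows = run_fep_windows(system, short_protocol, 300.0, 1)
    shifted = [
        WindowSamples(
            lam=w.lam, temperature=w.temperature, replicate_id=w.replicate_id,
            seed_used=w.seed_used, x=w.x,
            eps1=w.eps1 + 13.0, eps2=w.eps2 + 13.0,
            e_ground=w.e_ground + 13.0, e_map=w.e_map + 13.0,
        )
        for w in windows
    ]
    b1 = barrier_and_reaction(assemble_profile(windows))
    b2 = barrier_and_reaction(assemble_profile(shifted))
    assert b2.dG_act == pytest.approx(b1.dG_act, abs=1e-9)
    assert b2.dG_rxn == pytest.approx(b1.dG_rxn, abs=1e-9)


def test_single_state_profile_is_flat_and_barrierless(short_protocol):
    from conftest import harmonic_system

    system = harmonic_system()
    windows = run_fep_windows(system, short_protocol, 300.0, 0)
    with pytest.raises((NoBarrierError, ValueError)):
        barrier_and_reaction(assemble_profile(windows))


def test_symmetric_fixture_reaction_free_energy_near_zero(short_protocol):
    """Mirror-image diabats (dG_rxn target 0): |dG0| within noise."""
    from evbscan.surrogate import FixtureTargets, build_fixture

    fx = build_fixture(FixtureTargets(dG_act=10.0, TdS_act=0.0, dG_rxn=0.0), n_bath=4)
    results = [
        barrier_and_reaction(
            assemble_profile(run_fep_windows(fx.system, short_protocol, 300.0, rep))
        )
        for rep in range(3)
    ]
    row = average_replicates(results).table.iloc[0]
    # noise floor guards against a zero-sem fluke at short sampling
    assert abs(row.dG_rxn_mean) <= max(2 * row.dG_rxn_sem, 0.1)


def test_barrier_extraction_from_hand_built_profile():
    centers = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    dG = np.array([0.0, 5.0, 27.0, 10.0, 3.0])
    prof = FreeEnergyProfile(
        bin_centers=centers, dG=dG, counts=np.full(5, 100),
        usable=np.ones(5, bool), temperature=300.0,
    )
    bar = barrier_and_reaction(prof)
    assert bar.dG_act == pytest.approx(27.0, abs=1.5)  # coarse bins
    assert bar.dG_rxn == pytest.approx(3.0, abs=1.0)
    assert bar.X_reactant < bar.X_ts < bar.X_product


def test_flat_profile_raises_no_barrier():
    prof = FreeEnergyProfile(
        bin_centers=np.linspace(-1, 1, 9), dG=np.zeros(9),
        counts=np.full(9, 100), usable=np.ones(9, bool), temperature=300.0,
    )
    with pytest.raises(NoBarrierError):
        barrier_and_reaction(prof)


def test_average_replicates_statistics():
    def res(T, dG):
        return BarrierResult(dG, 0.0, -1.0, 0.0, 1.0, temperature=T)

    scan = average_replicates(
        [res(300.0, 10.0), res(300.0, 11.0), res(300.0, 12.0),
         res(310.0, 9.0), res(310.0, 9.0)]
    )
    row = scan.table.set_index("temperature")
    assert row.loc[300.0, "dG_act_mean"] == pytest.approx(11.0)
    assert row.loc[300.0, "dG_act_sem"] == pytest.approx(1.0 / np.sqrt(3))
    assert row.loc[310.0, "dG_act_sem"] == 0.0
    with pytest.raises(ValueError, match="2 replicates"):
        average_replicates([res(300.0, 10.0)])
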