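"""Compiled BAOAB Langevin integrator for the surrogate EVB systems.

The force field is the package's fixed surrogate form -- two equal-curvature
harmonic diabats mixed by a constant coupling, plus harmonic bath modes whose
stiffness follows a three-node quintic-smoothstep log profile -- so the
integrator can be specialized and jitted.  The BAOAB splitting gives the
correct stationary (Boltzmann) distribution for any stable time step, which
is the only property the free-energy pipeline relies on.

Solute parameters are packed as
    sol = [curvature, center1, off1, center2, off2, h12]
(offN = solute offset + gas-phase shift of state N) and the bath profile as
    bath = [log_k0, x_r, x_ts, x_p, g_r, g_ts, g_p].
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pack_params", "run_segment"]


def pack_params(system) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Pack an EVBSystem into the flat arrays the kernel consumes."""
    s1, s2 = system.states
    if s1.solute.curvature != s2.solute.curvature:
        raise ValueError("kernel requires equal diabat curvatures")
    sol = np.array(
        [
            s1.solute.curvature,
            s1.solute.center,
            s1.solute.offset + s1.alpha,
            s2.solute.center,
            s2.solute.offset + s2.alpha,
            system.coupling_h12,
        ],
        dtype=np.float64,
    )
    bs = system.bath_stiffness
    bath = np.array(
        [bs.log_k0, *bs.nodes_x, *bs.nodes_g], dtype=np.float64
    )
    masses = np.asarray(system.masses, dtype=np.float64)
    return sol, bath, int(system.n_bath), masses


@njit(cache=True, inline="always")
def _stiffness(x, bath):
    """k(x) and dk/dx for the three-node log-smoothstep profile."""
    log_k0 = bath[0]
    xr, xt, xp = bath[1], bath[2], bath[3]
    gr, gt, gp = bath[4], bath[5], bath[6]
    if x <= xr:
        g = gr
        dg = 0.0
    elif x >= xp:
        g = gp
        dg = 0.0
    elif x < xt:
        t = (x - xr) / (xt - xr)
        s = t * t * t * (10.0 + t * (-15.0 + 6.0 * t))
        ds = 30.0 * t * t * (1.0 - t) * (1.0 - t) / (xt - xr)
        g = gr + (gt - gr) * s
        dg = (gt - gr) * ds
    else:
        t = (x - xt) / (xp - xt)
        s = t * t * t * (10.0 + t * (-15.0 + 6.0 * t))
        ds = 30.0 * t * t * (1.0 - t) * (1.0 - t) / (xp - xt)
        g = gt + (gp - gt) * s
        dg = (gp - gt) * ds
    k = np.exp(log_k0 + g)
    return k, k * dg


@njit(cache=True, inline="always")
def _solute_forces(x, lam, sol):
    """Mapping-potential solute force and the diabatic energies at x."""
    a = sol[0]
    d1 = x - sol[1]
    d2 = x - sol[3]
    e1 = 0.5 * a * d1 * d1 + sol[2]
    e2 = 0.5 * a * d2 * d2 + sol[4]
    grad = (1.0 - lam) * a * d1 + lam * a * d2
    return -grad, e1, e2


@njit(cache=True)
def run_segment(
    x0,
    y0,
    v0,
    n_steps,
    stride,
    dt,
    friction,
    kT,
    lam,
    sol,
    bath,
    masses,
    restraint_k,
    restraint_x0,
    seed,
    record,
):
    """Advance one Langevin segment on the mapping potential at ``lam``.

    Returns the final phase-space state plus (when ``record``) samples taken
    every ``stride`` steps: solute coordinate, the two diabatic energies, the
    EVB ground-state energy, and the mapping energy (all including the bath
    and any restraint-free; energies in kcal/mol).  Reseeds the module RNG
    from ``seed`` so every segment is independently reproducible.
    """
    np.random.seed(seed)
    n_bath = y0.shape[0]
    h12 = sol[5]
    x = x0
    y = y0.copy()
    v = v0.copy()
    n_rec = n_steps // stride if record else 0
    xs = np.empty(n_rec)
    e1s = np.empty(n_rec)
    e2s = np.empty(n_rec)
    egs = np.empty(n_rec)
    ems = np.empty(n_rec)

    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    half_dt = 0.5 * dt

    # initial forces
    fx, e1, e2 = _solute_forces(x, lam, sol)
    k, dk = _stiffness(x, bath)
    sy2 = 0.0
    for j in range(n_bath):
        sy2 += y[j] * y[j]
    fx -= 0.5 * dk * sy2 + restraint_k * (x - restraint_x0)

    irec = 0
    for step in range(n_steps):
        # B: half kick
        v[0] += half_dt * fx / masses[0]
        for j in range(n_bath):
            v[1 + j] += half_dt * (-k * y[j]) / masses[1 + j]
        # A: half drift
        x += half_dt * v[0]
        for j in range(n_bath):
            y[j] += half_dt * v[1 + j]
        # O: Ornstein-Uhlenbeck
        v[0] = c1 * v[0] + c2 * np.sqrt(kT / masses[0]) * np.random.normal()
        for j in range(n_bath):
            v[1 + j] = c1 * v[1 + j] + c2 * np.sqrt(kT / masses[1 + j]) * np.random.normal()
        # A: half drift
        x += half_dt * v[0]
        for j in range(n_bath):
            y[j] += half_dt * v[1 + j]
        # B: half kick with fresh forces
        fx, e1, e2 = _solute_forces(x, lam, sol)
        k, dk = _stiffness(x, bath)
        sy2 = 0.0
        for j in range(n_bath):
            sy2 += y[j] * y[j]
        fx -= 0.5 * dk * sy2 + restraint_k * (x - restraint_x0)
        v[0] += half_dt * fx / masses[0]
        for j in range(n_bath):
            v[1 + j] += half_dt * (-k * y[j]) / masses[1 + j]

        if not np.isfinite(x) or not np.isfinite(e1) or not np.isfinite(e2):
            return x, y, v, xs[:irec], e1s[:irec], e2s[:irec], egs[:irec], ems[:irec], step + 1

        if record and (step + 1) % stride == 0:
            e_bath = 0.5 * k * sy2
            gap = e1 - e2
            eg = 0.5 * (e1 + e2) - 0.5 * np.sqrt(gap * gap + 4.0 * h12 * h12)
            xs[irec] = x
            e1s[irec] = e1 + e_bath
            e2s[irec] = e2 + e_bath
            egs[irec] = eg + e_bath
            ems[irec] = (1.0 - lam) * e1 + lam * e2 + e_bath
            irec += 1

    return x, y, v, xs, e1s, e2s, egs, ems, 0
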