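"""Two-state empirical valence bond (EVB) energy model.

A reaction step is described by two diabatic states -- a reactant-like and a
product-like bonding pattern -- each a smooth potential over a single solute
coordinate ``x`` plus a set of harmonic bath modes whose stiffness ``k(x)``
depends on the solute coordinate only.  The states are mixed by a constant
off-diagonal coupling ``H12``; the adiabatic ground state is the lowest
eigenvalue of the 2x2 EVB Hamiltonian,

    E_g = (eps1 + eps2)/2 - sqrt((eps1 - eps2)^2 + 4 H12^2)/2 .

The energy gap ``X = eps1 - eps2`` serves as the generalized reaction
coordinate.  Free-energy profiles are driven between the states by mapping
potentials ``eps_lam = (1 - lam) eps1 + lam eps2``.

Solute potentials are harmonic wells with a *common* curvature for the two
states.  This choice makes the gap X(x) exactly linear (hence strictly
monotone) in x and every mapping potential single-welled, which is what the
surrogate fixtures rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import yaml

from .constants import KB

__all__ = [
    "HarmonicWell",
    "StiffnessProfile",
    "DiabaticSurface",
    "EVBSystem",
    "GapSample",
    "ground_state_energy",
    "ground_state_weights",
    "ground_state_force",
    "mapping_potential",
]


def _check_finite(name: str, *values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name}: non-finite input {v!r}")


def ground_state_energy(eps1, eps2, h12):
    """Lowest eigenvalue of the 2x2 EVB Hamiltonian (kcal/mol).

    Symmetric under swapping ``eps1``/``eps2``; reduces to ``min(eps1, eps2)``
    for vanishing coupling and to ``eps - h12`` for degenerate states.
    """
    _check_finite("ground_state_energy", eps1, eps2, h12)
    if np.any(np.asarray(h12) < 0):
        raise ValueError(f"coupling h12 must be >= 0, got {h12}")
    eps1 = np.asarray(eps1, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    gap = eps1 - eps2
    out = 0.5 * (eps1 + eps2) - 0.5 * np.sqrt(gap * gap + 4.0 * h12 * h12)
    return out if out.ndim else float(out)


def ground_state_weights(eps1, eps2, h12):
    """Diabatic mixing weights (w1, w2) of the ground state, w1 + w2 = 1.

    These are dE_g/d eps_i, the Hellmann-Feynman weights used to assemble
    forces on the adiabatic surface.
    """
    eps1 = np.asarray(eps1, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    gap = eps1 - eps2
    root = np.sqrt(gap * gap + 4.0 * h12 * h12)
    with np.errstate(invalid="ignore"):
        ratio = np.where(root > 0, gap / root, 0.0)
    w1 = 0.5 * (1.0 - ratio)
    return w1, 1.0 - w1


def mapping_potential(eps1, eps2, lam):
    """FEP mapping potential (1 - lam) * eps1 + lam * eps2."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0.0) or np.any(lam_arr > 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = (1.0 - lam_arr) * np.asarray(eps1, float) + lam_arr * np.asarray(eps2, float)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HarmonicWell:
    """Solute potential 0.5 * curvature * (x - center)^2 + offset."""

    curvature: float
    center: float
    offset: float = 0.0

    def __post_init__(self):
        if self.curvature <= 0:
            raise ValueError(f"curvature must be positive, got {self.curvature}")

    def energy(self, x):
        d = np.asarray(x, float) - self.center
        return 0.5 * self.curvature * d * d + self.offset

    def gradient(self, x):
        return self.curvature * (np.asarray(x, float) - self.center)


def _smoothstep(t):
    """Quintic smoothstep: S(0)=0, S(1)=1, S'=S''=0 at both ends."""
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (10.0 + t * (-15.0 + 6.0 * t))


def _smoothstep_deriv(t):
    inside = (t > 0.0) & (t < 1.0)
    tc = np.clip(t, 0.0, 1.0)
    return np.where(inside, 30.0 * tc * tc * (1.0 - tc) ** 2, 0.0)


@dataclass(frozen=True)
class StiffnessProfile:
    """Bath-mode stiffness k(x) = exp(log_k0 + g(x)), in kcal mol^-1 Å^-2.

    ``g(x)`` interpolates between plateau values at three nodes (reactant,
    barrier, product regions) with quintic smoothsteps, so ``g'`` vanishes
    exactly at every node and k(x) > 0 everywhere.  The log-space plateau
    differences set the bath entropy change between the regions:
    a softer barrier region (g_ts < g_r) gives a positive activation entropy.
    """

    log_k0: float
    nodes_x: tuple[float, float, float] = (-1.0, 0.0, 1.0)
    nodes_g: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        xr, xt, xp = self.nodes_x
        if not (xr < xt < xp):
            raise ValueError(f"stiffness nodes must be ordered, got {self.nodes_x}")

    def log_k(self, x):
        x = np.asarray(x, dtype=float)
        xr, xt, xp = self.nodes_x
        gr, gt, gp = self.nodes_g
        g = np.where(x <= xr, gr, np.where(x >= xp, gp, 0.0))
        left = (x > xr) & (x < xt)
        right = (x >= xt) & (x < xp)
        t1 = (x - xr) / (xt - xr)
        t2 = (x - xt) / (xp - xt)
        g = np.where(left, gr + (gt - gr) * _smoothstep(t1), g)
        g = np.where(right, gt + (gp - gt) * _smoothstep(t2), g)
        out = self.log_k0 + g
        return out if out.ndim else float(out)

    def k(self, x):
        return np.exp(self.log_k(x))

    def dk_dx(self, x):
        x = np.asarray(x, dtype=float)
        xr, xt, xp = self.nodes_x
        gr, gt, gp = self.nodes_g
        dg = np.zeros_like(x)
        left = (x > xr) & (x < xt)
        right = (x >= xt) & (x < xp)
        t1 = (x - xr) / (xt - xr)
        t2 = (x - xt) / (xp - xt)
        dg = np.where(left, (gt - gr) * _smoothstep_deriv(t1) / (xt - xr), dg)
        dg = np.where(right, (gp - gt) * _smoothstep_deriv(t2) / (xp - xt), dg)
        out = self.k(x) * dg
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class DiabaticSurface:
    """One EVB diabatic state: solute well + shared bath stiffness + shift.

    ``alpha`` is the gas-phase shift of this state (kcal/mol), the free
    calibration parameter that positions the state relative to its partner.
    """

    solute: HarmonicWell
    bath_stiffness: StiffnessProfile
    alpha: float = 0.0

    def solute_energy(self, x):
        """Diabatic solute energy including the gas-phase shift."""
        return self.solute.energy(x) + self.alpha

    def solute_gradient(self, x):
        return self.solute.gradient(x)


class GapSample(NamedTuple):
    """One recorded configuration on a mapping potential."""

    eps1: float
    eps2: float
    e_ground: float
    e_map: float
    x: float

    @property
    def gap(self) -> float:
        return self.eps1 - self.eps2


@dataclass(frozen=True)
class EVBSystem:
    """Two diabatic states, constant coupling, and a separable harmonic bath.

    The bath stiffness profile must be identical in the two states -- it
    depends on the solute coordinate only -- which keeps the bath integral
    separable given x and the exact thermodynamics closed-form.
    """

    states: tuple[DiabaticSurface, DiabaticSurface]
    coupling_h12: float
    n_bath: int = 0
    masses: tuple[float, ...] | None = None
    domain: tuple[float, float] = (-2.5, 2.5)

    def __post_init__(self):
        if len(self.states) != 2:
            raise ValueError("exactly two diabatic states are required")
        if self.coupling_h12 < 0:
            raise ValueError(f"coupling_h12 must be >= 0, got {self.coupling_h12}")
        if self.n_bath < 0:
            raise ValueError(f"n_bath must be >= 0, got {self.n_bath}")
        if self.states[0].bath_stiffness != self.states[1].bath_stiffness:
            raise ValueError("bath stiffness must be shared by the two states")
        if self.domain[0] >= self.domain[1]:
            raise ValueError(f"invalid domain {self.domain}")
        if self.masses is None:
            object.__setattr__(self, "masses", (1.0,) * (1 + self.n_bath))
        if len(self.masses) != 1 + self.n_bath:
            raise ValueError(
                f"need {1 + self.n_bath} masses (solute + bath), got {len(self.masses)}"
            )
        if any(m <= 0 for m in self.masses):
            raise ValueError("masses must be positive")
        # bath stiffness positive over the domain (exp form guarantees it,
        # but guard against degenerate parameters)
        grid = np.linspace(*self.domain, 257)
        if not np.all(self.bath_stiffness.k(grid) > 0):
            raise ValueError("bath stiffness must be positive over the domain")

    # -- energies -----------------------------------------------------------

    @property
    def bath_stiffness(self) -> StiffnessProfile:
        return self.states[0].bath_stiffness

    def diabatic_energies(self, x):
        """Solute-level diabatic energies (eps1, eps2) at x."""
        return self.states[0].solute_energy(x), self.states[1].solute_energy(x)

    def gap(self, x):
        e1, e2 = self.diabatic_energies(x)
        return e1 - e2

    def gap_derivative(self, x):
        return self.states[0].solute_gradient(x) - self.states[1].solute_gradient(x)

    def ground_energy(self, x):
        """Adiabatic solute ground-state energy at x (bath excluded)."""
        e1, e2 = self.diabatic_energies(x)
        return ground_state_energy(e1, e2, self.coupling_h12)

    def bath_energy(self, x, y):
        y = np.asarray(y, dtype=float)
        return 0.5 * self.bath_stiffness.k(x) * float(np.dot(y, y))

    def max_frequency(self) -> float:
        """Largest harmonic frequency over the domain (for dt stability)."""
        grid = np.linspace(*self.domain, 513)
        k_max = float(np.max(self.bath_stiffness.k(grid)))
        a_max = max(s.solute.curvature for s in self.states)
        m_min = min(self.masses)
        return float(np.sqrt(max(k_max, a_max) / m_min))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def surf(s: DiabaticSurface) -> dict:
            return {
                "solute": {
                    "curvature": float(s.solute.curvature),
                    "center": float(s.solute.center),
                    "offset": float(s.solute.offset),
                },
                "alpha": float(s.alpha),
            }

        bs = self.bath_stiffness
        return {
            "states": [surf(s) for s in self.states],
            "coupling_h12": float(self.coupling_h12),
            "n_bath": int(self.n_bath),
            "masses": [float(m) for m in self.masses],
            "domain": [float(v) for v in self.domain],
            "bath_stiffness": {
                "log_k0": float(bs.log_k0),
                "nodes_x": [float(v) for v in bs.nodes_x],
                "nodes_g": [float(v) for v in bs.nodes_g],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EVBSystem":
        bs = StiffnessProfile(
            log_k0=float(d["bath_stiffness"]["log_k0"]),
            nodes_x=tuple(float(v) for v in d["bath_stiffness"]["nodes_x"]),
            nodes_g=tuple(float(v) for v in d["bath_stiffness"]["nodes_g"]),
        )
        states = tuple(
            DiabaticSurface(
                solute=HarmonicWell(
                    curvature=float(s["solute"]["curvature"]),
                    center=float(s["solute"]["center"]),
                    offset=float(s["solute"]["offset"]),
                ),
                bath_stiffness=bs,
                alpha=float(s["alpha"]),
            )
            for s in d["states"]
        )
        return cls(
            states=states,
            coupling_h12=float(d["coupling_h12"]),
            n_bath=int(d["n_bath"]),
            masses=tuple(float(m) for m in d["masses"]),
            domain=tuple(float(v) for v in d["domain"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EVBSystem":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_parameters(self, alpha2: float | None = None, h12: float | None = None) -> "EVBSystem":
        """Copy with the calibration unknowns replaced (state-2 shift, coupling)."""
        states = self.states
        if alpha2 is not None:
            states = (states[0], replace(states[1], alpha=float(alpha2)))
        return EVBSystem(
            states=states,
            coupling_h12=self.coupling_h12 if h12 is None else float(h12),
            n_bath=self.n_bath,
            masses=self.masses,
            domain=self.domain,
        )

    def with_bath(self, profile: StiffnessProfile) -> "EVBSystem":
        states = tuple(replace(s, bath_stiffness=profile) for s in self.states)
        return EVBSystem(
            states=states,
            coupling_h12=self.coupling_h12,
            n_bath=self.n_bath,
            masses=self.masses,
            domain=self.domain,
        )


def ground_state_force(system: EVBSystem, coords) -> np.ndarray:
    """Force vector on the EVB ground surface at coords = (x, y_1..y_n).

    Hellmann-Feynman: F = -(w1 grad eps1 + w2 grad eps2) with the ground-state
    mixing weights; the shared bath contributes identically to both states.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (1 + system.n_bath,):
        raise ValueError(
            f"coords must have length {1 + system.n_bath}, got {coords.shape}"
        )
    x, y = coords[0], coords[1:]
    lo, hi = system.domain
    if not (lo <= x <= hi):
        raise ValueError(f"solute coordinate {x} outside domain {system.domain}")
    e1, e2 = system.diabatic_energies(x)
    w1, w2 = ground_state_weights(e1, e2, system.coupling_h12)
    d_solute = w1 * system.states[0].solute_gradient(x) + w2 * system.states[1].solute_gradient(x)
    k = system.bath_stiffness.k(x)
    dk = system.bath_stiffness.dk_dx(x)
    force = np.empty_like(coords)
    force[0] = -(d_solute + 0.5 * dk * float(np.dot(y, y)))
    force[1:] = -k * y
    return force
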