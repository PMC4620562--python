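"""Equilibrium sampling on mapping potentials.

Implements the simulation protocol of a replicate free-energy profile:
Maxwell velocity initialization, stepwise heating from 1 K to the target
temperature while a harmonic restraint on the solute coordinate is released,
unrestrained equilibration, and then the sequential FEP windows along
lambda in [0, 1], each window seeded with the final configuration of the
previous one.

Dynamics are BAOAB Langevin (see :mod:`evbscan._kernels`), which has the
exact Boltzmann distribution as its stationary law -- the one property the
free-energy estimators depend on.  Energy conservation is neither expected
nor checked.

Seed policy: every segment's RNG seed derives from
``SeedSequence(master_seed, spawn_key=(replicate_id, segment_index))``.
The temperature is deliberately *not* part of the key, so a given replicate
sees the same noise realization at every temperature of a scan.  These
common random numbers make replicate errors nearly constant across the
narrow 290-310 K range; a constant offset in dG(T) cancels exactly from the
entropy (the Arrhenius intercept) and only perturbs the enthalpy, which
sharpens the temperature regression at no cost in correctness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from . import _kernels
from .constants import KB
from .evb_core import EVBSystem, GapSample

__all__ = [
    "SamplingProtocol",
    "WindowSamples",
    "ReplicateState",
    "initialize_velocities",
    "equilibrate",
    "run_fep_windows",
]

_HEAT_INDEX = 10_000    # segment-index block for heating stages
_EQUIL_INDEX = 20_000   # segment index of the unrestrained equilibration


class TrajectoryDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplingProtocol:
    """Per-replicate simulation protocol.

    Defaults: 21 evenly spaced FEP windows; 5 heating stages of 2,000 steps
    from 1 K to the target temperature with the solute restraint decaying
    from 10 to 0 kcal mol^-1 Å^-2; 10,000 steps of unrestrained
    equilibration; 2,000 equilibration plus 120,000 sampling steps per window
    at dt = 0.01 and unit friction, recording every 10th step.  The sampling
    length is sized so that the residual estimator noise of a replicate
    barrier is a few hundredths of a kcal/mol -- the precision the entropy
    regression over a 20 K scan needs.
    """

    n_windows: int = 21
    steps_equil_per_window: int = 2_000
    steps_sample_per_window: int = 120_000
    dt: float = 0.01
    friction: float = 1.0
    stride: int = 10
    heating_stages: int = 5
    steps_per_heating_stage: int = 2_000
    steps_post_heating: int = 10_000
    restraint_k_initial: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_windows < 2:
            raise ValueError("need at least 2 FEP windows")
        if self.dt <= 0 or self.friction <= 0 or self.stride < 1:
            raise ValueError("dt, friction and stride must be positive")

    @property
    def lambdas(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_windows)

    def heating_schedule(self, temperature: float) -> list[tuple[float, float]]:
        """(temperature, restraint stiffness) stages from 1 K to the target."""
        temps = np.linspace(1.0, temperature, self.heating_stages)
        ks = np.linspace(self.restraint_k_initial, 0.0, self.heating_stages)
        return [(float(t), float(k)) for t, k in zip(temps, ks)]

    def validate_for(self, system: EVBSystem) -> None:
        """Time-step stability: dt * omega_max < 0.5 for the stiffest mode."""
        w = system.max_frequency()
        if self.dt * w >= 0.5:
            raise ValueError(
                f"unstable protocol: dt*omega_max = {self.dt * w:.3f} >= 0.5 "
                f"(dt={self.dt}, omega_max={w:.2f})"
            )


@dataclass(frozen=True)
class WindowSamples:
    """Samples recorded in one FEP window of one replicate."""

    lam: float
    temperature: float
    replicate_id: int
    seed_used: int
    x: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray
    e_ground: np.ndarray
    e_map: np.ndarray

    @property
    def gap(self) -> np.ndarray:
        return self.eps1 - self.eps2

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def samples(self) -> Iterator[GapSample]:
        for i in range(len(self.x)):
            yield GapSample(
                eps1=float(self.eps1[i]),
                eps2=float(self.eps2[i]),
                e_ground=float(self.e_ground[i]),
                e_map=float(self.e_map[i]),
                x=float(self.x[i]),
            )


@dataclass(frozen=True)
class ReplicateState:
    """Phase-space configuration handed between protocol segments."""

    x: float
    y: np.ndarray
    v: np.ndarray


def dump_windows(windows: Sequence[WindowSamples], path) -> None:
    """Optional raw-sample dump: one columnar CSV per replicate (off by
    default in the pipeline; useful for estimator debugging)."""
    import pandas as pd

    frames = []
    for m, w in enumerate(windows):
        frames.append(
            pd.DataFrame(
                {
                    "window": m,
                    "lam": w.lam,
                    "x": w.x,
                    "eps1": w.eps1,
                    "eps2": w.eps2,
                    "e_ground": w.e_ground,
                    "e_map": w.e_map,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _segment_seed(master_seed: int, replicate_id: int, segment_index: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(replicate_id, segment_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def initialize_velocities(masses, temperature: float, seed) -> np.ndarray:
    """Maxwell-Boltzmann velocities: each component ~ N(0, k_B T / m).

    ``seed`` may be an int or a ready-made Generator; identical seeds give
    identical vectors.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(0.0, np.sqrt(KB * temperature / masses))


def _run(system, protocol, state, n_steps, stride, temperature, lam, seed,
         restraint_k=0.0, restraint_x0=0.0, record=False):
    sol, bath, n_bath, masses = _kernels.pack_params(system)
    x, y, v, xs, e1, e2, eg, em, bad = _kernels.run_segment(
        state.x, state.y, state.v,
        n_steps, stride, protocol.dt, protocol.friction, KB * temperature,
        lam, sol, bath, masses, restraint_k, restraint_x0, seed,
        record,
    )
    if bad:
        raise TrajectoryDivergedError(
            f"non-finite energy at step {bad} (T={temperature} K, lambda={lam:.3f})"
        )
    return ReplicateState(x=x, y=y, v=v), (xs, e1, e2, eg, em)


def equilibrate(
    system: EVBSystem,
    protocol: SamplingProtocol,
    temperature: float,
    replicate_id: int,
) -> ReplicateState:
    """Stepwise-heated, restraint-released equilibration of one replicate.

    Starts from the reactant-state solute minimum with a zero-displacement
    bath, Maxwell velocities at the first stage temperature, heats through
    the protocol's schedule while the solute restraint decays to zero, then
    runs the unrestrained equilibration.  The returned configuration samples
    the Boltzmann distribution of the lambda = 0 mapping potential.
    """
    protocol.validate_for(system)
    x0 = system.states[0].solute.center
    schedule = protocol.heating_schedule(temperature)
    seed0 = _segment_seed(protocol.seed, replicate_id, _HEAT_INDEX)
    v = initialize_velocities(system.masses, schedule[0][0], seed0)
    state = ReplicateState(x=x0, y=np.zeros(system.n_bath), v=v)
    for i, (t_stage, k_restraint) in enumerate(schedule):
        seed = _segment_seed(protocol.seed, replicate_id, _HEAT_INDEX + 1 + i)
        state, _ = _run(
            system, protocol, state, protocol.steps_per_heating_stage,
            protocol.stride, t_stage, 0.0, seed,
            restraint_k=k_restraint, restraint_x0=x0,
        )
    seed = _segment_seed(protocol.seed, replicate_id, _EQUIL_INDEX)
    state, _ = _run(
        system, protocol, state, protocol.steps_post_heating,
        protocol.stride, temperature, 0.0, seed,
    )
    return state


def run_fep_windows(
    system: EVBSystem,
    protocol: SamplingProtocol,
    temperature: float,
    replicate_id: int,
    state: ReplicateState | None = None,
) -> list[WindowSamples]:
    """One replicate's full FEP scan: sequential windows over lambda.

    Each window equilibrates briefly at its lambda, then records
    (x, eps1, eps2, E_g, eps_lambda) every ``stride`` steps; the final
    configuration seeds the next window.  Identical (seed, temperature,
    protocol) reproduce bitwise-identical sample streams.
    """
    protocol.validate_for(system)
    if state is None:
        state = equilibrate(system, protocol, temperature, replicate_id)
    windows: list[WindowSamples] = []
    for m, lam in enumerate(protocol.lambdas):
        seed = _segment_seed(protocol.seed, replicate_id, 2 * m)
        seed_sample = _segment_seed(protocol.seed, replicate_id, 2 * m + 1)
        try:
            if protocol.steps_equil_per_window:
                state, _ = _run(
                    system, protocol, state, protocol.steps_equil_per_window,
                    protocol.stride, temperature, float(lam), seed,
                )
            state, (xs, e1, e2, eg, em) = _run(
                system, protocol, state, protocol.steps_sample_per_window,
                protocol.stride, temperature, float(lam), seed_sample,
                record=True,
            )
        except TrajectoryDivergedError as exc:
            raise TrajectoryDivergedError(f"window {m}: {exc}") from exc
        windows.append(
            WindowSamples(
                lam=float(lam), temperature=temperature,
                replicate_id=replicate_id, seed_used=seed,
                x=xs, eps1=e1, eps2=e2, e_ground=eg, e_map=em,
            )
        )
    return windows
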