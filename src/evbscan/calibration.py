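"""EVB calibration: solve (alpha, H12) against target free energies.

Mirrors standard EVB practice: the gas-phase shift of the product state and
the off-diagonal coupling are the two free parameters, adjusted once so the
model reproduces known activation and reaction free energies at a reference
temperature.  The exact (closed-form) barrier evaluation makes the solve a
cheap damped-Newton root find; sampled verification is a separate concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import T_REF_DEFAULT
from .evb_core import EVBSystem
from .oracle import exact_barrier

__all__ = ["CalibrationError", "CalibrationResult", "calibrate"]

STEP_CAP = 2.0       # kcal/mol per Newton step and parameter
TOLERANCE = 0.01     # kcal/mol on each constrained observable
MAX_ITER = 100
FD_STEP = 1e-3       # finite-difference step for the Jacobian


class CalibrationError(RuntimeError):
    """Raised when the Newton iteration fails to reach the targets."""


@dataclass(frozen=True)
class CalibrationResult:
    alpha: float
    h12: float
    achieved_dG_act: float
    achieved_dG_rxn: float
    n_iterations: int
    system: EVBSystem  # the calibrated system

    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "h12": float(self.h12),
            "achieved_dG_act": float(self.achieved_dG_act),
            "achieved_dG_rxn": float(self.achieved_dG_rxn),
            "n_iterations": int(self.n_iterations),
        }


def _observables(system: EVBSystem, alpha: float, h12: float, T_ref: float):
    bar = exact_barrier(system.with_parameters(alpha2=alpha, h12=h12), T_ref)
    return bar.dG_act, bar.dG_rxn


def calibrate(
    system: EVBSystem,
    target_dG_act: float,
    target_dG_rxn: float | None = None,
    T_ref: float = T_REF_DEFAULT,
    tol: float = TOLERANCE,
    max_iter: int = MAX_ITER,
) -> CalibrationResult:
    """Solve the gas-phase shift (and coupling) for the target free energies.

    With both targets given, a 2-D damped Newton iteration adjusts
    (alpha, H12) until the exact barrier and reaction free energy at ``T_ref``
    match ``(target_dG_act, target_dG_rxn)``.  With only a barrier target,
    H12 is held at its configured value and alpha alone is solved.
    Deterministic given its inputs.
    """
    if target_dG_act <= 0:
        raise ValueError(f"target barrier must be positive, got {target_dG_act}")
    if target_dG_rxn is not None and target_dG_act < abs(target_dG_rxn) / 2.0:
        raise ValueError(
            f"targets unreachable: barrier {target_dG_act} below "
            f"|dG_rxn|/2 = {abs(target_dG_rxn) / 2.0}"
        )
    alpha = float(system.states[1].alpha)
    h12 = float(system.coupling_h12)
    two_param = target_dG_rxn is not None

    def residual(a, h):
        act, rxn = _observables(system, a, h, T_ref)
        if two_param:
            return np.array([act - target_dG_act, rxn - target_dG_rxn]), (act, rxn)
        return np.array([act - target_dG_act]), (act, rxn)

    r, achieved = residual(alpha, h12)
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(r)) <= tol:
            break
        if two_param:
            ra, _ = residual(alpha + FD_STEP, h12)
            rh, _ = residual(alpha, h12 + FD_STEP)
            J = np.column_stack([(ra - r) / FD_STEP, (rh - r) / FD_STEP])
            try:
                step = np.linalg.solve(J, -r)
            except np.linalg.LinAlgError as exc:
                raise CalibrationError(f"singular Jacobian at iteration {it}") from exc
        else:
            ra, _ = residual(alpha + FD_STEP, h12)
            deriv = (ra[0] - r[0]) / FD_STEP
            if deriv == 0:
                raise CalibrationError(f"flat response of dG_act to alpha at iteration {it}")
            step = np.array([-r[0] / deriv])
        step = np.clip(step, -STEP_CAP, STEP_CAP)
        # damping: halve the step until the residual norm decreases
        norm0 = float(np.linalg.norm(r))
        scale = 1.0
        for _ in range(8):
            a_new = alpha + scale * step[0]
            h_new = max(h12 + scale * step[1], 1e-6) if two_param else h12
            r_new, achieved_new = residual(a_new, h_new)
            if np.linalg.norm(r_new) < norm0:
                break
            scale *= 0.5
        alpha, r, achieved = a_new, r_new, achieved_new
        if two_param:
            h12 = h_new
    else:
        raise CalibrationError(
            f"no convergence after {max_iter} iterations; last residuals "
            f"(dG_act, dG_rxn) = {tuple(np.round(r, 4))}"
        )
    return CalibrationResult(
        alpha=alpha,
        h12=h12,
        achieved_dG_act=achieved[0],
        achieved_dG_rxn=achieved[1],
        n_iterations=it,
        system=system.with_parameters(alpha2=alpha, h12=h12),
    )
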