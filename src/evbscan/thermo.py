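"""Arrhenius / van't Hoff analysis of temperature-dependent free energies.

The central construction: plotting dG(T)/T against 1/T turns the linear
thermodynamic decomposition dG = dH - T*dS into a straight line with slope dH
and intercept -dS, so an ordinary least-squares fit over a temperature scan
extracts the enthalpic and entropic components.  Applied to activation free
energies this is the (computational) Arrhenius plot; applied to reaction free
energies it is the van't Hoff plot.

Also houses the Eyring transition-state-theory rate conversion and the small
unit/standard-state conversions used when comparing barriers across
concentration conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import KB, KB_SI, PLANCK_SI, T_REF_DEFAULT

__all__ = [
    "ThermoDecomposition",
    "arrhenius_fit",
    "vant_hoff_fit",
    "entropy_to_eu",
    "eyring_rate",
    "dG_from_rate",
    "convert_standard_state",
    "combine_stepwise",
]


@dataclass(frozen=True)
class ThermoDecomposition:
    """Enthalpy/entropy decomposition of a temperature-dependent free energy.

    ``dH`` in kcal/mol, ``dS`` in kcal mol^-1 K^-1; ``TdS_at_ref`` is
    ``T_ref * dS``.  ``rms_residual_eu`` is the root-mean-square of the fit
    residuals of dG/T, expressed in entropy units (cal mol^-1 K^-1).
    """

    dH: float
    dS: float
    T_ref: float
    kind_label: str  # "arrhenius" (activation) or "vant_hoff" (reaction)
    r_squared: float = float("nan")
    rms_residual_eu: float = float("nan")
    covariance: np.ndarray = field(
        default_factory=lambda: np.full((2, 2), np.nan)
    )
    n_points: int = 0

    @property
    def TdS_at_ref(self) -> float:
        return self.T_ref * self.dS

    def dG(self, temperature) -> float:
        """Fitted free energy dH - T*dS at the given temperature(s)."""
        return self.dH - np.asarray(temperature, float) * self.dS

    def to_dict(self) -> dict:
        return {
            "kind": self.kind_label,
            "dH_kcal_mol": self.dH,
            "dS_kcal_mol_K": self.dS,
            "TdS_at_ref_kcal_mol": self.TdS_at_ref,
            "T_ref_K": self.T_ref,
            "r_squared": self.r_squared,
            "rms_residual_eu": self.rms_residual_eu,
            "n_points": self.n_points,
            "covariance": np.asarray(self.covariance).tolist(),
        }


def _as_points(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValueError("points must be (temperature, dG[, sem]) rows")
    T = arr[:, 0]
    dG = arr[:, 1]
    sem = arr[:, 2] if arr.shape[1] == 3 else np.zeros_like(T)
    return T, dG, sem


def _gibbs_helmholtz_fit(points, kind: str, T_ref: float, weighted: bool) -> ThermoDecomposition:
    T, dG, sem = _as_points(points)
    if len(np.unique(T)) < 3:
        raise ValueError("need at least 3 distinct temperatures")
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    x = 1.0 / T
    y = dG / T
    # design matrix for y = dH * x + (-dS)
    A = np.column_stack([x, np.ones_like(x)])
    if weighted:
        if np.any(sem <= 0):
            raise ValueError("weighted fit requires positive s.e.m. values")
        w = T / sem  # y-errors are sem/T
        Aw = A * w[:, None]
        yw = y * w
    else:
        Aw, yw = A, y
    coef, _, _, _ = np.linalg.lstsq(Aw, yw, rcond=None)
    dH, neg_dS = coef
    resid = y - A @ coef
    dof = max(len(T) - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Aw.T @ Aw)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    rms_eu = float(np.sqrt(np.mean(resid**2))) * 1000.0
    return ThermoDecomposition(
        dH=float(dH),
        dS=float(-neg_dS),
        T_ref=T_ref,
        kind_label=kind,
        r_squared=r2,
        rms_residual_eu=rms_eu,
        covariance=cov,
        n_points=len(T),
    )


def arrhenius_fit(points, T_ref: float = T_REF_DEFAULT, weighted: bool = False) -> ThermoDecomposition:
    """Activation enthalpy/entropy from dG_act(T): OLS of dG/T on 1/T.

    ``points`` is an iterable of (temperature K, dG_act, [s.e.m.]) rows.
    Slope = dH_act, intercept = -dS_act.  Unweighted by default, matching the
    convention that the regression -- not the per-point s.e.m. -- sets the
    uncertainty of the decomposition.
    """
    return _gibbs_helmholtz_fit(points, "arrhenius", T_ref, weighted)


def vant_hoff_fit(points, T_ref: float = T_REF_DEFAULT, weighted: bool = False) -> ThermoDecomposition:
    """Reaction enthalpy/entropy from dG_rxn(T); same construction as
    :func:`arrhenius_fit` applied to the reaction free energy."""
    return _gibbs_helmholtz_fit(points, "vant_hoff", T_ref, weighted)


def entropy_to_eu(TdS: float, temperature: float) -> float:
    """Convert a T*dS term (kcal/mol at T) to entropy units (cal mol^-1 K^-1)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 1000.0 * TdS / temperature


def eyring_rate(dG_act: float, temperature: float) -> float:
    """Transition-state-theory rate k = (k_B T / h) exp(-dG_act / RT).

    Units are s^-1; for a bimolecular barrier quoted at a concentration
    standard state the result carries that convention (M^-1 s^-1).  The
    prefactor evaluates to 6.25e12 s^-1 at 300 K.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    prefactor = KB_SI * temperature / PLANCK_SI
    return prefactor * np.exp(-dG_act / (KB * temperature))


def dG_from_rate(rate: float, temperature: float) -> float:
    """Invert :func:`eyring_rate`: activation free energy from a rate."""
    if rate <= 0 or temperature <= 0:
        raise ValueError("rate and temperature must be positive")
    prefactor = KB_SI * temperature / PLANCK_SI
    return KB * temperature * np.log(prefactor / rate)


def convert_standard_state(dG: float, c_from: float, c_to: float, temperature: float) -> float:
    """Shift a bimolecular barrier between concentration standard states.

    dG_to = dG_from - RT ln(c_to / c_from); raising the reference
    concentration (1 M -> 55 M water) lowers the apparent barrier.
    """
    if c_from <= 0 or c_to <= 0:
        raise ValueError("concentrations must be positive")
    return dG - KB * temperature * np.log(c_to / c_from)


def combine_stepwise(pt: ThermoDecomposition, attack: ThermoDecomposition) -> ThermoDecomposition:
    """Overall decomposition of a pre-equilibrium + attack stepwise mechanism.

    The overall barrier is the pre-equilibrium reaction free energy plus the
    attack activation free energy, so enthalpies and entropies add;
    covariances add under independence of the two fits.
    """
    if pt.T_ref != attack.T_ref:
        raise ValueError(
            f"T_ref mismatch: {pt.T_ref} (reaction) vs {attack.T_ref} (activation)"
        )
    cov = np.asarray(pt.covariance, float) + np.asarray(attack.covariance, float)
    return ThermoDecomposition(
        dH=pt.dH + attack.dH,
        dS=pt.dS + attack.dS,
        T_ref=pt.T_ref,
        kind_label="arrhenius",
        r_squared=float("nan"),
        rms_residual_eu=float("nan"),
        covariance=cov,
        n_points=min(pt.n_points, attack.n_points),
    )
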