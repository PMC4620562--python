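"""Free-energy profiles from FEP umbrella-sampling windows.

The classic EVB estimator: the Zwanzig (exponential-averaging) increments
between consecutive mapping potentials fix the window offsets,

    dG_{m -> m+1} = -kT ln < exp(-beta (eps_{m+1} - eps_m)) >_m ,

and within each window the ground-state surface is projected onto the energy
gap X = eps1 - eps2 by umbrella reweighting,

    G(X_b) = dG_m - kT ln < delta_b exp(-beta (E_g - eps_m)) >_m .

Where several windows populate a gap bin, the window with the larger count
owns the bin; the assembled profile is anchored to zero at its reactant-side
minimum.  Replicates are averaged per temperature into means and standard
errors, the error model of the temperature-scan analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._extrema import NoBarrierError, locate_stationary
from .constants import KB, beta
from .sampling import WindowSamples

__all__ = [
    "FreeEnergyProfile",
    "BarrierResult",
    "ReplicateScan",
    "GapCoverageError",
    "NoBarrierError",
    "fep_increment",
    "fep_chain",
    "assemble_profile",
    "barrier_and_reaction",
    "average_replicates",
]

DEFAULT_N_BINS = 50
DEFAULT_MIN_COUNT = 10


class GapCoverageError(ValueError):
    """Raised when consecutive windows leave a hole in gap coverage."""


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Ground-state free energy vs gap coordinate, one replicate/temperature.

    ``usable`` marks bins whose owning window contributed at least the count
    threshold; under-populated bins are flagged rather than interpolated.
    """

    bin_centers: np.ndarray
    dG: np.ndarray
    counts: np.ndarray
    usable: np.ndarray
    temperature: float
    replicate_id: int = 0
    standard_state: str = "1M"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "dG": self.dG,
                "counts": self.counts,
                "usable": self.usable,
                "temperature": self.temperature,
                "replicate": self.replicate_id,
            }
        )


@dataclass(frozen=True)
class BarrierResult:
    dG_act: float
    dG_rxn: float
    X_reactant: float
    X_ts: float
    X_product: float
    temperature: float
    replicate_id: int = 0


@dataclass(frozen=True)
class ReplicateScan:
    """Per-temperature replicate statistics of dG_act and dG_rxn."""

    table: pd.DataFrame          # temperature, mean/sem of dG_act and dG_rxn, n
    results: tuple[BarrierResult, ...]

    def activation_points(self) -> list[tuple[float, float, float]]:
        """(T, mean dG_act, sem) rows for an Arrhenius fit."""
        return list(
            self.table[["temperature", "dG_act_mean", "dG_act_sem"]].itertuples(
                index=False, name=None
            )
        )

    def reaction_points(self) -> list[tuple[float, float, float]]:
        """(T, mean dG_rxn, sem) rows for a van't Hoff fit."""
        return list(
            self.table[["temperature", "dG_rxn_mean", "dG_rxn_sem"]].itertuples(
                index=False, name=None
            )
        )


def fep_increment(samples_m: WindowSamples, lam_next: float) -> float:
    """Zwanzig free-energy increment from window m to ``lam_next`` (kcal/mol).

    Evaluated with a log-sum-exp shift, so large perturbation energies cannot
    overflow.  The identity perturbation returns exactly 0.
    """
    if samples_m.n_samples == 0:
        raise ValueError("empty window")
    if not (0.0 <= lam_next <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam_next}")
    b = beta(samples_m.temperature)
    # eps_next - eps_m = (lam_next - lam_m) * (eps2 - eps1); bath cancels
    d_eps = (lam_next - samples_m.lam) * (samples_m.eps2 - samples_m.eps1)
    n = len(d_eps)
    return float(-(logsumexp(-b * d_eps) - np.log(n)) / b)


def fep_chain(
    windows: Sequence[WindowSamples], direction: str = "bidirectional"
) -> np.ndarray:
    """Cumulative FEP offsets dG_lambda over the window ladder.

    ``forward``: accumulate Zwanzig increments m -> m+1 from window m's
    samples; ``reverse``: the m+1 -> m increments from window m+1, cumulated
    from the top and re-anchored at lambda = 0.  The default
    ``bidirectional`` averages the forward and (negated) reverse estimates of
    every edge, which cancels the leading-order exponential-averaging bias of
    one-sided Zwanzig chains; the forward/reverse discrepancy remains
    available as the thermodynamic-cycle closure diagnostic.
    """
    lams = [w.lam for w in windows]
    n = len(windows)
    dG = np.zeros(n)
    if direction == "forward":
        edges = [fep_increment(windows[m], lams[m + 1]) for m in range(n - 1)]
    elif direction == "reverse":
        edges = [-fep_increment(windows[m + 1], lams[m]) for m in range(n - 1)]
    elif direction == "bidirectional":
        edges = [
            0.5
            * (
                fep_increment(windows[m], lams[m + 1])
                - fep_increment(windows[m + 1], lams[m])
            )
            for m in range(n - 1)
        ]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    dG[1:] = np.cumsum(edges)
    return dG


def assemble_profile(
    windows: Sequence[WindowSamples],
    n_bins: int = DEFAULT_N_BINS,
    min_count: int = DEFAULT_MIN_COUNT,
) -> FreeEnergyProfile:
    """Assemble the ground-state free-energy profile over the gap coordinate.

    Requires at least two windows with overlapping gap coverage; an empty
    interior bin (a coverage hole between consecutive windows) is an error,
    not something to interpolate over.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    temperature = windows[0].temperature
    if any(w.temperature != temperature for w in windows):
        raise ValueError("windows sampled at inconsistent temperatures")
    b = beta(temperature)
    dG_lam = fep_chain(windows)

    gaps = [w.gap for w in windows]
    # coverage: consecutive windows must overlap on the gap coordinate
    order = np.argsort([g.mean() for g in gaps])
    for a_i, b_i in zip(order[:-1], order[1:]):
        lo_a, hi_a = gaps[a_i].min(), gaps[a_i].max()
        lo_b, hi_b = gaps[b_i].min(), gaps[b_i].max()
        if min(hi_a, hi_b) < max(lo_a, lo_b):
            raise GapCoverageError(
                f"gap coverage hole between consecutive windows over X = "
                f"[{min(hi_a, hi_b):.1f}, {max(lo_a, lo_b):.1f}] kcal/mol"
            )
    lo = min(g.min() for g in gaps)
    hi = max(g.max() for g in gaps)
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[1:] + edges[:-1])

    counts = np.zeros((len(windows), n_bins), dtype=np.int64)
    # per (window, bin) log of the mean umbrella weight
    log_term = np.full((len(windows), n_bins), -np.inf)
    for m, w in enumerate(windows):
        idx = np.clip(np.digitize(gaps[m], edges) - 1, 0, n_bins - 1)
        log_w = -b * (w.e_ground - w.e_map)
        n_m = len(idx)
        for bin_i in np.unique(idx):
            sel = idx == bin_i
            counts[m, bin_i] = int(sel.sum())
            log_term[m, bin_i] = logsumexp(log_w[sel]) - np.log(n_m)

    owner = np.argmax(counts, axis=0)
    own_counts = counts[owner, np.arange(n_bins)]
    with np.errstate(invalid="ignore"):
        dG = dG_lam[owner] - log_term[owner, np.arange(n_bins)] / b
    usable = own_counts >= min_count
    if usable.sum() < 5:
        raise ValueError("too few well-populated bins to form a profile")

    # anchor: reactant side is negative gap (state 1 below state 2)
    reactant_side = usable & (centers < 0)
    anchor_side = reactant_side if reactant_side.any() else usable
    dG = dG - np.min(dG[anchor_side])
    dG = np.where(np.isfinite(dG), dG, np.nan)
    return FreeEnergyProfile(
        bin_centers=centers,
        dG=dG,
        counts=own_counts,
        usable=usable,
        temperature=temperature,
        replicate_id=windows[0].replicate_id,
    )


def barrier_and_reaction(profile: FreeEnergyProfile) -> BarrierResult:
    """Extract dG_act and dG_rxn from a profile's stationary points.

    Reactant minimum = lowest-gap local minimum, product = highest-gap local
    minimum, TS = highest bin between them; each refined by a three-point
    quadratic fit.  A profile without an interior maximum raises
    :class:`NoBarrierError` rather than reporting a zero barrier.
    """
    xs = profile.bin_centers[profile.usable]
    gs = profile.dG[profile.usable]
    sp = locate_stationary(xs, gs)
    return BarrierResult(
        dG_act=sp.g_ts - sp.g_reactant,
        dG_rxn=sp.g_product - sp.g_reactant,
        X_reactant=sp.x_reactant,
        X_ts=sp.x_ts,
        X_product=sp.x_product,
        temperature=profile.temperature,
        replicate_id=profile.replicate_id,
    )


def average_replicates(results: Sequence[BarrierResult]) -> ReplicateScan:
    """Group barrier results by temperature; mean and s.e.m. per group.

    s.e.m. = sample standard deviation (ddof=1) / sqrt(n); every temperature
    must have at least two replicates.
    """
    if not results:
        raise ValueError("no results to average")
    df = pd.DataFrame(
        {
            "temperature": [r.temperature for r in results],
            "dG_act": [r.dG_act for r in results],
            "dG_rxn": [r.dG_rxn for r in results],
        }
    )
    rows = []
    for T, grp in df.groupby("temperature", sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"temperature {T} K has fewer than 2 replicates")
        rows.append(
            {
                "temperature": T,
                "dG_act_mean": grp["dG_act"].mean(),
                "dG_act_sem": grp["dG_act"].std(ddof=1) / np.sqrt(n),
                "dG_rxn_mean": grp["dG_rxn"].mean(),
                "dG_rxn_sem": grp["dG_rxn"].std(ddof=1) / np.sqrt(n),
                "n": n,
            }
        )
    return ReplicateScan(table=pd.DataFrame(rows), results=tuple(results))
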