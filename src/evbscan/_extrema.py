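"""Stationary-point location on tabulated free-energy curves.

Shared by the exact (grid) profiles and the sampled (binned) profiles: find
the reactant minimum, the intervening maximum, and the product minimum of a
double-well curve, refining each with a three-point quadratic fit around the
extremal grid point.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class NoBarrierError(ValueError):
    """Raised when a profile has no interior maximum between two minima."""


class StationaryPoints(NamedTuple):
    x_reactant: float
    g_reactant: float
    x_ts: float
    g_ts: float
    x_product: float
    g_product: float


def _quadratic_refine(xs: np.ndarray, gs: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points (i-1, i, i+1); falls back to the
    grid point for flat or edge cases."""
    if i <= 0 or i >= len(xs) - 1:
        return float(xs[i]), float(gs[i])
    x0, x1, x2 = xs[i - 1], xs[i], xs[i + 1]
    g0, g1, g2 = gs[i - 1], gs[i], gs[i + 1]
    coeff = np.polyfit([x0, x1, x2], [g0, g1, g2], 2)
    a, b, c = coeff
    if abs(a) < 1e-300:
        return float(x1), float(g1)
    xv = -b / (2.0 * a)
    lo, hi = min(x0, x2), max(x0, x2)
    if not (lo <= xv <= hi):  # degenerate triple; keep the grid point
        return float(x1), float(g1)
    return float(xv), float(np.polyval(coeff, xv))


def locate_stationary(xs, gs) -> StationaryPoints:
    """Reactant/TS/product stationary points of a double-well curve.

    The reactant minimum is the lowest-x local minimum, the product minimum
    the highest-x one, and the transition state the highest point between
    them.  Curves without two interior minima separated by a higher point
    (monotone or flat profiles) have no barrier.
    """
    xs = np.asarray(xs, dtype=float)
    gs = np.asarray(gs, dtype=float)
    if xs.ndim != 1 or xs.shape != gs.shape or len(xs) < 5:
        raise ValueError("need matching 1-D arrays with at least 5 points")
    if np.ptp(gs) <= 0:
        raise NoBarrierError("flat profile: no barrier present")
    candidates = np.flatnonzero(
        (gs[1:-1] <= gs[:-2]) & (gs[1:-1] <= gs[2:])
    ) + 1
    # endpoints count as minima when the curve rises away from them
    if gs[0] < gs[1]:
        candidates = np.concatenate([[0], candidates])
    if gs[-1] < gs[-2]:
        candidates = np.concatenate([candidates, [len(gs) - 1]])
    # collapse plateau runs to single representatives
    minima = [i for j, i in enumerate(candidates) if j == 0 or i - candidates[j - 1] > 1]
    if len(minima) < 2:
        raise NoBarrierError("monotone profile: fewer than two local minima")
    i_r, i_p = minima[0], minima[-1]
    i_ts = i_r + 1 + int(np.argmax(gs[i_r + 1 : i_p]))
    if gs[i_ts] <= gs[i_r] or gs[i_ts] <= gs[i_p]:
        raise NoBarrierError("interior maximum does not exceed the flanking minima")
    x_r, g_r = _quadratic_refine(xs, gs, i_r)
    x_t, g_t = _quadratic_refine(xs, gs, i_ts)
    x_p, g_p = _quadratic_refine(xs, gs, i_p)
    return StationaryPoints(x_r, g_r, x_t, g_t, x_p, g_p)
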