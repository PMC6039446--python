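"""Electrode-drift correction and replicate averaging.

Because K+ is the only permeant cation, the true reversal potential of the
open-channel current is the Nernst potential E_K; slow electrode drift
(typically a few mV over hours-long recordings) shows up as a horizontal
offset of the measured IV curve.  The correction fits a 3rd-order
polynomial to I_OF(V) around the zero crossing, reads off the apparent
reversal potential, and shifts the condition's voltage axis so the crossing
lands on E_K.  Replicates recorded on differing voltage grids are
interpolated with natural cubic splines onto a common grid before
averaging.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .dataset import ConditionCurve

__all__ = ["DriftCorrection", "drift_correct", "spline_average", "NoCrossingError"]


class NoCrossingError(ValueError):
    """The IV curve does not bracket a zero crossing."""


class DriftCorrection(NamedTuple):
    curve: ConditionCurve
    offset_mV: float  # detected apparent reversal minus E_K


def _apparent_reversal(V: np.ndarray, I: np.ndarray, expected: float, window: int = 6) -> float:
    sign = np.sign(I)
    nz = sign != 0
    crossings = np.nonzero(np.diff(sign[nz]) != 0)[0]
    if crossings.size == 0:
        raise NoCrossingError("IV curve does not change sign; cannot locate reversal")
    # fit around the crossing nearest the expected reversal
    v_nz = V[nz]
    cross_v = 0.5 * (v_nz[crossings] + v_nz[crossings + 1])
    center = cross_v[np.argmin(np.abs(cross_v - expected))]
    order = np.argsort(np.abs(V - center))[:window]
    sel = np.sort(order)
    coeffs = np.polyfit(V[sel], I[sel], deg=min(3, len(sel) - 1))
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    in_range = real[(real >= V.min() - 10) & (real <= V.max() + 10)]
    if in_range.size == 0:
        raise NoCrossingError("polynomial fit has no real root in the voltage range")
    if in_range.size > 1:
        warnings.warn("multiple polynomial roots in range; using the one nearest E_K", stacklevel=2)
    return float(in_range[np.argmin(np.abs(in_range - expected))])


def drift_correct(curve: ConditionCurve, expected_E_K: float) -> DriftCorrection:
    """Shift a condition's curves so the I_OF reversal lands on E_K.

    Returns the shifted curve and the detected offset (apparent reversal
    minus expected E_K); raises :class:`NoCrossingError` when no sign change
    brackets a reversal.
    """
    apparent = _apparent_reversal(curve.V, curve.I_OF, expected_E_K)
    offset = apparent - expected_E_K
    return DriftCorrection(curve=curve.shifted(-offset), offset_mV=offset)


def spline_average(
    replicates: Sequence[tuple[np.ndarray, np.ndarray]],
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average replicate curves recorded on differing abscissa grids.

    Each replicate ``(x, y)`` is interpolated with a cubic spline
    (not-a-knot end conditions, which reproduce cubic polynomials exactly)
    onto the common grid (default: the union of all replicate abscissas
    restricted to the overlap) and the pointwise mean and sample standard
    deviation are returned as ``(grid, mean, sd)``.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates to average")
    lo = max(np.min(x) for x, _ in replicates)
    hi = min(np.max(x) for x, _ in replicates)
    if not hi > lo:
        raise ValueError("replicate abscissa ranges do not overlap")
    if grid is None:
        merged = np.unique(np.concatenate([np.asarray(x, float) for x, _ in replicates]))
        grid = merged[(merged >= lo) & (merged <= hi)]
    else:
        grid = np.asarray(grid, float)
        if grid.min() < lo or grid.max() > hi:
            raise ValueError("requested grid extends beyond the replicate overlap")
    values = np.empty((len(replicates), grid.size))
    for r, (x, y) in enumerate(replicates):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) < 2:
            raise ValueError("replicate curves need at least two points")
        spline = CubicSpline(x, y, bc_type="not-a-knot")
        values[r] = spline(grid)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    return grid, mean, sd
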