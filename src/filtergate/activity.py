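"""Mean activity coefficients for KCl and concentration -> activity conversion.

Ion-binding steps in the permeation models are proportional to K+ *activity*
rather than concentration.  The default coefficient table holds standard
25 C literature values for the KCl mean activity coefficient (Robinson &
Stokes style compilations), with the molality/molarity distinction ignored at
the precision relevant here.  Between table nodes the coefficient is
interpolated linearly in ln(c); below the lowest node the Debye-Hueckel
limiting-law shape ln(gamma) ~ -A*sqrt(c) is used so that gamma -> 1 as
c -> 0.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

__all__ = [
    "DEFAULT_KCL_ACTIVITY_TABLE",
    "ActivityTable",
    "activity_from_concentration",
]

#: KCl mean activity coefficients at 25 C, concentration in mM.
DEFAULT_KCL_ACTIVITY_TABLE: dict[float, float] = {
    1.0: 0.965,
    5.0: 0.927,
    10.0: 0.901,
    20.0: 0.868,
    50.0: 0.815,
    100.0: 0.770,
    200.0: 0.718,
    300.0: 0.688,
    500.0: 0.649,
    700.0: 0.626,
    1000.0: 0.604,
    1500.0: 0.583,
    2000.0: 0.573,
    3000.0: 0.569,
}


class ActivityTable:
    """Monotone table of mean activity coefficients gamma(c).

    Parameters
    ----------
    table:
        Mapping concentration (mM) -> mean activity coefficient in (0, 1].
        Must cover the working range; the default covers 1-3000 mM.
    """

    def __init__(self, table: Mapping[float, float] | None = None) -> None:
        if table is None:
            table = DEFAULT_KCL_ACTIVITY_TABLE
        items = sorted(table.items())
        if len(items) < 2:
            raise ValueError("activity table needs at least two nodes")
        self.c_nodes = np.array([c for c, _ in items], dtype=float)
        self.gamma_nodes = np.array([g for _, g in items], dtype=float)
        if np.any(self.c_nodes <= 0):
            raise ValueError("table concentrations must be positive")
        if np.any((self.gamma_nodes <= 0) | (self.gamma_nodes > 1)):
            raise ValueError("activity coefficients must lie in (0, 1]")
        # Debye-Hueckel limiting-law constant matched to the lowest node.
        self._dh_a = -math.log(self.gamma_nodes[0]) / math.sqrt(self.c_nodes[0])

    def gamma(self, c):
        """Mean activity coefficient at concentration ``c`` (mM, scalar or array)."""
        c_arr = np.asarray(c, dtype=float)
        if np.any(c_arr < 0):
            raise ValueError("concentration must be non-negative")
        if np.any(c_arr > self.c_nodes[-1]):
            raise ValueError(
                f"concentration exceeds table support ({self.c_nodes[-1]:g} mM)"
            )
        out = np.empty_like(c_arr)
        low = c_arr < self.c_nodes[0]
        out[low] = np.exp(-self._dh_a * np.sqrt(c_arr[low]))
        hi = ~low
        out[hi] = np.interp(
            np.log(np.maximum(c_arr[hi], 1e-300)),
            np.log(self.c_nodes),
            self.gamma_nodes,
        )
        return out if out.ndim else float(out)

    def activity(self, c):
        """Activity a = c * gamma(c) in mM."""
        c_arr = np.asarray(c, dtype=float)
        g = self.gamma(c)
        out = c_arr * np.asarray(g)
        return out if out.ndim else float(out)


def activity_from_concentration(c, table: ActivityTable | None = None):
    """Convert a KCl concentration (mM) to a K+ activity (mM).

    ``table`` defaults to the standard 25 C KCl coefficient table.  Raises
    ``ValueError`` for negative concentrations or values outside the table
    support.
    """
    if table is None:
        table = ActivityTable()
    return table.activity(c)
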