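"""The O/S/M/F gating scheme and its analytic time-averaged currents.

One open state O (current I_true) connects in a star topology to three
closed states (0 pA): S (slow, many-ms), M (medium, closed dwells of
50-150 us) and F (fast, closed dwells of ~1-10 us).  Band-limited recording
averages over the fast transitions, which defines three currents:

* I_true - the open-channel current an infinite-bandwidth amplifier would
  measure,
* I_OF = I_true * k_FO / (k_OF + k_FO) - the current if O-M gating were
  fully resolved and only O-F gating were averaged over,
* I_app = I_true * p_O with p_O the stationary O occupancy of the O/M/F
  subsystem - the current after averaging over both O-M and O-F gating.

|I_app| <= |I_OF| <= |I_true| whenever all rates are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = ["GatingScheme", "DerivedCurrents", "analytic_time_averages"]

RATE_FIELDS = ("k_OS", "k_SO", "k_OM", "k_MO", "k_OF", "k_FO")


@dataclass(frozen=True)
class GatingScheme:
    """Rate constants (s^-1) of the star-shaped gating model plus I_true (pA)."""

    k_OM: float = 0.0
    k_MO: float = 0.0
    k_OF: float = 0.0
    k_FO: float = 0.0
    k_OS: float = 0.0
    k_SO: float = 0.0
    i_true: float = 0.0

    def __post_init__(self) -> None:
        for name in RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def open_exit_rate(self) -> float:
        return self.k_OS + self.k_OM + self.k_OF

    def replace(self, **kwargs) -> "GatingScheme":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            **{name: getattr(self, name) for name in RATE_FIELDS},
            "i_true": self.i_true,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GatingScheme":
        return cls(**{k: float(v) for k, v in doc.items()})


class DerivedCurrents(NamedTuple):
    i_true: float
    i_of: float
    i_app: float


def analytic_time_averages(scheme: GatingScheme) -> DerivedCurrents:
    """Stationary-averaging forms of I_OF and I_app for a gating scheme.

    Slow (S) gating is excluded: the amplitude-histogram analysis treats
    slow closures separately, so I_app averages over the O/M/F subsystem
    only.  Raises for degenerate schemes where a closed state is absorbing
    (k_OF > 0 with k_FO = 0, or k_OM > 0 with k_MO = 0).
    """
    if scheme.k_OF > 0 and scheme.k_FO == 0:
        raise ValueError("degenerate scheme: F is absorbing (k_OF > 0, k_FO = 0)")
    if scheme.k_OM > 0 and scheme.k_MO == 0:
        raise ValueError("degenerate scheme: M is absorbing (k_OM > 0, k_MO = 0)")
    duty_of = 1.0 if scheme.k_OF == 0 else scheme.k_FO / (scheme.k_OF + scheme.k_FO)
    occ_m = 0.0 if scheme.k_OM == 0 else scheme.k_OM / scheme.k_MO
    occ_f = 0.0 if scheme.k_OF == 0 else scheme.k_OF / scheme.k_FO
    p_open = 1.0 / (1.0 + occ_m + occ_f)
    return DerivedCurrents(
        i_true=scheme.i_true,
        i_of=scheme.i_true * duty_of,
        i_app=scheme.i_true * p_open,
    )
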