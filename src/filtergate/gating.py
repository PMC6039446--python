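"""Links between filter occupation probabilities and the closing rate k_OM.

The sub-millisecond closing rate k_OM of the channel is modelled as a
function of the stationary occupation probabilities P_m of the permeation
model, with a single scale factor w (s^-1) that is independent of voltage
and K+ concentration:

* ``proportional``:  k_OM = w * P_m      (occupancy stabilises the gate shut)
* ``inverse``:       k_OM = w / P_m      (occupancy rigidifies the open state)
* ``ratio``:         k_OM = w * P_m / P_m'  (two occupancies with opposing
  roles, e.g. outer-mouth ion versus S0 ion)

The K+ motive force Kmf = V - E_K is the electrochemical driving force on
K+; plotting k_OM of internal-concentration series against Kmf collapses
them onto a common curve, and :func:`kmf_collapse_diagnostic` quantifies
that collapse.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import T_DEFAULT_C, thermal_voltage_mV
from .kinetics import OccupationVector, occupation_batch
from .models import Condition, ModelSpec, RateParameterSet

__all__ = [
    "GatingLink",
    "KmfRecord",
    "CollapseFit",
    "nernst_potential",
    "kmf",
    "predict_kOM",
    "kmf_collapse_diagnostic",
    "DegenerateOccupancyError",
]

_MIN_DENOM = 1e-300


class DegenerateOccupancyError(ZeroDivisionError):
    """An occupation probability in a denominator is numerically zero."""


@dataclass(frozen=True)
class GatingLink:
    """One candidate relation k_OM(P); parse from strings like 'P3', '1/P3', 'P4/P3'."""

    kind: str  # proportional | inverse | ratio
    state: str
    denom_state: str | None = None
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "inverse", "ratio"):
            raise ValueError(f"unknown link kind {self.kind!r}")
        if (self.kind == "ratio") != (self.denom_state is not None):
            raise ValueError("ratio links need a denominator state, others must not have one")
        if not self.w > 0:
            raise ValueError("scale factor w must be positive")

    @classmethod
    def parse(cls, spec: str, w: float = 1.0) -> "GatingLink":
        """Parse the configuration syntax mirroring the comparison-table headers."""
        spec = spec.strip()
        m = re.fullmatch(r"1\s*/\s*P(\w+)", spec)
        if m:
            return cls("inverse", m.group(1), w=w)
        m = re.fullmatch(r"P(\w+)\s*/\s*P(\w+)", spec)
        if m:
            return cls("ratio", m.group(1), m.group(2), w=w)
        m = re.fullmatch(r"P(\w+)", spec)
        if m:
            return cls("proportional", m.group(1), w=w)
        raise ValueError(f"cannot parse gating link {spec!r}")

    @property
    def label(self) -> str:
        if self.kind == "proportional":
            return f"P{self.state}"
        if self.kind == "inverse":
            return f"1/P{self.state}"
        return f"P{self.state}/P{self.denom_state}"

    def with_w(self, w: float) -> "GatingLink":
        return GatingLink(self.kind, self.state, self.denom_state, w)


class KmfRecord(NamedTuple):
    E_K: float  # Nernst reversal potential, mV
    Kmf: float  # driving force V - E_K, mV


def nernst_potential(cond: Condition) -> float:
    """Nernst reversal potential E_K = (RT/F) ln(a_out/a_in) in mV."""
    if cond.a_in <= 0 or cond.a_out <= 0:
        raise ValueError("activities must be positive")
    return thermal_voltage_mV(cond.T) * math.log(cond.a_out / cond.a_in)


def kmf(cond: Condition) -> KmfRecord:
    """K+ motive force Kmf = V - E_K at the given condition."""
    e_k = nernst_potential(cond)
    return KmfRecord(E_K=e_k, Kmf=cond.V - e_k)


def predict_kOM(link: GatingLink, occ: OccupationVector) -> float:
    """Predicted closing rate (s^-1) from an occupation vector."""
    p = occ[link.state]
    if link.kind == "proportional":
        return link.w * p
    if link.kind == "inverse":
        if p < _MIN_DENOM:
            raise DegenerateOccupancyError(f"P{link.state} ~ 0 under inverse link")
        return link.w / p
    q = occ[link.denom_state]
    if q < _MIN_DENOM:
        raise DegenerateOccupancyError(f"P{link.denom_state} ~ 0 under ratio link")
    return link.w * p / q


def predict_kOM_batch(link: GatingLink, model: ModelSpec, P: np.ndarray) -> np.ndarray:
    """Vectorised k_OM over an occupation matrix of shape (n_cond, N)."""
    i = model.state_index(link.state)
    with np.errstate(over="ignore", divide="ignore"):
        if link.kind == "proportional":
            return link.w * P[:, i]
        if link.kind == "inverse":
            return link.w / np.maximum(P[:, i], _MIN_DENOM)
        j = model.state_index(link.denom_state)
        return link.w * P[:, i] / np.maximum(P[:, j], _MIN_DENOM)


@dataclass
class CollapseFit:
    """Empirical 4-parameter fit of the pooled occupancy ratio versus Kmf.

    ratio(Kmf) = c2 / (c1 * exp(q1 * Kmf/V_T) + exp(q2 * Kmf/V_T)); q1 and
    q2 are free voltage-fraction scalings (different reactions feel
    different fractions of the field) and c1, c2 are positive constants.
    ``residual`` is the root-mean-square log-residual of the pooled fit.
    """

    c1: float
    c2: float
    kmf_scale_1: float
    kmf_scale_2: float
    residual: float

    def predict(self, kmf_mV: np.ndarray, T: float = T_DEFAULT_C) -> np.ndarray:
        kappa = np.asarray(kmf_mV, dtype=float) / thermal_voltage_mV(T)
        return self.c2 / (self.c1 * np.exp(self.kmf_scale_1 * kappa) + np.exp(self.kmf_scale_2 * kappa))


class CollapseDiagnostic(NamedTuple):
    fit: CollapseFit | None
    score_kmf: float
    score_voltage: float


def _collapse_score(xs: list[np.ndarray], ys: list[np.ndarray], n_grid: int = 33) -> float:
    """Mean coefficient of variation across series on a shared abscissa grid."""
    lo = max(x.min() for x in xs)
    hi = min(x.max() for x in xs)
    if not hi > lo:
        raise ValueError("series do not overlap on the requested axis")
    grid = np.linspace(lo, hi, n_grid)
    interp = np.array([np.interp(grid, x, y) for x, y in zip(xs, ys)])
    mean = interp.mean(axis=0)
    sd = interp.std(axis=0, ddof=0)
    return float(np.mean(sd / np.abs(mean)))


def kmf_collapse_diagnostic(
    model: ModelSpec,
    params: RateParameterSet,
    link: GatingLink,
    series: Sequence[Sequence[Condition]],
    fit_ratio: bool = True,
) -> CollapseDiagnostic:
    """Quantify the Kmf collapse of predicted k_OM curves.

    ``series`` is a list of condition series (each a fixed concentration
    pair over a voltage grid), typically the internal-concentration panels.
    Returns the collapse score (mean coefficient of variation across series
    at matched abscissa values) both versus Kmf and versus raw voltage, and
    optionally the empirical :class:`CollapseFit` of the pooled occupancy
    ratio P_num/P_den against Kmf (only for ratio links).
    """
    if len(series) == 0:
        raise ValueError("no condition series supplied")
    xs_v, ys_v, xs_kmf, ys_kmf = [], [], [], []
    ratio_pts_x, ratio_pts_y = [], []
    for conds in series:
        V = np.array([c.V for c in conds])
        a_in = np.array([c.a_in for c in conds])
        a_out = np.array([c.a_out for c in conds])
        P = occupation_batch(model, params, V, a_in, a_out)
        k = predict_kOM_batch(link, model, P)
        km = np.array([kmf(c).Kmf for c in conds])
        order = np.argsort(V)
        xs_v.append(V[order])
        ys_v.append(k[order])
        korder = np.argsort(km)
        xs_kmf.append(km[korder])
        ys_kmf.append(k[korder])
        if link.kind == "ratio":
            i = model.state_index(link.state)
            j = model.state_index(link.denom_state)
            ratio_pts_x.append(km)
            ratio_pts_y.append(P[:, i] / P[:, j])
    if len(series) == 1:
        return CollapseDiagnostic(fit=None, score_kmf=0.0, score_voltage=0.0)
    score_v = _collapse_score(xs_v, ys_v)
    score_k = _collapse_score(xs_kmf, ys_kmf)
    fit = None
    if fit_ratio and link.kind == "ratio":
        x = np.concatenate(ratio_pts_x)
        y = np.concatenate(ratio_pts_y)
        fit = _fit_collapse_form(x, y, T=series[0][0].T)
    return CollapseDiagnostic(fit=fit, score_kmf=score_k, score_voltage=score_v)


def predict_series(
    model: ModelSpec,
    params: RateParameterSet,
    link: GatingLink,
    conds: Sequence[Condition],
) -> np.ndarray:
    """k_OM predictions for one condition series (ordered as given)."""
    V = np.array([c.V for c in conds])
    a_in = np.array([c.a_in for c in conds])
    a_out = np.array([c.a_out for c in conds])
    P = occupation_batch(model, params, V, a_in, a_out)
    return predict_kOM_batch(link, model, P)


def _fit_collapse_form(kmf_mV: np.ndarray, ratio: np.ndarray, T: float) -> CollapseFit:
    kappa = kmf_mV / thermal_voltage_mV(T)

    def resid(theta):
        lc1, lc2, q1, q2 = theta
        pred = lc2 - np.logaddexp(lc1 + q1 * kappa, q2 * kappa)
        return pred - np.log(ratio)

    theta0 = np.array([0.0, float(np.log(np.median(ratio))), 1.0, 0.0])
    sol = least_squares(resid, theta0, method="lm", max_nfev=5000)
    lc1, lc2, q1, q2 = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return CollapseFit(c1=math.exp(lc1), c2=math.exp(lc2), kmf_scale_1=q1, kmf_scale_2=q2, residual=rms)
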