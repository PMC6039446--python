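"""Global fit of IV and k_OM(V) curves with one shared parameter set.

All condition curves of a dataset (per-series IV plus per-series closing
rate) are fitted simultaneously: the free parameters are the base rates of
the permeation model, the Eyring-barrier parameters, and the single gating
scale w.  The objective is

    error = w_I * sum (I_model - I_data)^2            over all IV points
          + w_k * sum (ln k_OM,model - ln k_OM,data)^2 over masked points,

with the closing-rate term restricted by default to negative voltages
(where the selectivity-filter gating process dominates) and the logarithm
giving currents and rates about equal weight.  Optimisation is Nelder-Mead
over unconstrained transforms (log rates, logit electrical positions, log
characteristic voltages, log w) with seeded multi-start, followed by a
Levenberg-Marquardt polish of the best candidates on the residual vector.
Model ranking across candidate gating links uses the resulting error sums.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .activity import ActivityTable
from .constants import T_DEFAULT_C, thermal_voltage_mV
from .dataset import ExperimentDataset
from .gating import GatingLink, predict_kOM_batch
from .kinetics import currents_and_occupations
from .models import EyringBarrier, ModelSpec, RateParameterSet

__all__ = [
    "FitConfig",
    "FitResult",
    "ComparisonTable",
    "ParamTransform",
    "global_objective",
    "run_global_fit",
    "compare_gating_links",
    "default_links",
]

_PENALTY = 1e3  # per-point residual for invalid model predictions


@dataclass(frozen=True)
class FitConfig:
    """Weights, masks, constraint flag and optimiser settings of the global fit."""

    weight_current: float = 1.0
    weight_rate: float = 1.0
    #: include a k_OM datum only where this holds (default: negative voltages)
    kom_voltage_mask: Callable[[np.ndarray], np.ndarray] = staticmethod(lambda V: V < 0)
    nernst_constraint: bool = True
    restarts: int = 20
    perturb_sd_log10: float = 0.5
    simplex_maxfev: int = 2000
    simplex_xatol: float = 1e-4
    simplex_fatol: float = 1e-12
    polish: bool = True
    polish_top: int = 3
    polish_max_nfev: int = 400
    seed: int = 0
    T: float = T_DEFAULT_C

    def __post_init__(self) -> None:
        if self.weight_current <= 0 or self.weight_rate <= 0:
            raise ValueError("weights must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


class _Compiled:
    """Dataset flattened to arrays for the vectorised objective."""

    def __init__(self, dataset: ExperimentDataset, config: FitConfig):
        table = ActivityTable()
        V, a_in, a_out, I, lnk, curve_ix = [], [], [], [], [], []
        self.curve_ids = []
        for ci, curve in enumerate(dataset):
            self.curve_ids.append(curve.series_id)
            V.append(curve.V)
            a_in.append(np.full_like(curve.V, table.activity(curve.c_in)))
            a_out.append(np.full_like(curve.V, table.activity(curve.c_out)))
            I.append(curve.I_OF)
            lnk.append(np.log(curve.k_OM))
            curve_ix.append(np.full(curve.V.shape, ci, dtype=int))
        self.V = np.concatenate(V)
        self.a_in = np.concatenate(a_in)
        self.a_out = np.concatenate(a_out)
        self.I = np.concatenate(I)
        self.lnk = np.concatenate(lnk)
        self.curve_ix = np.concatenate(curve_ix)
        self.n_curves = len(dataset)
        self.kom_mask = np.asarray(config.kom_voltage_mask(self.V), dtype=bool)
        self.kom_mask &= np.isfinite(self.lnk)
        self.iv_mask = np.isfinite(self.I)


@dataclass
class FitResult:
    params: RateParameterSet
    w: float
    link: GatingLink
    error_sum: float
    per_curve: dict[str, dict[str, float]]
    n_eval: int
    restart_errors: list[float] = field(default_factory=list)
    polish_improved: bool = False
    seed: int | None = None

    def breakdown_total(self) -> float:
        return sum(v["iv"] + v["kom"] for v in self.per_curve.values())


class ParamTransform:
    """Bijective map between fit vectors and (RateParameterSet, w).

    Base rates and w live on a log scale and electrical positions on a
    logit scale, guaranteeing positivity and s in (0, 1) without explicit
    constraints.  With the Nernst constraint active, the designated
    backward base rate is recomputed from the cycle product and the inverse
    characteristic voltages of the cycle's Eyring groups are a softmax
    split of 1/V_T, so every vector maps to a thermodynamically consistent
    parameter set.
    """

    def __init__(self, model: ModelSpec, constrained: bool = True, T: float = T_DEFAULT_C):
        self.model = model
        self.constrained = constrained
        self.T = T
        self.v_thermal = thermal_voltage_mV(T)
        self.groups = list(model.eyring_groups())
        all_params = [e.param for e in model.edges]
        if constrained:
            elim = model.constraint_eliminated_rate
            if elim is None:
                raise ValueError(f"model {model.name!r} designates no eliminated rate")
            self.free_rates = [p for p in all_params if p != elim]
        else:
            self.free_rates = all_params
        self.names = [f"ln_{p}" for p in self.free_rates]
        self.names += [f"logit_s_{g}" for g in self.groups]
        if constrained:
            self.names += [f"vsplit_{g}" for g in self.groups[:-1]]
        else:
            self.names += [f"ln_V_{g}" for g in self.groups]
        self.names.append("ln_w")

    @property
    def n_params(self) -> int:
        return len(self.names)

    def pack(self, params: RateParameterSet, w: float) -> np.ndarray:
        x = [np.log(params.base_rates[p]) for p in self.free_rates]
        for g in self.groups:
            s = np.clip(params.eyring[g].s, 1e-6, 1 - 1e-6)
            x.append(np.log(s / (1 - s)))
        if self.constrained:
            inv = np.array([1.0 / params.eyring[g].v_char for g in self.groups])
            frac = inv / inv.sum()
            x.extend(np.log(frac[:-1] / frac[-1]))
        else:
            x.extend(np.log(params.eyring[g].v_char) for g in self.groups)
        x.append(np.log(w))
        return np.array(x)

    def unpack(self, x: np.ndarray) -> tuple[RateParameterSet, float]:
        x = np.asarray(x, dtype=float)
        i = 0
        base = {}
        for p in self.free_rates:
            base[p] = float(np.exp(np.clip(x[i], -80, 80)))
            i += 1
        s_vals = {}
        for g in self.groups:
            s_vals[g] = float(1.0 / (1.0 + np.exp(-np.clip(x[i], -500, 500))))
            i += 1
        eyring = {}
        if self.constrained:
            n_g = len(self.groups)
            if n_g:
                z = np.concatenate([x[i : i + n_g - 1], [0.0]])
                i += n_g - 1
                frac = np.exp(z - z.max())
                frac /= frac.sum()
                for g, f in zip(self.groups, frac):
                    eyring[g] = EyringBarrier(s=s_vals[g], v_char=self.v_thermal / f)
        else:
            for g in self.groups:
                eyring[g] = EyringBarrier(s=s_vals[g], v_char=float(np.exp(x[i])))
                i += 1
        w = float(np.exp(np.clip(x[i], -80, 80)))
        params = RateParameterSet(base_rates=base, eyring=eyring)
        if self.constrained:
            params = self._complete_rates(params)
        return params, w

    def _complete_rates(self, params: RateParameterSet) -> RateParameterSet:
        model = self.model
        elim = model.constraint_eliminated_rate
        num = den = 1.0
        for s, t in model.cycle_pairs():
            num *= params.base_rates[model.edge(s, t).param]
            bwd = model.edge(t, s).param
            if bwd != elim:
                den *= params.base_rates[bwd]
        params.base_rates[elim] = num / den
        return params


def _predict(model, params, link_kind_link, compiled):
    I_model, P = currents_and_occupations(
        model, params, compiled.V, compiled.a_in, compiled.a_out
    )
    k_model = predict_kOM_batch(link_kind_link, model, P)
    return I_model, k_model


def _residuals(
    model: ModelSpec,
    params: RateParameterSet,
    w: float,
    link: GatingLink,
    compiled: _Compiled,
    config: FitConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """(IV residuals, ln-k_OM residuals) with weights folded in as sqrt."""
    I_model, k_model = _predict(model, params, link.with_w(w), compiled)
    res_iv = np.sqrt(config.weight_current) * (I_model - compiled.I)
    res_iv = np.where(np.isfinite(res_iv), res_iv, _PENALTY)[compiled.iv_mask]
    k_sel = k_model[compiled.kom_mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        lnk_model = np.log(k_sel)
    res_k = np.sqrt(config.weight_rate) * (lnk_model - compiled.lnk[compiled.kom_mask])
    res_k = np.where(np.isfinite(res_k) & (k_sel > 0), res_k, _PENALTY)
    return res_iv, res_k


def global_objective(
    model: ModelSpec,
    params: RateParameterSet,
    w: float,
    link: GatingLink,
    dataset: ExperimentDataset,
    config: FitConfig = FitConfig(),
) -> tuple[float, dict[str, dict[str, float]]]:
    """Error sum and per-curve {iv, kom} residual breakdown (deterministic)."""
    compiled = _Compiled(dataset, config)
    res_iv, res_k = _residuals(model, params, w, link, compiled, config)
    per_curve: dict[str, dict[str, float]] = {
        cid: {"iv": 0.0, "kom": 0.0} for cid in compiled.curve_ids
    }
    ix_iv = compiled.curve_ix[compiled.iv_mask]
    for ci, r in zip(ix_iv, res_iv):
        per_curve[compiled.curve_ids[ci]]["iv"] += float(r) ** 2
    ix_k = compiled.curve_ix[compiled.kom_mask]
    for ci, r in zip(ix_k, res_k):
        per_curve[compiled.curve_ids[ci]]["kom"] += float(r) ** 2
    total = float(np.sum(res_iv**2) + np.sum(res_k**2))
    return total, per_curve


def default_initial_params(model: ModelSpec) -> RateParameterSet:
    """A generic, model-agnostic starting point in the physical rate regime."""
    base = {}
    for e in model.edges:
        base[e.param] = 1e6 if e.kind in ("bind_internal", "bind_external") else 1e8
    v_t = thermal_voltage_mV()
    n_g = max(len(model.eyring_groups()), 1)
    # equal split of the one-charge budget across the cycle's barriers
    eyring = {g: EyringBarrier(s=0.5, v_char=n_g * v_t) for g in model.eyring_groups()}
    return RateParameterSet(base_rates=base, eyring=eyring)


def _initial_w(model, params, link, compiled) -> float:
    """Closed-form w matching the masked k_OM data in the log mean."""
    _, k_unit = _predict(model, params, link.with_w(1.0), compiled)
    k_unit = k_unit[compiled.kom_mask]
    good = np.isfinite(k_unit) & (k_unit > 0)
    if not good.any():
        return 1.0
    return float(np.exp(np.mean(compiled.lnk[compiled.kom_mask][good] - np.log(k_unit[good]))))


def run_global_fit(
    dataset: ExperimentDataset,
    model: ModelSpec,
    link: GatingLink,
    config: FitConfig = FitConfig(),
    init_params: RateParameterSet | None = None,
    init_w: float | None = None,
) -> FitResult:
    """Multi-start simplex global fit with Levenberg-Marquardt polish.

    Restarts perturb the initial guess log-normally (sd ``perturb_sd_log10``
    decades in transformed coordinates); the best candidates are polished on
    the residual vector.  Returns the best parameter set, gating scale w,
    error sum and per-curve residual breakdown.
    """
    compiled = _Compiled(dataset, config)
    transform = ParamTransform(model, config.nernst_constraint, config.T)
    if init_params is None:
        init_params = default_initial_params(model)
    if config.nernst_constraint:
        # make the guess feasible before packing
        init_params = transform.unpack(transform.pack(init_params, 1.0))[0]
    if init_w is None:
        init_w = _initial_w(model, init_params, link, compiled)
    x0 = transform.pack(init_params, init_w)
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p, w = transform.unpack(x)
        res_iv, res_k = _residuals(model, p, w, link, compiled, config)
        return float(np.sum(res_iv**2) + np.sum(res_k**2))

    def resid_vector(x: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        p, w = transform.unpack(x)
        return np.concatenate(_residuals(model, p, w, link, compiled, config))

    rng = np.random.default_rng(config.seed)
    sd = config.perturb_sd_log10 * np.log(10.0)
    starts = [x0] + [
        x0 + rng.normal(0.0, sd, size=x0.size) for _ in range(config.restarts - 1)
    ]
    candidates = []
    for xs in starts:
        res = optimize.minimize(
            objective,
            xs,
            method="Nelder-Mead",
            options={
                "maxfev": config.simplex_maxfev,
                "xatol": config.simplex_xatol,
                "fatol": config.simplex_fatol,
                "adaptive": True,
            },
        )
        candidates.append((float(res.fun), res.x))
    candidates.sort(key=lambda c: c[0])
    restart_errors = [c[0] for c in candidates]
    best_f, best_x = candidates[0]
    polish_improved = False
    if config.polish:
        for f_c, x_c in candidates[: config.polish_top]:
            try:
                sol = optimize.least_squares(
                    resid_vector, x_c, method="lm", max_nfev=config.polish_max_nfev
                )
            except Exception:
                continue
            f_pol = float(np.sum(sol.fun**2))
            if f_pol < best_f:
                best_f, best_x = f_pol, sol.x
                polish_improved = True
    if not np.isfinite(best_f):
        raise RuntimeError("global fit failed: no restart produced a finite error")
    params, w = transform.unpack(best_x)
    error_sum, per_curve = global_objective(model, params, w, link, dataset, config)
    return FitResult(
        params=params,
        w=w,
        link=link.with_w(w),
        error_sum=error_sum,
        per_curve=per_curve,
        n_eval=n_eval,
        restart_errors=restart_errors,
        polish_improved=polish_improved,
        seed=config.seed,
    )


def default_links(model: ModelSpec) -> list[GatingLink]:
    """The candidate gating links for a model: P_m, 1/P_m for every state,
    plus the ratio P4/P3 when both states exist (11 candidates for the
    five-state model)."""
    links = [GatingLink("proportional", s) for s in model.states]
    links += [GatingLink("inverse", s) for s in model.states]
    if "4" in model.states and "3" in model.states:
        links.append(GatingLink("ratio", "4", "3"))
    return links


@dataclass
class ComparisonTable:
    """Per-link best-fit error sums and the winning link."""

    rows: dict[str, float]
    results: dict[str, FitResult]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def argmin(self) -> str:
        return min(self.rows, key=self.rows.get)

    @property
    def ties(self) -> list[str]:
        best = self.rows[self.argmin]
        return [k for k, v in self.rows.items() if v <= best * (1 + 1e-9)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"link": list(self.rows), "error_sum": list(self.rows.values())}
        )
        df["best"] = df["link"] == self.argmin
        return df

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare_gating_links(
    dataset: ExperimentDataset,
    model: ModelSpec,
    links: Sequence[GatingLink] | None = None,
    config: FitConfig = FitConfig(),
    init_params: RateParameterSet | None = None,
) -> ComparisonTable:
    """One independent multi-start global fit per candidate link.

    Each link gets its own deterministic restart seed derived from the
    link label and the config seed, so duplicate link entries reproduce
    identical error sums.  Per-link failures are recorded without aborting
    the table.
    """
    if links is None:
        links = default_links(model)
    rows: dict[str, float] = {}
    results: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for link in links:
        link_seed = (zlib.crc32(link.label.encode()) ^ config.seed) % (2**31 - 1)
        link_config = _with_seed(config, link_seed)
        try:
            fit = run_global_fit(dataset, model, link, link_config, init_params=init_params)
        except Exception as exc:  # record and continue with remaining links
            failures[link.label] = f"{type(exc).__name__}: {exc}"
            continue
        rows[link.label] = fit.error_sum
        results[link.label] = fit
    if not rows:
        raise RuntimeError(f"all link fits failed: {failures}")
    return ComparisonTable(rows=rows, results=results, failures=failures)


def _with_seed(config: FitConfig, seed: int) -> FitConfig:
    from dataclasses import replace

    return replace(config, seed=seed)
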