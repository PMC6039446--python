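"""Synthetic study generator: design, ground truth, noisy curves, traces.

No raw recordings ship with this project, so every pipeline stage is
exercised on synthetic data whose study conditions mirror the experimental
design: 18 condition series (6 symmetric KCl concentrations, 6 internal
variations at fixed 100 mM external, 6 external variations at fixed 100 mM
internal), each measured on the voltage grid -160..+160 mV in 20 mV steps,
with 3 replicates, multiplicative rate noise below 25 % and additive
current noise below 1 pA.

The ground-truth parameter set is chosen by the implementers to reproduce
the qualitative phenomenology of the system (near-linear symmetric IV
around 100 mM, exponential rise of the closing rate at negative voltages,
left shift with internal K+, insensitivity to external K+ at negative
voltages); it is synthetic and is not a fitted parameter set from any
experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .dataset import ConditionCurve, ExperimentDataset
from .fastgating import GatingScheme, TraceConfig, TraceRecord, render_filtered_trace, simulate_events
from .gating import GatingLink, predict_kOM_batch
from .kinetics import currents_and_occupations
from .models import Condition, ModelSpec, RateParameterSet, EyringBarrier, load_model_spec
from .nernst import apply_nernst_constraint

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "OFDuty",
    "default_design",
    "default_ground_truth",
    "generate_dataset",
    "generate_trace_fixture",
    "write_trace_fixture",
    "load_trace_fixture",
]

VOLTAGE_GRID = np.arange(-160.0, 161.0, 20.0)  # 17 points

SYMMETRIC_MM = (50.0, 100.0, 250.0, 500.0, 1000.0, 1500.0)
VARIED_MM = (50.0, 250.0, 500.0, 750.0, 1000.0, 1500.0)
FIXED_MM = 100.0


@dataclass(frozen=True)
class StudyDesign:
    """Condition series, voltage grid, replication and noise levels."""

    series: tuple[tuple[str, float, float], ...]  # (series_id, c_in, c_out)
    voltages: np.ndarray = field(default_factory=lambda: VOLTAGE_GRID.copy())
    n_rep: int = 3
    cv_rates: float = 0.15  # lognormal CV on rate constants, capped at 0.25
    sd_current_pA: float = 0.5  # additive Gaussian sd on currents, capped at 1.0

    def __post_init__(self) -> None:
        if self.cv_rates < 0 or self.cv_rates > 0.25:
            raise ValueError("rate-constant CV must lie in [0, 0.25]")
        if self.sd_current_pA < 0 or self.sd_current_pA > 1.0:
            raise ValueError("current noise sd must lie in [0, 1] pA")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")

    @property
    def n_curves(self) -> int:
        """Curves entering the global objective: one IV + one k_OM(V) per series."""
        return 2 * len(self.series)

    def groups(self) -> dict[str, list[tuple[str, float, float]]]:
        out: dict[str, list[tuple[str, float, float]]] = {
            "symmetric": [],
            "internal": [],
            "external": [],
        }
        for sid, c_in, c_out in self.series:
            out[sid.split(":")[0]].append((sid, c_in, c_out))
        return out


def default_design(n_rep: int = 3, cv_rates: float = 0.15, sd_current_pA: float = 0.5) -> StudyDesign:
    """The default 18-series symmetric/asymmetric KCl design.

    Symmetric series at 50/100/250/500/1000/1500 mM; internal-varied series
    at 50/250/500/750/1000/1500 mM with external fixed at 100 mM; and the
    mirror-image external-varied series.  The 100/100 mM condition appears
    exactly once (in the symmetric set).
    """
    series: list[tuple[str, float, float]] = []
    for c in SYMMETRIC_MM:
        series.append((f"symmetric:{c:g}", c, c))
    for c in VARIED_MM:
        series.append((f"internal:{c:g}", c, FIXED_MM))
    for c in VARIED_MM:
        series.append((f"external:{c:g}", FIXED_MM, c))
    return StudyDesign(
        series=tuple(series), n_rep=n_rep, cv_rates=cv_rates, sd_current_pA=sd_current_pA
    )


@dataclass(frozen=True)
class OFDuty:
    """O-F duty factor linking the cycle current to the effective I_OF.

    Defaults to the stationary O-F averaging form k_FO/(k_OF+k_FO) with
    voltage-independent O-F rates; ``v_slope`` (per mV, default 0) adds a
    mild exponential voltage dependence to k_OF when wanted.
    """

    k_OF: float = 3e4
    k_FO: float = 1e6
    v_slope: float = 0.0

    def __call__(self, V: np.ndarray) -> np.ndarray:
        k_of = self.k_OF * np.exp(self.v_slope * np.asarray(V, dtype=float))
        return self.k_FO / (k_of + self.k_FO)


@dataclass(frozen=True)
class KMOCurve:
    """Phenomenological opening-rate curve k_MO(V) = k0 * exp(V / v_char).

    The opening rate is carried through the data model for completeness but
    is never linked to filter occupancies; a smooth positive curve with a
    shallow voltage dependence opposite to the closing rate suffices.
    """

    k0: float = 1.2e4
    v_char: float = 300.0

    def __call__(self, V: np.ndarray) -> np.ndarray:
        return self.k0 * np.exp(np.asarray(V, dtype=float) / self.v_char)


@dataclass
class GroundTruth:
    """Generating model, parameters and gating link of the synthetic study."""

    model_name: str
    params: RateParameterSet
    link: GatingLink
    of_duty: OFDuty = OFDuty()
    kmo: KMOCurve = KMOCurve()
    provenance: str = (
        "synthetic ground truth chosen to reproduce the qualitative "
        "phenomenology of the system; not fitted to any experiment"
    )

    def model(self) -> ModelSpec:
        return load_model_spec(self.model_name)


def default_ground_truth() -> GroundTruth:
    """Thermodynamically consistent truth on the five-state model, P4/P3 link."""
    model = load_model_spec("five_state_roux")
    params = RateParameterSet(
        base_rates={
            "k12": 2.0e6,  # s^-1 mM^-1, internal binding
            "k21": 2.0e8,  # replaced by the Nernst constraint below
            "k23": 2.3e8,
            "k32": 2.2e8,
            "k34": 1.1e8,
            "k43": 7.5e8,
            "k45": 9.0e8,
            "k54": 2.0e6,  # s^-1 mM^-1, external binding
            "k51": 5.0e8,
            "k15": 3.3e8,
        },
        eyring={
            "23": EyringBarrier(s=0.20, v_char=90.0),
            "51": EyringBarrier(s=0.72, v_char=36.0),  # v_char reset by constraint
        },
    )
    params = apply_nernst_constraint(model, params, adjust_group="51")
    link = GatingLink("ratio", "4", "3", w=3.0e4)
    return GroundTruth(model_name="five_state_roux", params=params, link=link)


def _conditions(c_in: float, c_out: float, voltages: np.ndarray) -> list[Condition]:
    return [Condition(V=float(v), c_in=c_in, c_out=c_out) for v in voltages]


def generate_dataset(
    truth: GroundTruth,
    design: StudyDesign | None = None,
    noise: bool = True,
    seed: int | np.random.Generator | None = 0,
) -> ExperimentDataset:
    """Synthesise the per-condition summary dataset from a ground truth.

    Per series: the effective current I_OF is the cycle current scaled by
    the O-F duty factor, the closing rate comes from the gating link on the
    stationary occupations, and the opening rate from the phenomenological
    k_MO curve.  With noise on, each of ``n_rep`` replicates receives
    multiplicative log-normal noise (configured CV) on rate constants and
    additive Gaussian noise on currents; replicates are then averaged and
    their sample sd reported.  Fully reproducible under ``seed``.
    """
    if design is None:
        design = default_design()
    model = truth.model()
    truth.params.require(model)
    rng = np.random.default_rng(seed)
    curves = []
    for sid, c_in, c_out in design.series:
        conds = _conditions(c_in, c_out, design.voltages)
        V = np.array([c.V for c in conds])
        a_in = np.array([c.a_in for c in conds])
        a_out = np.array([c.a_out for c in conds])
        I_cycle, P = currents_and_occupations(model, truth.params, V, a_in, a_out)
        I_of = I_cycle * truth.of_duty(V)
        k_om = predict_kOM_batch(truth.link, model, P)
        k_mo = truth.kmo(V)
        if noise and (design.cv_rates > 0 or design.sd_current_pA > 0):
            sigma = np.sqrt(np.log1p(design.cv_rates**2))
            reps_I = np.stack(
                [I_of + rng.normal(0.0, design.sd_current_pA, size=V.shape) for _ in range(design.n_rep)]
            )
            reps_kom = np.stack(
                [k_om * rng.lognormal(-0.5 * sigma**2, sigma, size=V.shape) for _ in range(design.n_rep)]
            )
            reps_kmo = np.stack(
                [k_mo * rng.lognormal(-0.5 * sigma**2, sigma, size=V.shape) for _ in range(design.n_rep)]
            )
            I_val, I_sd = reps_I.mean(axis=0), reps_I.std(axis=0, ddof=1)
            kom_val, kom_sd = reps_kom.mean(axis=0), reps_kom.std(axis=0, ddof=1)
            kmo_val, kmo_sd = reps_kmo.mean(axis=0), reps_kmo.std(axis=0, ddof=1)
            n_rep = design.n_rep
        else:
            I_val, I_sd = I_of, np.zeros_like(V)
            kom_val, kom_sd = k_om, np.zeros_like(V)
            kmo_val, kmo_sd = k_mo, np.zeros_like(V)
            n_rep = 1
        curves.append(
            ConditionCurve(
                series_id=sid,
                c_in=c_in,
                c_out=c_out,
                V=V,
                I_OF=I_val,
                I_sd=I_sd,
                k_OM=kom_val,
                k_OM_sd=kom_sd,
                k_MO=kmo_val,
                k_MO_sd=kmo_sd,
                n_rep=n_rep,
            )
        )
    return ExperimentDataset(curves)


def generate_trace_fixture(
    scheme: GatingScheme,
    duration: float,
    config: TraceConfig = TraceConfig(),
    seed: int | None = 0,
) -> tuple[TraceRecord, dict]:
    """Simulate and render one trace fixture plus its ground-truth sidecar."""
    events = simulate_events(scheme, duration, seed)
    trace = render_filtered_trace(events, scheme, config, seed=seed)
    sidecar = {
        "scheme": scheme.to_dict(),
        "duration_s": duration,
        "sampling_rate_Hz": config.sampling_rate,
        "filter": {"type": "bessel", "order": config.filter_order, "cutoff_Hz": config.filter_cutoff},
        "fine_dt_s": config.fine_dt,
        "baseline_sd_pA": config.baseline_sd,
        "seed": seed,
    }
    return trace, sidecar


def write_trace_fixture(trace: TraceRecord, sidecar: dict, stem: str | Path) -> None:
    """Store a fixture as CSV (time, current) with a JSON sidecar."""
    stem = Path(stem)
    t = np.arange(len(trace.samples)) / trace.config.sampling_rate
    pd.DataFrame({"time_s": t, "current_pA": trace.samples}).to_csv(
        stem.with_suffix(".csv"), index=False
    )
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_trace_fixture(stem: str | Path) -> tuple[TraceRecord, dict]:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".csv"))
    config = TraceConfig(
        sampling_rate=float(sidecar["sampling_rate_Hz"]),
        filter_cutoff=float(sidecar["filter"]["cutoff_Hz"]),
        filter_order=int(sidecar["filter"]["order"]),
        fine_dt=float(sidecar["fine_dt_s"]),
        baseline_sd=float(sidecar["baseline_sd_pA"]),
    )
    scheme = GatingScheme.from_dict(sidecar["scheme"])
    trace = TraceRecord(
        samples=df["current_pA"].to_numpy(float),
        config=config,
        scheme=scheme,
        seed=sidecar.get("seed"),
    )
    return trace, sidecar
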