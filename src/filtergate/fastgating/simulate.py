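"""Stochastic simulation and band-limited rendering of gating traces.

Event simulation follows the standard continuous-time Markov recipe: for
each gating event two random numbers decide the sink state (with
probability proportional to the branch rates) and the exponential dwell
time in the source state.  The star topology (closed states return only to
O) lets the whole event sequence be drawn vectorised.

Rendering mimics the recording chain: the piecewise-constant current
(I_true in O, 0 pA in any closed state) is laid out on an internal fine
grid (default 1 us), passed through a digital 4-pole Bessel low-pass
(bilinear transform with cutoff prewarping, -3 dB magnitude normalisation,
DC gain forced to exactly 1) and decimated to the sampling rate (default
5 kHz, cutoff 1 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal

from .scheme import GatingScheme

__all__ = [
    "EventSequence",
    "TraceConfig",
    "TraceRecord",
    "simulate_events",
    "render_filtered_trace",
    "design_bessel_sos",
    "filter_impulse_response",
]

STATE_O, STATE_S, STATE_M, STATE_F = 0, 1, 2, 3
STATE_NAMES = ("O", "S", "M", "F")
_CLOSED = {STATE_S: "k_SO", STATE_M: "k_MO", STATE_F: "k_FO"}


class EventSequence(NamedTuple):
    """Alternating gating events: integer state codes and dwell times (s)."""

    states: np.ndarray  # int8 codes, STATE_*
    dwells: np.ndarray  # float64 seconds
    absorbed: bool  # True when the last event has no exit (infinite dwell)


@dataclass(frozen=True)
class TraceConfig:
    """Recording-chain parameters.

    ``fine_dt`` is the internal rendering step; the renderer refuses schemes
    whose shortest expected dwell spans fewer than ``min_dwell_steps`` steps,
    because microsecond gating must be laid out before filtering.
    """

    sampling_rate: float = 5000.0  # Hz
    filter_cutoff: float = 1000.0  # Hz, -3 dB of the 4-pole Bessel
    filter_order: int = 4
    fine_dt: float = 1e-6  # s
    baseline_sd: float = 1.0  # pA, Gaussian baseline noise of the set-up
    min_dwell_steps: int = 5

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * self.filter_cutoff:
            raise ValueError("sampling rate must exceed twice the filter cutoff")
        if self.fine_dt <= 0:
            raise ValueError("fine_dt must be positive")


@dataclass
class TraceRecord:
    """A sampled, filtered (noise-free) current trace plus its provenance."""

    samples: np.ndarray  # pA at config.sampling_rate
    config: TraceConfig
    scheme: GatingScheme | None = None
    seed: int | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.config.sampling_rate


def simulate_events(
    scheme: GatingScheme,
    duration: float,
    seed: int | np.random.Generator | None = None,
) -> EventSequence:
    """Draw the gating event sequence covering at least ``duration`` seconds.

    The start state is drawn from the stationary distribution of the scheme
    (a closed state with no return rate is absorbing and becomes the start
    with probability one).  Dwell times are exponential with the source
    state's total exit rate; the sink is chosen with probability
    proportional to the branch rates.  States with no exit yield a single
    flagged event with infinite dwell.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    # Per-role child streams (start state / open dwells / sink choices /
    # closed dwells).  Dwells are standard exponentials scaled by the
    # current rates and sinks are fixed uniforms cut by the branch
    # probabilities, so under a fixed seed the whole event sequence varies
    # smoothly with the rate constants - the common-random-numbers
    # property the histogram fitter relies on.
    rng = np.random.default_rng(seed)
    g_start, g_open, g_sink, g_closed = rng.spawn(4)
    k_exit = scheme.open_exit_rate
    if k_exit == 0.0:
        return EventSequence(
            states=np.array([STATE_O], dtype=np.int8),
            dwells=np.array([np.inf]),
            absorbed=True,
        )
    branch = np.array([scheme.k_OS, scheme.k_OM, scheme.k_OF])
    sink_codes = np.array([STATE_S, STATE_M, STATE_F], dtype=np.int8)
    p_branch = branch / k_exit
    return_rates = np.array([scheme.k_SO, scheme.k_MO, scheme.k_FO])

    # a closed state that is entered but never left absorbs the chain
    absorbing = [c for c, b, r in zip(sink_codes, branch, return_rates) if b > 0 and r == 0]
    if absorbing:
        return EventSequence(
            states=np.array([absorbing[0]], dtype=np.int8),
            dwells=np.array([np.inf]),
            absorbed=True,
        )
    # stationary start: occupancies proportional to branch prob x mean dwell
    closed_occ = np.where(return_rates > 0, branch / np.where(return_rates > 0, return_rates, 1.0), 0.0)
    occ = np.concatenate(([1.0], closed_occ))  # relative to p_O = 1
    occ = occ / occ.sum()
    u_start = g_start.random()
    start_ix = int(np.searchsorted(np.cumsum(occ), u_start, side="right"))
    start_codes = np.concatenate(([STATE_O], sink_codes))
    start_code = int(start_codes[min(start_ix, 3)])

    states_chunks: list[np.ndarray] = []
    dwells_chunks: list[np.ndarray] = []
    t_accum = 0.0
    if start_code != STATE_O:
        k_back = float(return_rates[list(sink_codes).index(start_code)])
        first_dwell = g_start.exponential(1.0 / k_back)
        states_chunks.append(np.array([start_code], dtype=np.int8))
        dwells_chunks.append(np.array([first_dwell]))
        t_accum += first_dwell
    mean_closed = float(np.sum(np.where(return_rates > 0, p_branch / np.where(return_rates > 0, return_rates, 1.0), 0.0)))
    pair_mean = 1.0 / k_exit + mean_closed
    cum_branch = np.cumsum(p_branch)
    while t_accum < duration:
        remaining = duration - t_accum
        n_pairs = max(64, int(1.1 * remaining / pair_mean) + 16)
        n_pairs = min(n_pairs, 4_000_000)
        o_dwells = g_open.exponential(1.0, size=n_pairs) / k_exit
        sinks_idx = np.searchsorted(cum_branch, g_sink.random(size=n_pairs), side="right")
        sinks_idx = np.minimum(sinks_idx, 2)
        closed_dwells = g_closed.exponential(1.0, size=n_pairs) / return_rates[sinks_idx]
        states = np.empty(2 * n_pairs, dtype=np.int8)
        states[0::2] = STATE_O
        states[1::2] = sink_codes[sinks_idx]
        dwells = np.empty(2 * n_pairs)
        dwells[0::2] = o_dwells
        dwells[1::2] = closed_dwells
        states_chunks.append(states)
        dwells_chunks.append(dwells)
        t_accum += float(dwells.sum())
    states = np.concatenate(states_chunks)
    dwells = np.concatenate(dwells_chunks)
    # trim to the first event crossing `duration`
    cum = np.cumsum(dwells)
    stop = int(np.searchsorted(cum, duration)) + 1
    return EventSequence(states=states[:stop], dwells=dwells[:stop], absorbed=False)


def design_bessel_sos(order: int, cutoff: float, fs: float) -> np.ndarray:
    """Digital Bessel low-pass as second-order sections, DC gain exactly 1.

    Bilinear transform of the analog prototype with cutoff prewarping
    (scipy's discretisation), magnitude-normalised so that ``cutoff`` is the
    -3 dB point, then rescaled for exact unit DC gain.
    """
    sos = signal.bessel(order, cutoff, btype="low", norm="mag", output="sos", fs=fs)
    dc = np.prod([s[:3].sum() / s[3:].sum() for s in sos])
    sos = sos.copy()
    sos[0, :3] /= dc
    return sos


def filter_impulse_response(config: TraceConfig, n: int | None = None) -> np.ndarray:
    """Sampled impulse response of the rendering filter on the fine grid."""
    fs = 1.0 / config.fine_dt
    sos = design_bessel_sos(config.filter_order, config.filter_cutoff, fs)
    if n is None:
        n = int(20 * fs / config.filter_cutoff)
    x = np.zeros(n)
    x[0] = 1.0
    return signal.sosfilt(sos, x)


def _check_resolvable(scheme: GatingScheme, config: TraceConfig) -> None:
    dwells = [1.0 / scheme.open_exit_rate] if scheme.open_exit_rate > 0 else []
    for code, back in _CLOSED.items():
        k_back = getattr(scheme, back)
        k_to = getattr(scheme, {"k_SO": "k_OS", "k_MO": "k_OM", "k_FO": "k_OF"}[back])
        if k_to > 0 and k_back > 0:
            dwells.append(1.0 / k_back)
    if dwells and min(dwells) < config.min_dwell_steps * config.fine_dt:
        raise ValueError(
            f"shortest expected dwell {min(dwells):.3g} s spans fewer than "
            f"{config.min_dwell_steps} fine-grid steps of {config.fine_dt:.3g} s; "
            "reduce fine_dt (TraceConfig) to resolve the fastest gating process"
        )


def render_filtered_trace(
    events: EventSequence,
    scheme: GatingScheme,
    config: TraceConfig = TraceConfig(),
    seed: int | None = None,
) -> TraceRecord:
    """Render events as a filtered, decimated (noise-free) current trace.

    The current is I_true in O and 0 pA in S/M/F, laid out on the fine grid
    with event boundaries placed by rounding cumulative event times (so
    long-run timing stays unbiased), filtered with the digital Bessel
    low-pass and decimated to the sampling rate.
    """
    if len(events.states) == 0:
        raise ValueError("empty event sequence")
    _check_resolvable(scheme, config)
    dwells = events.dwells
    if events.absorbed:
        # replace the trailing infinite dwell with a 20x-filter-settling tail
        dwells = dwells.copy()
        dwells[-1] = 20.0 / config.filter_cutoff
    cum = np.cumsum(dwells)
    edges = np.round(cum / config.fine_dt).astype(np.int64)
    counts = np.diff(np.concatenate(([0], edges)))
    keep = counts > 0
    levels = np.where(events.states == STATE_O, scheme.i_true, 0.0)
    fine = np.repeat(levels[keep], counts[keep])
    if fine.size == 0:
        raise ValueError("all events shorter than the fine grid step")
    fs_fine = 1.0 / config.fine_dt
    sos = design_bessel_sos(config.filter_order, config.filter_cutoff, fs_fine)
    zi = signal.sosfilt_zi(sos) * fine[0]
    filtered, _ = signal.sosfilt(sos, fine, zi=zi)
    decim = int(round(fs_fine / config.sampling_rate))
    if decim < 1:
        raise ValueError("fine grid coarser than the sampling interval")
    samples = filtered[::decim].copy()
    return TraceRecord(samples=samples, config=config, scheme=scheme, seed=seed)
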