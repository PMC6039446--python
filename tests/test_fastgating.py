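import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal, stats

from filtergate.fastgating import (
    GatingScheme,
    TraceConfig,
    amplitude_histogram,
    analytic_time_averages,
    apparent_current,
    design_bessel_sos,
    render_filtered_trace,
    simulate_events,
)
from filtergate.fastgating.simulate import (
    STATE_F,
    STATE_M,
    STATE_O,
    STATE_S,
    EventSequence,
    filter_impulse_response,
)

OM_SCHEME = GatingScheme(k_OM=1e4, k_MO=1e4, i_true=-14.0)


def block_standard_error(samples, n_blocks=20):
    blocks = np.array_split(samples, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)


class TestSimulateEvents:
    def test_single_branch_always_goes_to_M(self):
        ev = simulate_events(OM_SCHEME, 0.5, seed=0)
        closed = ev.states[ev.states != STATE_O]
        assert np.all(closed == STATE_M)

    def test_mean_open_dwell_matches_total_exit_rate(self):
        scheme = GatingScheme(k_OS=2e2, k_OM=8e3, k_OF=2e3, k_SO=1e2, k_MO=1e4, k_FO=5e5, i_true=10.0)
        ev = simulate_events(scheme, 40.0, seed=1)
        o_dwells = ev.dwells[ev.states == STATE_O]
        assert len(o_dwells) > 1e5
        expected = 1.0 / scheme.open_exit_rate
        se = o_dwells.std(ddof=1) / np.sqrt(len(o_dwells))
        assert abs(o_dwells.mean() - expected) < 3 * se

    def test_branching_fractions_within_binomial_ci(self):
        scheme = GatingScheme(k_OS=2e2, k_OM=8e3, k_OF=2e3, k_SO=1e2, k_MO=1e4, k_FO=5e5, i_true=10.0)
        ev = simulate_events(scheme, 40.0, seed=2)
        closed = ev.states[ev.states != STATE_O]
        n = len(closed)
        p_expected = scheme.k_OM / scheme.open_exit_rate
        p_hat = np.mean(closed == STATE_M)
        assert abs(p_hat - p_expected) < 3 * np.sqrt(p_expected * (1 - p_expected) / n)

    @pytest.mark.parametrize(
        "state_code,rate_attr",
        [(STATE_O, "open_exit_rate"), (STATE_M, "k_MO")],
    )
    def test_dwell_distributions_are_exponential(self, state_code, rate_attr):
        # Kolmogorov-Smirnov at alpha = 0.01 on 1e4 dwells per state
        ev = simulate_events(OM_SCHEME, 3.0, seed=3)
        dwells = ev.dwells[ev.states == state_code][:10_000]
        assert len(dwells) == 10_000
        rate = getattr(OM_SCHEME, rate_attr) if rate_attr != "open_exit_rate" else OM_SCHEME.open_exit_rate
        res = stats.kstest(dwells, "expon", args=(0, 1.0 / rate))
        assert res.pvalue > 0.01

    def test_no_exit_from_open_returns_flagged_infinite_dwell(self):
        ev = simulate_events(GatingScheme(i_true=5.0), 1.0, seed=0)
        assert ev.absorbed and len(ev.states) == 1 and np.isinf(ev.dwells[0])

    def test_absorbing_closed_state_truncates(self):
        ev = simulate_events(GatingScheme(k_OM=1e4, k_MO=0.0, i_true=5.0), 1.0, seed=0)
        assert ev.absorbed
        assert ev.states[-1] == STATE_M and np.isinf(ev.dwells[-1])

    def test_reproducible_under_seed(self):
        a = simulate_events(OM_SCHEME, 1.0, seed=9)
        b = simulate_events(OM_SCHEME, 1.0, seed=9)
        assert np.array_equal(a.states, b.states) and np.array_equal(a.dwells, b.dwells)


class TestFilter:
    def test_dc_gain_is_exactly_one(self):
        sos = design_bessel_sos(4, 1000.0, 1e6)
        dc = np.prod([s[:3].sum() / s[3:].sum() for s in sos])
        assert dc == pytest.approx(1.0, abs=1e-9)

    def test_minus_3dB_point_within_5pct_of_cutoff(self):
        fs = 1e6
        cutoff = 1000.0
        sos = design_bessel_sos(4, cutoff, fs)
        w, h = signal.sosfreqz(sos, worN=np.linspace(0.5 * cutoff, 2 * cutoff, 2001), fs=fs)
        f_3db = w[np.argmin(np.abs(np.abs(h) - 1 / np.sqrt(2)))]
        assert abs(f_3db - cutoff) / cutoff < 0.05

    def test_constant_open_renders_flat_at_i_true(self):
        scheme = GatingScheme(k_OM=1.0, k_MO=1e4, i_true=-12.0)
        ev = EventSequence(states=np.array([STATE_O], dtype=np.int8), dwells=np.array([2.0]), absorbed=False)
        trace = render_filtered_trace(ev, scheme, TraceConfig())
        assert np.allclose(trace.samples, -12.0, atol=1e-9)

    def test_long_closure_settles_to_closed_level(self):
        scheme = GatingScheme(k_OM=1.0, k_MO=1.0, i_true=-12.0)
        ev = EventSequence(
            states=np.array([STATE_O, STATE_M, STATE_O], dtype=np.int8),
            dwells=np.array([0.1, 0.05, 0.1]),
            absorbed=False,
        )
        trace = render_filtered_trace(ev, scheme, TraceConfig())
        assert trace.samples.min() > -12.5
        assert np.any(np.abs(trace.samples) < 1e-6)

    def test_brief_closure_attenuated_and_matches_convolution_oracle(self):
        # a 100 us closure under a 1 kHz Bessel cannot reach the closed level;
        # the rendered trace must match direct convolution of the step
        # sequence with the sampled impulse response
        config = TraceConfig()
        scheme = GatingScheme(k_OM=1.0, k_MO=1.0, i_true=-10.0)
        dwells = np.array([0.04, 100e-6, 0.04])
        ev = EventSequence(
            states=np.array([STATE_O, STATE_M, STATE_O], dtype=np.int8),
            dwells=dwells,
            absorbed=False,
        )
        trace = render_filtered_trace(ev, scheme, config)
        # attenuation: minimum well above the closed level 0 is impossible
        # (negative current), so check magnitude: |min| stays below |i_true|
        # and the excursion toward 0 is partial
        assert trace.samples.min() < -9.9
        assert trace.samples.max() < -2.0  # nowhere near the closed level 0
        # oracle: convolve the fine-grid step sequence with the impulse response
        n_fine = int(round(dwells.sum() / config.fine_dt))
        fine = np.full(n_fine, -10.0)
        i0 = int(round(0.04 / config.fine_dt))
        i1 = int(round((0.04 + 100e-6) / config.fine_dt))
        fine[i0:i1] = 0.0
        imp = filter_impulse_response(config)
        # pad with the initial level to emulate the filter's settled state
        pad = len(imp)
        padded = np.concatenate([np.full(pad, -10.0), fine])
        conv = signal.fftconvolve(padded, imp, mode="full")[pad : pad + n_fine]
        decim = int(round(1.0 / (config.sampling_rate * config.fine_dt)))
        oracle = conv[::decim]
        m = min(len(oracle), len(trace.samples))
        assert np.allclose(trace.samples[:m], oracle[:m], atol=1e-6)

    def test_refuses_unresolvable_fast_gating(self):
        # mean F dwell of 2 us spans < 5 steps of the default 1 us grid
        scheme = GatingScheme(k_OM=1e3, k_MO=1e4, k_OF=1e4, k_FO=5e5, i_true=1.0)
        ev = simulate_events(scheme, 0.01, seed=0)
        with pytest.raises(ValueError, match="fine"):
            render_filtered_trace(ev, scheme, TraceConfig(fine_dt=4e-6))


class TestHistogram:
    def test_constant_trace_gives_gaussian_peak_at_level(self):
        scheme = GatingScheme(k_OM=1.0, k_MO=1e4, i_true=16.0)
        ev = EventSequence(states=np.array([STATE_O], dtype=np.int8), dwells=np.array([2.0]), absorbed=False)
        trace = render_filtered_trace(ev, scheme, TraceConfig(baseline_sd=1.0))
        hist = amplitude_histogram(trace)
        centers = hist.centers
        mean = np.sum(centers * hist.counts) / hist.total
        sd = np.sqrt(np.sum((centers - mean) ** 2 * hist.counts) / hist.total)
        assert mean == pytest.approx(16.0, abs=0.05)
        assert sd == pytest.approx(1.0, abs=0.05)

    def test_total_count_preserved_by_noise_convolution(self):
        ev = simulate_events(OM_SCHEME, 2.0, seed=4)
        trace = render_filtered_trace(ev, OM_SCHEME, TraceConfig(baseline_sd=1.0))
        hist = amplitude_histogram(trace)
        assert hist.total == pytest.approx(len(trace.samples), rel=1e-12)

    def test_underresolved_kernel_warns(self):
        ev = simulate_events(OM_SCHEME, 0.5, seed=4)
        trace = render_filtered_trace(ev, OM_SCHEME, TraceConfig(baseline_sd=1.0))
        wide = np.arange(trace.samples.min() - 6.0, trace.samples.max() + 6.0, 2.0)
        with pytest.warns(UserWarning, match="under-resolved"):
            amplitude_histogram(trace, bins=wide)

    def test_slow_two_state_peak_areas_match_occupancies(self):
        # gating much slower than the filter: two clean peaks whose areas
        # reflect the stationary occupancies of O and M
        scheme = GatingScheme(k_OM=300.0, k_MO=700.0, i_true=-12.0)
        ev = simulate_events(scheme, 30.0, seed=5)
        trace = render_filtered_trace(ev, scheme, TraceConfig(baseline_sd=0.5))
        hist = amplitude_histogram(trace)
        centers = hist.centers
        open_area = hist.counts[centers < -6.0].sum() / hist.total
        p_open = scheme.k_MO / (scheme.k_OM + scheme.k_MO)
        assert open_area == pytest.approx(p_open, abs=0.04)


class TestApparentCurrent:
    def test_constant_trace(self):
        scheme = GatingScheme(k_OM=1.0, k_MO=1e4, i_true=16.0)
        ev = EventSequence(states=np.array([STATE_O], dtype=np.int8), dwells=np.array([1.0]), absorbed=False)
        trace = render_filtered_trace(ev, scheme, TraceConfig())
        assert apparent_current(trace) == pytest.approx(16.0, abs=1e-9)

    def test_symmetric_fast_two_state_halves_current(self):
        ev = simulate_events(OM_SCHEME, 20.0, seed=6)
        trace = render_filtered_trace(ev, OM_SCHEME, TraceConfig())
        assert apparent_current(trace) == pytest.approx(-7.0, abs=0.15)

    def test_matches_analytic_within_monte_carlo_error(self):
        # ~2.5 us mean F dwells need a finer rendering grid than the default
        scheme = GatingScheme(k_OM=6e3, k_MO=1.2e4, k_OF=5e4, k_FO=4e5, i_true=-14.0)
        ev = simulate_events(scheme, 20.0, seed=7)
        trace = render_filtered_trace(ev, scheme, TraceConfig(fine_dt=0.4e-6))
        i_app = apparent_current(trace)
        expected = analytic_time_averages(scheme).i_app
        se = block_standard_error(trace.samples)
        assert abs(i_app - expected) < 3 * se

    def test_short_trace_rejected(self):
        trace = render_filtered_trace(
            EventSequence(np.array([STATE_O], dtype=np.int8), np.array([1e-3]), False),
            GatingScheme(k_OM=1.0, k_MO=1e4, i_true=1.0),
            TraceConfig(),
        )
        with pytest.raises(ValueError):
            apparent_current(trace)


class TestAnalyticAverages:
    def test_no_fast_gating_keeps_i_of_at_i_true(self):
        d = analytic_time_averages(GatingScheme(k_OM=1e4, k_MO=1e4, i_true=-14.0))
        assert d.i_of == -14.0
        assert d.i_app == pytest.approx(-7.0)

    def test_balanced_fast_gate_halves_i_of(self):
        d = analytic_time_averages(GatingScheme(k_OF=2e5, k_FO=2e5, i_true=-14.0))
        assert d.i_of == pytest.approx(-7.0)

    def test_degenerate_scheme_rejected(self):
        with pytest.raises(ValueError, match="absorbing"):
            analytic_time_averages(GatingScheme(k_OF=1e5, k_FO=0.0, i_true=1.0))

    @given(
        st.floats(min_value=0, max_value=2e4),
        st.floats(min_value=1e3, max_value=2e4),
        st.floats(min_value=0, max_value=2e5),
        st.floats(min_value=1e4, max_value=1e6),
    )
    def test_current_magnitude_ordering(self, k_om, k_mo, k_of, k_fo):
        # |I_app| <= |I_OF| <= |I_true| for any non-negative rates
        d = analytic_time_averages(
            GatingScheme(k_OM=k_om, k_MO=k_mo, k_OF=k_of, k_FO=k_fo, i_true=-14.0)
        )
        assert abs(d.i_app) <= abs(d.i_of) + 1e-12
        assert abs(d.i_of) <= abs(d.i_true) + 1e-12
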