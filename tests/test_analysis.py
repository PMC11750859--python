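import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mossyfiber.analysis import (
    afterdischarge_summary,
    annotate_half_durations,
    derivative_trace,
    detect_spikes,
    half_duration,
    latency_order,
    rising_phase_dvdt_peaks,
)
from mossyfiber.fixtures import FixtureSpec, make_spike_train_trace
from mossyfiber.traces import TraceSet


def _fixture(**kw):
    spec = FixtureSpec(**kw)
    return make_spike_train_trace(spec)


class TestDetectSpikes:
    def test_recovers_template_spike_times_within_one_sample(self):
        times = (10.0, 25.0, 40.0, 55.0, 70.0)
        trace, truth = _fixture(spike_times_ms=times, dt_ms=0.1)
        evs = detect_spikes(trace.time_ms, trace["fixture"])
        assert len(evs) == 5
        for ev, t_true in zip(evs, times):
            assert abs(ev.t_peak_ms - t_true) <= trace.dt_ms
            assert abs(ev.v_peak_mv - 20.0) < 0.5
            assert abs(ev.v_baseline_mv + 80.0) < 0.5

    def test_constant_trace_yields_no_events(self):
        t = np.arange(0.0, 100.0, 0.1)
        assert detect_spikes(t, np.full_like(t, -80.0)) == []

    def test_subthreshold_oscillation_yields_no_events(self):
        t = np.arange(0.0, 100.0, 0.1)
        v = -55.0 + 25.0 * np.sin(2 * np.pi * t / 20.0)  # peaks at -30
        assert detect_spikes(t, v, threshold_mv=-20.0) == []

    def test_refractory_merges_rapid_rebounds(self):
        t = np.arange(0.0, 10.0, 0.01)
        v = np.full_like(t, -80.0)
        # two crossings 1 ms apart: second is inside the 2 ms refractory
        v[(t > 3.0) & (t < 3.4)] = 0.0
        v[(t > 4.0) & (t < 4.4)] = 0.0
        assert len(detect_spikes(t, v)) == 1

    @settings(derandomize=True, max_examples=25)
    @given(thr=st.floats(-40.0, 15.0))
    def test_raising_threshold_never_adds_events(self, thr):
        trace, _ = _fixture(spike_times_ms=(10.0, 30.0, 50.0),
                            noise_sd_mv=1.0, seed=3)
        t, v = trace.time_ms, trace["fixture"]
        n_lo = len(detect_spikes(t, v, threshold_mv=thr))
        n_hi = len(detect_spikes(t, v, threshold_mv=thr + 5.0))
        assert n_hi <= n_lo


class TestHalfDuration:
    def test_triangular_spike_geometry(self):
        # baseline -80, peak +20, total base width 2 ms -> half-width 1 ms
        trace, truth = _fixture(spike_times_ms=(20.0,), template="triangular",
                                width_ms=2.0, dt_ms=0.01)
        ev = detect_spikes(trace.time_ms, trace["fixture"])[0]
        hd = half_duration(trace.time_ms, trace["fixture"], ev)
        assert hd == pytest.approx(1.0, abs=0.01)

    def test_gaussian_spike_fwhm(self):
        trace, truth = _fixture(spike_times_ms=(20.0,), template="gaussian",
                                width_ms=0.5, dt_ms=0.01)
        ev = detect_spikes(trace.time_ms, trace["fixture"])[0]
        hd = half_duration(trace.time_ms, trace["fixture"], ev)
        assert hd == pytest.approx(2.3548 * 0.5, abs=0.01)
        assert hd == pytest.approx(truth["half_width_ms"][0], abs=0.01)

    def test_truncated_falling_flank_is_flagged(self):
        t = np.arange(0.0, 10.0, 0.01)
        v = np.where(t > 5.0, 20.0, -80.0)  # steps up, never comes down
        ev = detect_spikes(t, v)[0]
        hd = half_duration(t, v, ev)
        assert np.isnan(hd)
        assert "falling_flank_undefined" in ev.flags

    @settings(derandomize=True, max_examples=25)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-50.0, 50.0))
    def test_invariant_under_affine_voltage_transform(self, a, b):
        trace, _ = _fixture(spike_times_ms=(20.0,), template="gaussian",
                            width_ms=0.5, dt_ms=0.01)
        t, v = trace.time_ms, trace["fixture"]
        ev1 = detect_spikes(t, v)[0]
        h1 = half_duration(t, v, ev1)
        v2 = a * v + b
        thr2 = a * (-20.0) + b
        ev2 = detect_spikes(t, v2, threshold_mv=thr2)[0]
        h2 = half_duration(t, v2, ev2)
        assert h2 == pytest.approx(h1, rel=1e-9)

    def test_annotate_fills_all_events(self):
        trace, _ = _fixture(spike_times_ms=(10.0, 30.0, 50.0), dt_ms=0.05)
        evs = detect_spikes(trace.time_ms, trace["fixture"])
        annotate_half_durations(trace.time_ms, trace["fixture"], evs)
        for ev in evs:
            assert np.isfinite(ev.half_duration_ms)


class TestAfterdischarge:
    def _events_at(self, times):
        trace, _ = _fixture(spike_times_ms=tuple(times), duration_ms=3000.0,
                            dt_ms=0.1)
        return detect_spikes(trace.time_ms, trace["fixture"])

    def test_no_events_after_stimulus_means_absent(self):
        evs = self._events_at([100.0, 200.0, 300.0])
        s = afterdischarge_summary(evs, stimulus_end_ms=400.0)
        assert not s.present and s.n_spikes == 0 and s.frequency_hz is None

    def test_six_spikes_at_100ms_spacing_give_10hz(self):
        end = 1000.0
        evs = self._events_at([end + 100.0 * k for k in range(1, 7)])
        s = afterdischarge_summary(evs, stimulus_end_ms=end)
        assert s.present and s.n_spikes == 6
        assert s.frequency_hz == pytest.approx(10.0, rel=1e-3)

    def test_spikes_before_stimulus_end_do_not_affect_frequency(self):
        end = 1000.0
        post = [end + 100.0 * k for k in range(1, 7)]
        s1 = afterdischarge_summary(self._events_at(post), end)
        s2 = afterdischarge_summary(
            self._events_at([50.0, 500.0, 900.0] + post), end)
        assert s1.frequency_hz == pytest.approx(s2.frequency_hz, rel=1e-9)
        assert s2.n_spikes == 6

    def test_guard_excludes_single_rebound_spike(self):
        end = 1000.0
        s = afterdischarge_summary(self._events_at([end + 20.0]), end)
        assert s.n_spikes == 0 and not s.present

    def test_presence_needs_three_spikes(self):
        end = 1000.0
        s = afterdischarge_summary(
            self._events_at([end + 100.0, end + 200.0]), end)
        assert s.n_spikes == 2 and not s.present
        assert s.frequency_hz == pytest.approx(10.0, rel=1e-3)


class TestDerivative:
    def test_linear_ramp_has_constant_derivative(self):
        t = np.arange(0.0, 10.0, 0.01)
        d = derivative_trace(t, -3.0 + 2.5 * t)
        np.testing.assert_allclose(d, 2.5, rtol=1e-9)

    def test_sine_derivative_is_cosine_to_second_order(self):
        dt, w = 0.01, 2.0 * np.pi / 5.0
        t = np.arange(0.0, 20.0, dt)
        d = derivative_trace(t, np.sin(w * t))
        err = np.max(np.abs(d[1:-1] - w * np.cos(w * t)[1:-1]))
        assert err < w ** 3 * dt ** 2  # O(dt^2) central differences

    def test_constant_trace_derivative_is_zero(self):
        t = np.arange(0.0, 5.0, 0.01)
        np.testing.assert_allclose(
            derivative_trace(t, np.full_like(t, -80.0)), 0.0, atol=1e-9)


class TestRisingPhasePeaks:
    @staticmethod
    def _sigmoid(t, t0, tau):
        return 1.0 / (1.0 + np.exp(-(t - t0) / tau))

    def test_two_shifted_sigmoids_give_two_dvdt_peaks(self):
        # low detection threshold so the whole rise lies inside the
        # crossing-to-peak window the counter inspects
        t = np.arange(0.0, 20.0, 0.01)
        v = -80.0 + 50.0 * self._sigmoid(t, 8.0, 0.3) \
            + 50.0 * self._sigmoid(t, 10.0, 0.3)
        ev = detect_spikes(t, v, threshold_mv=-70.0)[0]
        assert rising_phase_dvdt_peaks(t, v, ev) == 2

    def test_single_sigmoid_rise_gives_one_peak(self):
        t = np.arange(0.0, 20.0, 0.01)
        v = -80.0 + 100.0 * self._sigmoid(t, 10.0, 0.3)
        ev = detect_spikes(t, v, threshold_mv=-70.0)[0]
        assert rising_phase_dvdt_peaks(t, v, ev) == 1


class TestLatencyOrder:
    def _shifted_pair(self, lag_ms):
        spec = FixtureSpec(spike_times_ms=(20.0, 40.0, 60.0), dt_ms=0.01,
                           duration_ms=100.0)
        trace, _ = make_spike_train_trace(spec)
        v = trace["fixture"]
        shift = int(round(lag_ms / trace.dt_ms))
        v2 = np.roll(v, shift)
        v2[:shift] = v[0]
        return TraceSet(time_ms=trace.time_ms,
                        data={"soma": v, "bouton_10": v2},
                        dt_ms=trace.dt_ms)

    def test_pure_shift_recovers_order_and_lag(self):
        ts = self._shifted_pair(0.8)
        out = latency_order(ts)
        assert len(out["groups"]) == 3
        for g in out["groups"]:
            assert g["order"] == ["soma", "bouton_10"]
            lag = g["times"]["bouton_10"] - g["times"]["soma"]
            assert lag == pytest.approx(0.8, abs=ts.dt_ms)
        assert out["unmatched"] == {}

    def test_identical_traces_fall_back_to_input_order_with_tie_flag(self):
        spec = FixtureSpec(spike_times_ms=(20.0,), dt_ms=0.01)
        trace, _ = make_spike_train_trace(spec)
        v = trace["fixture"]
        ts = TraceSet(time_ms=trace.time_ms, data={"a": v, "b": v.copy()},
                      dt_ms=trace.dt_ms)
        out = latency_order(ts)
        g = out["groups"][0]
        assert g["order"] == ["a", "b"]
        assert "tie" in g["flags"]

    def test_missing_spike_reported_as_unmatched(self):
        ts = self._shifted_pair(0.5)
        # remove the second spike from the soma trace only
        v = ts["soma"].copy()
        sl = (ts.time_ms > 35.0) & (ts.time_ms < 45.0)
        v[sl] = -80.0
        ts2 = TraceSet(time_ms=ts.time_ms,
                       data={"soma": v, "bouton_10": ts["bouton_10"]},
                       dt_ms=ts.dt_ms)
        out = latency_order(ts2)
        assert len(out["groups"]) == 2
        assert len(out["unmatched"]["bouton_10"]) == 1
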