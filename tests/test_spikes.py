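"""Spike detection, AP morphometry (amplitude, duration, ratio, latency)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sonophys.acoustics import Modality, StimProtocol
from sonophys.errors import DegenerateWindowError, DomainError
from sonophys.spikes import (
    SpikeOrder,
    analyze_trace_spikes,
    ap_amplitude,
    ap_ratio,
    detect_spikes,
    latency,
    success_rate,
    SpikeEvent,
)
from sonophys.synthetic_data import CellParams, simulate_membrane
from sonophys.traces import Epoch

from conftest import make_trace


RATE = 10.0  # kHz


def add_triangular_ap(samples, peak_idx, rise_mv=40.0, rise_ms=1.0,
                      fall_to=-10.0, fall_ms=5.0, baseline=-40.0):
    """Piecewise-linear AP: rise to baseline+rise_mv, fall to ``fall_to``."""
    n_rise = int(rise_ms * RATE)
    n_fall = int(fall_ms * RATE)
    peak = baseline + rise_mv
    samples[peak_idx - n_rise : peak_idx + 1] = np.linspace(baseline, peak, n_rise + 1)
    samples[peak_idx : peak_idx + n_fall + 1] = np.linspace(peak, fall_to, n_fall + 1)
    return samples


def _windows():
    return Epoch(1000.0, 1400.0), Epoch(700.0, 1000.0)


class TestDetection:
    def test_noise_alone_never_crosses(self, flat_trace):
        detection, baseline = _windows()
        assert detect_spikes(flat_trace, detection, baseline) == []

    def test_single_ap_detected_as_first(self):
        samples = np.full(20_000, -40.0)
        add_triangular_ap(samples, peak_idx=11_000, rise_mv=30.0, fall_to=-45.0)
        tr = make_trace(samples)
        detection, baseline = _windows()
        events = detect_spikes(tr, detection, baseline)
        assert len(events) == 1
        assert events[0].order is SpikeOrder.first
        assert events[0].peak_time == pytest.approx(1100.0, abs=0.11)

    def test_two_aps_ordered_first_following(self):
        samples = np.full(20_000, -40.0)
        add_triangular_ap(samples, peak_idx=11_000)
        add_triangular_ap(samples, peak_idx=11_500)
        events = detect_spikes(make_trace(samples), *_windows())
        assert [e.order for e in events] == [SpikeOrder.first, SpikeOrder.following]
        assert events[0].peak_time < events[1].peak_time

    def test_empty_detection_window_rejected(self, flat_trace):
        with pytest.raises(DegenerateWindowError):
            detect_spikes(flat_trace, Epoch(1000.0, 1000.0), Epoch(700.0, 1000.0))

    @given(offset=st.floats(-50.0, 50.0))
    @settings(max_examples=25)
    def test_offset_invariance(self, offset):
        """Detection depends only on height above baseline, not absolute level."""
        samples = np.full(20_000, -40.0)
        add_triangular_ap(samples, peak_idx=11_000)
        add_triangular_ap(samples, peak_idx=12_500, rise_mv=25.0)
        base_events = detect_spikes(make_trace(samples), *_windows())
        shifted_events = detect_spikes(make_trace(samples + offset), *_windows())
        assert [e.peak_time for e in shifted_events] == [
            e.peak_time for e in base_events]
        assert [e.amplitude for e in shifted_events] == pytest.approx(
            [e.amplitude for e in base_events])

    def test_subthreshold_pass_flags_small_events(self):
        samples = np.full(20_000, -40.0)
        add_triangular_ap(samples, peak_idx=11_000, rise_mv=30.0, fall_to=-45.0)
        add_triangular_ap(samples, peak_idx=12_000, rise_mv=12.0, fall_to=-45.0)
        events = detect_spikes(make_trace(samples), *_windows(),
                               secondary_threshold_mv=8.0)
        assert [e.subthreshold for e in events] == [False, True]
        summary = success_rate([events])
        assert summary.n_with_spike == 1  # subthreshold events do not count

    def test_plateau_below_threshold_ignored(self):
        # 12 mV sustained depolarization with noise stays undetected
        rng = np.random.default_rng(0)
        samples = -40.0 + 0.5 * rng.standard_normal(20_000)
        samples[10_000:13_000] += 12.0
        assert detect_spikes(make_trace(samples), *_windows()) == []


class TestAmplitude:
    def test_peak_to_subsequent_minimum(self):
        samples = np.full(20_000, -40.0)
        add_triangular_ap(samples, peak_idx=11_000, rise_mv=60.0, fall_to=-50.0)
        amp, trough_t = ap_amplitude(make_trace(samples), 1100.0, 1400.0)
        assert amp == pytest.approx(70.0, abs=0.2)
        assert trough_t > 1100.0

    def test_monotone_decay_to_plateau(self):
        samples = np.full(20_000, -40.0)
        add_triangular_ap(samples, peak_idx=11_000, rise_mv=50.0, fall_to=-40.0)
        amp, _ = ap_amplitude(make_trace(samples), 1100.0, 1400.0)
        assert amp == pytest.approx(50.0, abs=0.2)

    def test_biphasic_template_with_ahp(self):
        samples = np.full(20_000, -40.0)
        add_triangular_ap(samples, peak_idx=11_000, rise_mv=50.0, fall_to=-55.0)
        amp, _ = ap_amplitude(make_trace(samples), 1100.0, 1400.0)
        assert amp == pytest.approx(65.0, abs=0.2)

    def test_peak_at_trace_end_rejected(self):
        tr = make_trace(np.full(1000, -40.0))
        with pytest.raises(DegenerateWindowError):
            ap_amplitude(tr, tr.t_end - tr.dt)


class TestDuration:
    def test_triangular_closed_form(self):
        """Fall 40 -> -10 mV over 5 ms: amplitude 50, half level 15, 2.5 ms."""
        samples = np.full(20_000, -40.0)
        add_triangular_ap(samples, peak_idx=11_000, rise_mv=80.0, rise_ms=1.0,
                          fall_to=-10.0, fall_ms=5.0)
        samples[11_050:14_500] = -10.0  # hold the trough plateau past the window
        tr = make_trace(samples)
        events = detect_spikes(tr, *_windows())
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(50.0, abs=0.2)
        assert events[0].duration == pytest.approx(2.5, abs=0.11)

    def test_one_sample_fall_interpolated(self):
        samples = np.full(20_000, -40.0)
        samples[10_995:11_001] = np.linspace(-40.0, 10.0, 6)
        samples[11_001] = -50.0  # instantaneous drop
        tr = make_trace(samples)
        events = detect_spikes(tr, *_windows())
        assert len(events) == 1
        assert 0 < events[0].duration <= tr.dt + 1e-12

    def test_time_shift_invariance(self):
        def measure(peak_idx, detection):
            samples = np.full(30_000, -40.0)
            add_triangular_ap(samples, peak_idx=peak_idx)
            ev = detect_spikes(make_trace(samples), detection,
                               Epoch(100.0, 400.0))[0]
            return ev.amplitude, ev.duration

        a1 = measure(11_000, Epoch(1000.0, 1400.0))
        a2 = measure(21_000, Epoch(2000.0, 2400.0))
        assert a1 == pytest.approx(a2)

    def test_generator_half_width_recovered(self):
        """Measured duration matches the drawn half-width within a sample."""
        cell = CellParams(threshold_theta=2.0, noise_sigma=0.0, refractory=30.0)
        prot = StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=1.0,
                            n_windows=1)
        trace, truth = simulate_membrane(prot, cell, seed=9)
        events = [e for w in analyze_trace_spikes(trace) for e in w]
        assert len(events) >= 5
        by_time = {round(t, 1): w for t, w in
                   zip(truth.spike_times, truth.spike_widths)}
        for ev in events:
            nominal = by_time[round(ev.peak_time, 1)]
            assert ev.duration == pytest.approx(nominal, abs=trace.dt + 1e-9)


class TestRatioAndLatency:
    @pytest.mark.parametrize("amp, dur, expected", [(70.0, 2.5, 28.0), (50.0, 2.0, 25.0)])
    def test_ratio(self, amp, dur, expected):
        ev = SpikeEvent(
            peak_time=0.0, peak_value=0.0, trough_time=1.0, trough_value=-amp,
            amplitude=amp, duration=dur, latency=0.0, modality=Modality.US,
            order=SpikeOrder.first)
        assert ap_ratio(ev) == pytest.approx(expected)

    def test_zero_duration_rejected(self):
        ev = SpikeEvent(
            peak_time=0.0, peak_value=0.0, trough_time=1.0, trough_value=-50.0,
            amplitude=50.0, duration=math.nan, latency=0.0,
            modality=Modality.US, order=SpikeOrder.first)
        with pytest.raises(DegenerateWindowError):
            ap_ratio(ev)

    def test_latency_arithmetic(self):
        assert latency(1105.0, 1000.0) == pytest.approx(105.0)
        with pytest.raises(DomainError):
            latency(900.0, 1000.0)

    def test_el_spikes_onset_locked(self):
        """EL steps that clear threshold fire within ~20 ms of onset."""
        cell = CellParams(threshold_theta=2.0)
        prot = StimProtocol(modality=Modality.EL, el_current=4.0,
                            el_duration=0.3, n_windows=3)
        trace, _ = simulate_membrane(prot, cell, seed=4)
        events = [e for w in analyze_trace_spikes(trace) for e in w]
        assert len(events) == 3
        assert all(e.latency < 20.0 for e in events)


class TestSuccessRate:
    def test_two_of_three(self):
        ev = SpikeEvent(
            peak_time=0.0, peak_value=0.0, trough_time=1.0, trough_value=-50.0,
            amplitude=50.0, duration=2.0, latency=0.0, modality=Modality.US,
            order=SpikeOrder.first)
        summary = success_rate([[ev], [], [ev, ev]])
        assert summary.n_stimulations == 3
        assert summary.n_with_spike == 2
        assert summary.success_rate == pytest.approx(2 / 3)

    def test_no_spikes(self):
        assert success_rate([[], []]).success_rate == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DegenerateWindowError):
            success_rate([])

    def test_success_rate_non_decreasing_with_intensity(self):
        """At fixed DC, higher pressure can only recruit more windows."""
        rates = []
        for p in (8.0, 14.0, 20.0):
            hits = 0
            for i in range(12):
                cell = CellParams(threshold_theta=4.0 + 0.4 * i)
                prot = StimProtocol(modality=Modality.US, p_rms=p,
                                    duty_cycle=1.0, n_windows=1)
                trace, _ = simulate_membrane(prot, cell, seed=100 + i)
                events = [e for w in analyze_trace_spikes(trace) for e in w]
                hits += bool(events)
            rates.append(hits / 12)
        assert rates == sorted(rates)


class TestDetectionOracle:
    def test_hit_rate_one_false_alarms_zero(self):
        """Every ground-truth spike in a detection window is found, and every
        detected event matches a ground-truth spike (amplitudes >= 25 mV,
        noise sigma <= 1 mV)."""
        cell = CellParams(threshold_theta=3.0, noise_sigma=1.0, refractory=25.0)
        prot = StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=1.0)
        hits = misses = false_alarms = 0
        for seed in range(6):
            trace, truth = simulate_membrane(prot, cell, seed=seed)
            detected = [e for w in analyze_trace_spikes(trace) for e in w]
            det_times = np.array([e.peak_time for e in detected])
            for t, a, w in zip(truth.spike_times, truth.spike_amplitudes,
                               truth.spike_windows):
                if w is None or a < 25.0:
                    continue
                if det_times.size and np.min(np.abs(det_times - t)) < 1.5:
                    hits += 1
                else:
                    misses += 1
            true_times = np.array(truth.spike_times)
            for t in det_times:
                if np.min(np.abs(true_times - t)) > 1.5:
                    false_alarms += 1
        assert misses == 0
        assert false_alarms == 0
        assert hits >= 50
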