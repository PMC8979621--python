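"""Spike detection and action-potential morphometry.

Spikes are local maxima exceeding the pre-stimulus baseline median by a
fixed threshold (15 mV by default), separated by at least a refractory
interval.  For each detected peak the pipeline measures:

* amplitude — peak voltage minus the subsequent minimum, where the minimum
  is searched between the peak and the next spike peak (or the end of the
  detection window);
* early-repolarization duration — time from the peak to the first crossing
  of the half-amplitude level on the falling flank, linearly interpolated
  between samples;
* latency — delay from the stimulation-window onset to the peak.

The first spike of each stimulation window is tagged ``first`` and the rest
``following``; the success rate of a protocol is the fraction of stimulation
windows with at least one detected spike inside the detection window
(stimulus duration plus 100 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .acoustics import IntensityBin, Modality
from .errors import DegenerateWindowError, DomainError
from .subthreshold import build_schedule
from .traces import Epoch, Trace, extract_epoch

__all__ = [
    "SpikeOrder",
    "SpikeEvent",
    "SuccessSummary",
    "detect_spikes",
    "ap_amplitude",
    "ap_duration",
    "ap_ratio",
    "latency",
    "success_rate",
    "analyze_trace_spikes",
    "spike_table",
]

#: Detection threshold above the baseline median, mV.
DEFAULT_THRESHOLD_MV = 15.0
#: Minimum peak separation, ms.
DEFAULT_REFRACTORY_MS = 10.0
#: Minimum peak prominence, mV; rejects noise maxima riding on sustained
#: depolarization plateaus that clear the absolute threshold.
DEFAULT_MIN_PROMINENCE_MV = 10.0
#: Post-window margin, ms, available to waveform measurement (trough search,
#: prominence) for spikes peaking near the end of the counting window.  The
#: detection window bounds which spikes are counted, not their repolarization.
MEASURE_MARGIN_MS = 20.0


class SpikeOrder(str, Enum):
    first = "first"
    following = "following"


@dataclass
class SpikeEvent:
    """One detected action potential and its waveform measurements."""

    peak_time: float
    peak_value: float
    trough_time: float
    trough_value: float
    amplitude: float
    duration: float
    latency: float
    modality: Modality
    order: SpikeOrder
    window_id: int = 0
    subthreshold: bool = False

    @property
    def ratio(self) -> float:
        return ap_ratio(self)


@dataclass(frozen=True)
class SuccessSummary:
    """Spike-elicitation probability over a set of stimulation windows."""

    n_stimulations: int
    n_with_spike: int
    bin: IntensityBin | None = None

    @property
    def success_rate(self) -> float:
        return self.n_with_spike / self.n_stimulations


def _interp_crossing(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    """Time where the segment (t0,v0)->(t1,v1) crosses ``level`` (v0 > level >= v1)."""
    if v0 == v1:
        return t1
    return t0 + (v0 - level) / (v0 - v1) * (t1 - t0)


def ap_amplitude(
    trace: Trace, peak_time: float, search_end: float | None = None
) -> tuple[float, float]:
    """Peak-to-subsequent-minimum amplitude of the spike peaking at ``peak_time``.

    The minimum is searched in ``(peak_time, search_end)``; by default up to
    the end of the trace.  Returns ``(amplitude_mV, trough_time_ms)``.
    """
    i_peak = trace.index_at(peak_time)
    if search_end is None:
        i_end = trace.n_samples
    else:
        i_end = trace.index_at(search_end)
    if i_peak < 0 or i_peak >= trace.n_samples:
        raise DomainError(f"peak time {peak_time} ms outside trace")
    if i_end <= i_peak + 1:
        raise DegenerateWindowError("no samples after the peak to search for a trough")
    seg = trace.samples[i_peak:i_end]
    i_tr = int(np.argmin(seg[1:])) + 1
    amplitude = float(seg[0] - seg[i_tr])
    trough_time = trace.t_start + (i_peak + i_tr) * trace.dt
    return amplitude, trough_time


def ap_duration(trace: Trace, spike: SpikeEvent) -> float:
    """Early-repolarization duration: peak to half-amplitude crossing, ms.

    The half level is ``peak_value - amplitude/2``; the first crossing on the
    falling flank (between the peak and the trough) is taken, linearly
    interpolated between the bracketing samples.  Returns NaN if no crossing
    exists before the trough (degenerate waveform).
    """
    i_peak = trace.index_at(spike.peak_time)
    i_tr = trace.index_at(spike.trough_time)
    level = spike.peak_value - spike.amplitude / 2.0
    v = trace.samples
    for i in range(i_peak + 1, min(i_tr, trace.n_samples - 1) + 1):
        if v[i] <= level:
            t_prev = trace.t_start + (i - 1) * trace.dt
            t_cross = _interp_crossing(t_prev, v[i - 1], t_prev + trace.dt, v[i], level)
            return t_cross - spike.peak_time
    return math.nan


def ap_ratio(spike: SpikeEvent) -> float:
    """Amplitude over duration, mV/ms — proportional to the decay-phase slope."""
    if not (spike.duration and math.isfinite(spike.duration)):
        raise DegenerateWindowError("spike has no valid duration")
    return spike.amplitude / spike.duration


def latency(spike: SpikeEvent | float, window_onset: float) -> float:
    """Delay from the stimulation-window onset to the spike peak, ms."""
    peak_time = spike.peak_time if isinstance(spike, SpikeEvent) else float(spike)
    lat = peak_time - window_onset
    if lat < 0:
        raise DomainError(f"spike at {peak_time} ms precedes window onset {window_onset}")
    return lat


def detect_spikes(
    trace: Trace,
    detection_window: Epoch,
    baseline_epoch: Epoch,
    threshold_mv: float = DEFAULT_THRESHOLD_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
    min_prominence_mv: float = DEFAULT_MIN_PROMINENCE_MV,
    secondary_threshold_mv: float | None = None,
    modality: Modality = Modality.US,
    window_id: int = 0,
) -> list[SpikeEvent]:
    """Detect and measure spikes within one stimulation's detection window.

    The absolute detection level is ``median(baseline) + threshold_mv``,
    with the baseline taken per stimulation so slow drift between windows
    does not shift the criterion.  If ``secondary_threshold_mv`` is given, an
    additional lower-threshold pass flags events between the two levels as
    ``subthreshold``; these are excluded from success-rate computation.
    """
    seg = extract_epoch(trace, detection_window)
    if seg.size == 0:
        raise DegenerateWindowError("empty detection window")
    base = extract_epoch(trace, baseline_epoch)
    if base.size == 0:
        raise DegenerateWindowError("empty baseline epoch")
    base_median = float(np.median(base))
    level = base_median + threshold_mv
    detect_level = level
    if secondary_threshold_mv is not None:
        if secondary_threshold_mv >= threshold_mv:
            raise DomainError("secondary threshold must be below the main threshold")
        detect_level = base_median + secondary_threshold_mv

    distance = max(1, int(round(refractory_ms * trace.sampling_rate)))
    # pad the search segment so maxima near the window edges keep their true
    # prominence; only in-window peaks are kept
    margin = int(round(MEASURE_MARGIN_MS * trace.sampling_rate))
    i0 = trace.index_at(detection_window.start)
    i1 = i0 + seg.size
    lo = max(0, i0 - 2)
    hi = min(trace.n_samples, i1 + margin)
    padded, _ = find_peaks(
        trace.samples[lo:hi],
        height=detect_level,
        distance=distance,
        prominence=min_prominence_mv,
    )
    peaks = [int(p) + lo - i0 for p in padded if i0 <= int(p) + lo < i1]
    events: list[SpikeEvent] = []
    n_supra = 0
    for j, p in enumerate(peaks):
        peak_idx = i0 + int(p)
        peak_time = trace.t_start + peak_idx * trace.dt
        peak_value = float(trace.samples[peak_idx])
        next_peak_time = (
            trace.t_start + (i0 + int(peaks[j + 1])) * trace.dt
            if j + 1 < len(peaks)
            else min(detection_window.end + MEASURE_MARGIN_MS, trace.t_end)
        )
        amplitude, trough_time = ap_amplitude(trace, peak_time, next_peak_time)
        is_sub = peak_value < level
        order = SpikeOrder.first if (n_supra == 0 and not is_sub) else SpikeOrder.following
        event = SpikeEvent(
            peak_time=peak_time,
            peak_value=peak_value,
            trough_time=trough_time,
            trough_value=peak_value - amplitude,
            amplitude=amplitude,
            duration=math.nan,
            latency=latency(peak_time, detection_window.start),
            modality=modality,
            order=order,
            window_id=window_id,
            subthreshold=is_sub,
        )
        event.duration = ap_duration(trace, event)
        if not is_sub:
            n_supra += 1
        events.append(event)
    return events


def success_rate(
    window_events: Sequence[Sequence[SpikeEvent]] | Mapping[int, Sequence[SpikeEvent]],
    bin: IntensityBin | None = None,
) -> SuccessSummary:
    """Fraction of stimulation windows with at least one suprathreshold spike."""
    if isinstance(window_events, Mapping):
        groups = list(window_events.values())
    else:
        groups = list(window_events)
    if len(groups) == 0:
        raise DegenerateWindowError("success rate over zero stimulations")
    n_hit = sum(
        1 for events in groups if any(not ev.subthreshold for ev in events)
    )
    return SuccessSummary(n_stimulations=len(groups), n_with_spike=n_hit, bin=bin)


def analyze_trace_spikes(
    trace: Trace,
    threshold_mv: float = DEFAULT_THRESHOLD_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
    min_prominence_mv: float = DEFAULT_MIN_PROMINENCE_MV,
    secondary_threshold_mv: float | None = None,
) -> list[list[SpikeEvent]]:
    """Detect spikes in every stimulation window of a trace.

    US windows use the DC-dependent schedule (detection = stimulus + 100 ms,
    baseline = first pre-onset baseline epoch).  EL windows use the step
    duration + 100 ms with an equal-duration pre-onset baseline.  Returns one
    event list per stimulation window, in trace order.
    """
    per_window: list[list[SpikeEvent]] = []
    for window_id, (onset, protocol) in enumerate(trace.stim_events):
        if protocol.modality is Modality.US:
            schedule = build_schedule(protocol, onset)
            detection = schedule.detection
            baseline = Epoch(onset - protocol.stim_duration, onset)
        else:
            dur_ms = (protocol.el_duration or 0.0) * 1000.0
            detection = Epoch(onset, onset + dur_ms + 100.0)
            baseline = Epoch(onset - dur_ms, onset)
        # clip the baseline to the trace for recordings starting at the onset
        baseline = Epoch(max(baseline.start, trace.t_start), baseline.end)
        events = detect_spikes(
            trace,
            detection,
            baseline,
            threshold_mv=threshold_mv,
            refractory_ms=refractory_ms,
            min_prominence_mv=min_prominence_mv,
            secondary_threshold_mv=secondary_threshold_mv,
            modality=protocol.modality,
            window_id=window_id,
        )
        per_window.append(events)
    return per_window


def spike_table(traces: Iterable[Trace], **detect_kwargs) -> pd.DataFrame:
    """Per-spike measurement table over many traces."""
    rows = []
    for trace in traces:
        for window_events, (onset, protocol) in zip(
            analyze_trace_spikes(trace, **detect_kwargs), trace.stim_events
        ):
            for ev in window_events:
                rows.append(
                    {
                        "cell_id": trace.cell_id,
                        "window_id": ev.window_id,
                        "modality": ev.modality.value,
                        "order": ev.order.value,
                        "subthreshold": ev.subthreshold,
                        "peak_time_ms": ev.peak_time,
                        "amplitude_mV": ev.amplitude,
                        "duration_ms": ev.duration,
                        "ratio_mV_per_ms": (
                            ev.amplitude / ev.duration
                            if math.isfinite(ev.duration) and ev.duration
                            else math.nan
                        ),
                        "latency_ms": ev.latency,
                    }
                )
    return pd.DataFrame(rows)
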