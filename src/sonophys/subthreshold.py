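"""DC-dependent window scheduling and subthreshold depolarization statistics.

The membrane-potential response to one tone burst is quantified as

    DV_i = median(V, response_i) - median(V, baseline_i)

where for pulsed protocols (DC < 1) ``response_i`` is the i-th tone burst
and ``baseline_i`` the interval of equal duration immediately preceding it,
and for continuous stimulation (DC = 1) a single 300 ms response window is
compared against the preceding 300 ms.  Medians, not means, are used so
occasional action potentials riding on the depolarization do not dominate
the estimate.  Positive DV is depolarization.

Slow accumulation that outlasts individual bursts is captured separately by
the baseline variation B_i: the difference of consecutive off-interval
medians (the full T-off periods between bursts, plus the pre-onset and
post-offset intervals for continuous stimulation).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .acoustics import (
    Medium,
    Modality,
    StimProtocol,
    WATER,
    burst_timing,
    classify_intensity,
    compute_ispta,
)
from .errors import DegenerateWindowError, UnsupportedModalityError
from .traces import Epoch, EpochRole, Trace, extract_epoch

__all__ = [
    "WindowSchedule",
    "SubthresholdResult",
    "build_schedule",
    "delta_v",
    "baseline_variation",
    "mean_response",
    "analyze_window",
    "subthreshold_table",
]

#: Post-stimulus extension of the spike-detection window, ms.
DETECTION_EXTENSION_MS = 100.0


@dataclass(frozen=True)
class WindowSchedule:
    """Analysis windows for one stimulation window of a US protocol.

    ``cycles`` pairs each response (tone-burst) epoch with its equal-duration
    preceding baseline.  ``off_epochs`` is the sequence of off-state windows
    used for baseline-variation estimates.  ``detection`` spans the stimulus
    plus a 100 ms post-stimulus extension and is where spikes are counted.
    """

    onset: float
    protocol: StimProtocol
    cycles: tuple[tuple[Epoch, Epoch], ...]
    off_epochs: tuple[Epoch, ...]
    detection: Epoch
    post: Epoch

    @property
    def baselines(self) -> tuple[Epoch, ...]:
        return tuple(b for b, _ in self.cycles)

    @property
    def responses(self) -> tuple[Epoch, ...]:
        return tuple(r for _, r in self.cycles)


@dataclass
class SubthresholdResult:
    """Per-stimulation-window subthreshold summary."""

    protocol: StimProtocol
    onset: float
    delta_v: list[float]
    baseline_variations: list[float]
    ispta: float

    @property
    def mean_delta_v(self) -> float:
        return mean_response(self.delta_v)


def build_schedule(protocol: StimProtocol, onset: float) -> WindowSchedule:
    """Baseline/response/detection windows for a stimulation at ``onset`` ms.

    For DC = 1 the single response is the whole stimulation and the baseline
    the preceding interval of the same length; for pulsed protocols each
    tone burst is a response and its baseline the immediately preceding
    interval of burst duration (the tail of the previous off period).
    """
    if protocol.modality is not Modality.US:
        raise UnsupportedModalityError("window schedules are defined for US protocols")
    bursts = burst_timing(protocol)
    cycles = []
    for start, end in bursts:
        dur = end - start
        response = Epoch(onset + start, onset + end, EpochRole.response)
        baseline = Epoch(onset + start - dur, onset + start, EpochRole.baseline)
        cycles.append((baseline, response))

    # Off-state windows for B_i: T-off before each burst and after the last
    # one.  For continuous stimulation these are the 300 ms pre/post windows.
    if protocol.duty_cycle >= 1.0:
        off_dur = protocol.stim_duration
        off_starts = [onset - off_dur, onset + protocol.stim_duration]
    else:
        off_dur = protocol.t_off
        off_starts = [onset - off_dur] + [onset + end for _, end in bursts]
    off_epochs = tuple(
        Epoch(s, s + off_dur, EpochRole.baseline) for s in off_starts
    )

    sd = protocol.stim_duration
    detection = Epoch(onset, onset + sd + DETECTION_EXTENSION_MS, EpochRole.detection)
    post = Epoch(onset + sd, onset + sd + DETECTION_EXTENSION_MS, EpochRole.post)
    return WindowSchedule(
        onset=onset,
        protocol=protocol,
        cycles=tuple(cycles),
        off_epochs=off_epochs,
        detection=detection,
        post=post,
    )


def _median(trace: Trace, epoch: Epoch) -> float:
    samples = extract_epoch(trace, epoch)
    if samples.size == 0:
        raise DegenerateWindowError(f"empty window [{epoch.start}, {epoch.end}) ms")
    return float(np.median(samples))


def delta_v(trace: Trace, schedule: WindowSchedule) -> list[float]:
    """Per-cycle depolarization: response median minus baseline median, mV."""
    return [_median(trace, r) - _median(trace, b) for b, r in schedule.cycles]


def baseline_variation(
    trace: Trace, windows: WindowSchedule | Sequence[Epoch]
) -> list[float]:
    """Consecutive differences of off-interval medians, B_i, in mV.

    Accepts a schedule (uses its off epochs) or an explicit epoch sequence.
    Fewer than two windows yield an empty result.
    """
    if isinstance(windows, WindowSchedule):
        epochs: Sequence[Epoch] = windows.off_epochs
    else:
        epochs = list(windows)
    if len(epochs) < 2:
        return []
    medians = [_median(trace, e) for e in epochs]
    return [b - a for a, b in zip(medians[:-1], medians[1:])]


def mean_response(per_cycle_delta_v: Sequence[float]) -> float:
    """Average response amplitude over cycles (plain arithmetic mean)."""
    if len(per_cycle_delta_v) == 0:
        raise DegenerateWindowError("mean response of an empty cycle list")
    return fmean(per_cycle_delta_v)


def analyze_window(
    trace: Trace,
    protocol: StimProtocol,
    onset: float,
    medium: Medium = WATER,
) -> SubthresholdResult:
    """Full subthreshold summary of one stimulation window."""
    schedule = build_schedule(protocol, onset)
    try:
        b_i = baseline_variation(trace, schedule)
    except Exception:
        # post-offset off window may fall outside short recordings
        b_i = []
    return SubthresholdResult(
        protocol=protocol,
        onset=onset,
        delta_v=delta_v(trace, schedule),
        baseline_variations=b_i,
        ispta=compute_ispta(protocol, medium),
    )


def subthreshold_table(
    traces: Iterable[Trace], medium: Medium = WATER
) -> pd.DataFrame:
    """Per-stimulation subthreshold summary over many traces.

    One row per US stimulation window with cell identity, protocol fields,
    I_spta and its bin, per-cycle DV, mean DV and the B_i list.
    """
    rows = []
    for trace in traces:
        for window_id, (onset, protocol) in enumerate(trace.stim_events):
            if protocol.modality is not Modality.US:
                continue
            res = analyze_window(trace, protocol, onset, medium)
            rows.append(
                {
                    "cell_id": trace.cell_id,
                    "cell_type": trace.cell_type,
                    "window_id": window_id,
                    "onset_ms": onset,
                    "p_rms_kpa": protocol.p_rms,
                    "duty_cycle": protocol.duty_cycle,
                    "ispta_mw_cm2": res.ispta,
                    "bin": classify_intensity(res.ispta).value,
                    "delta_v_mv": res.delta_v,
                    "mean_delta_v_mv": res.mean_delta_v,
                    "baseline_variation_mv": res.baseline_variations,
                }
            )
    return pd.DataFrame(rows)
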