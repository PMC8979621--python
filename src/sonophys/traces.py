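"""Data model and I/O for stimulus-annotated membrane-voltage time series.

A :class:`Trace` is a uniformly sampled intracellular voltage recording in
mV with a list of stimulation events (onset time + protocol).  Time is in ms
throughout; sample ``i`` covers ``[t_start + i*dt, t_start + (i+1)*dt)`` and
all analysis intervals are half-open ``[start, end)``.

On disk a trace is a two-column CSV (``time_ms,voltage_mV``) with a JSON
sidecar of the same stem carrying cell identity and the stimulation events.
No proprietary acquisition formats are handled here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .acoustics import Modality, StimProtocol, protocol_from_dict, protocol_to_dict
from .errors import (
    DegenerateWindowError,
    DomainError,
    TraceFormatError,
    TraceMetadataError,
)

__all__ = [
    "EpochRole",
    "Epoch",
    "Trace",
    "read_trace",
    "write_trace",
    "extract_epoch",
    "detrend_window",
]

#: Relative tolerance on sampling-interval uniformity when reading CSVs.
_DT_RTOL = 1e-4


class EpochRole(str, Enum):
    baseline = "baseline"
    response = "response"
    detection = "detection"
    post = "post"


@dataclass(frozen=True)
class Epoch:
    """Half-open analysis interval ``[start, end)`` in ms."""

    start: float
    end: float
    role: EpochRole = EpochRole.baseline

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise DomainError(f"epoch end {self.end} precedes start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def shift(self, offset: float) -> "Epoch":
        return Epoch(self.start + offset, self.end + offset, self.role)


@dataclass
class Trace:
    """Uniformly sampled membrane-voltage recording.

    Parameters
    ----------
    sampling_rate : float
        Sampling rate in kHz (samples per ms).
    samples : ndarray
        Membrane voltage in mV.
    t_start : float
        Time of the first sample, ms.
    cell_id : str
        Recording identifier.
    cell_type : str
        "N" (nociceptive) or "P" (pressure) mechanosensory neuron.
    stim_events : list of (onset_ms, StimProtocol)
        Stimulation windows, onsets strictly increasing.
    """

    sampling_rate: float
    samples: np.ndarray
    t_start: float = 0.0
    cell_id: str = "cell0"
    cell_type: str = "N"
    stim_events: list[tuple[float, StimProtocol]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise TraceFormatError("samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise TraceFormatError("sampling_rate must be positive")
        self._validate_events()

    def _validate_events(self) -> None:
        prev_onset = None
        prev_isi_ms = 0.0
        for onset, prot in self.stim_events:
            if prev_onset is not None:
                gap = onset - prev_onset
                if gap <= 0:
                    raise TraceMetadataError("stim onsets must be strictly increasing")
                if gap < prev_isi_ms * (1 - 1e-9):
                    raise TraceMetadataError(
                        f"gap {gap:.1f} ms between stimulations is shorter than the "
                        f"protocol inter-stimulation interval {prev_isi_ms:.1f} ms"
                    )
            if prot.modality is Modality.US:
                window_end = onset + prot.stim_duration + 100.0
            else:
                window_end = onset + (prot.el_duration or 0.0) * 1000.0 + 100.0
            if onset < self.t_start - 1e-9 or window_end > self.t_end + 1e-9:
                raise TraceMetadataError(
                    f"stimulation window [{onset}, {window_end}) ms exceeds trace "
                    f"extent [{self.t_start}, {self.t_end})"
                )
            prev_onset = onset
            prev_isi_ms = prot.isi * 1000.0

    @property
    def dt(self) -> float:
        """Sampling interval, ms."""
        return 1.0 / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def t_end(self) -> float:
        return self.t_start + self.n_samples * self.dt

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the sample whose interval starts at (or nearest to) t."""
        return int(round((t - self.t_start) * self.sampling_rate))


def extract_epoch(trace: Trace, interval: Epoch | tuple[float, float]) -> np.ndarray:
    """Samples of ``trace`` with t in ``[start, end)``.

    The returned view has ``round(rate * (end - start))`` samples.  An empty
    interval yields an empty array; an interval outside the trace raises.
    """
    if isinstance(interval, Epoch):
        start, end = interval.start, interval.end
    else:
        start, end = interval
    if end < start:
        raise DomainError(f"interval end {end} precedes start {start}")
    i0 = int(round((start - trace.t_start) * trace.sampling_rate))
    n = int(round((end - start) * trace.sampling_rate))
    if i0 < 0 or i0 + n > trace.n_samples:
        raise DomainError(
            f"interval [{start}, {end}) ms outside trace extent "
            f"[{trace.t_start}, {trace.t_end}) ms"
        )
    return trace.samples[i0 : i0 + n]


def detrend_window(samples: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line from a signal window.

    Residuals have (numerically) zero mean and zero best-fit slope.  Applied
    before spike-waveform measurements so slow depolarization ramps do not
    leak into peak/trough estimates.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise DegenerateWindowError("detrending needs at least 2 samples")
    return _signal.detrend(x, type="linear")


def write_trace(trace: Trace, path: str | Path) -> tuple[Path, Path]:
    """Write ``trace`` as ``<path>.csv`` plus ``<path>.json`` sidecar.

    Returns the two written paths.  Field order is deterministic so repeated
    writes of the same trace are byte-identical.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {"time_ms": np.round(trace.times(), 9), "voltage_mV": trace.samples}
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")  # exact round trip
    meta = {
        "cell_id": trace.cell_id,
        "cell_type": trace.cell_type,
        "sampling_rate_khz": trace.sampling_rate,
        "t_start_ms": trace.t_start,
        "stim_onsets_ms": [onset for onset, _ in trace.stim_events],
        "stim_events": [
            {"onset_ms": onset, "protocol": protocol_to_dict(prot)}
            for onset, prot in trace.stim_events
        ],
    }
    json_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return csv_path, json_path


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace`.

    ``path`` may point at either file of the pair (or their common stem).
    Sampling must be uniform to within a small relative tolerance; the rate
    is recovered from the median interval.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    if not csv_path.exists():
        raise TraceFormatError(f"missing trace CSV {csv_path}")
    if not json_path.exists():
        raise TraceMetadataError(f"missing sidecar {json_path}")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if not {"time_ms", "voltage_mV"}.issubset(df.columns):
        raise TraceFormatError("trace CSV must have columns time_ms, voltage_mV")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise TraceFormatError("trace must contain at least 2 samples")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if dt <= 0 or np.any(np.abs(dts - dt) > _DT_RTOL * dt):
        raise TraceFormatError("non-uniform sampling beyond tolerance")
    meta = json.loads(json_path.read_text())
    events = [
        (ev["onset_ms"], protocol_from_dict(ev["protocol"]))
        for ev in meta.get("stim_events", [])
    ]
    rate = meta.get("sampling_rate_khz", 1.0 / dt)
    if abs(rate - 1.0 / dt) > _DT_RTOL * rate:
        raise TraceMetadataError(
            f"sidecar sampling rate {rate} kHz disagrees with CSV spacing {1.0/dt} kHz"
        )
    try:
        return Trace(
            sampling_rate=rate,
            samples=df["voltage_mV"].to_numpy(dtype=float),
            t_start=meta.get("t_start_ms", float(t[0])),
            cell_id=meta.get("cell_id", "cell0"),
            cell_type=meta.get("cell_type", "N"),
            stim_events=events,
        )
    except TraceMetadataError:
        raise
    except Exception as exc:  # invariant failures surface as metadata errors
        raise TraceMetadataError(str(exc)) from exc
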