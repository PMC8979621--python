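"""Synthetic membrane-voltage traces with known ground truth.

The generator emulates the response structure of leech mechanosensory
neurons under pulsed ultrasound and electrical step stimulation:

* a slow depolarization ``u(t)`` that accumulates during tone bursts,
  saturates softly, and decays with a long time constant after each burst,
  so the effect outlasts the stimulation::

      on-state:   du/dt = g * I_sppa * (1 - u/u_max)
      off-state:  du/dt = -u / tau_slow

  with gain ``g`` in mV per (mW/cm^2 * s).  Both phases are integrated with
  the exact exponential update, so noise-free simulations match the
  closed-form solution to machine precision;

* threshold firing: a spike is emitted whenever ``u`` plus the (temporally
  correlated) membrane noise exceeds a per-cell threshold outside the
  refractory interval.  Because ``u`` grows during bursts and persists
  between them, spikes cluster toward burst ends and can occur after the
  stimulation has stopped;

* electrical step responses with a fast membrane time constant, a single
  onset-locked spike when the step clears threshold (spike-frequency
  adaptation is collapsed to "first crossing only"), and a small
  post-stimulus undershoot below the resting level;

* spliced action-potential waveforms whose peak-to-trough amplitude and
  half-amplitude fall width are drawn per spike from modality-specific
  log-normal distributions, parameterized by their ordinary mean and SD so
  that sample means of downstream measurements are directly comparable to
  the nominal values.

Every simulated trace comes with a :class:`SyntheticGroundTruth` recording
the true spike times, the drawn waveform parameters, the noise-free ``u``
trajectory and the true per-cycle depolarization, so detection and
morphometry can be validated exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .acoustics import (
    Medium,
    Modality,
    StimProtocol,
    WATER,
    burst_timing,
    compute_isppa,
)
from .errors import DomainError
from .subthreshold import build_schedule
from .traces import Trace, write_trace

__all__ = [
    "CellParams",
    "APTemplateParams",
    "SyntheticGroundTruth",
    "ExperimentDataset",
    "default_el_control",
    "simulate_membrane",
    "generate_cell_population",
    "generate_experiment",
]

#: Default digitization rate, kHz.
DEFAULT_RATE_KHZ = 10.0
#: Onset-to-onset spacing of stimulation windows, ms.
DEFAULT_WINDOW_SPACING_MS = 2000.0
#: Pre-stimulus padding, ms (long enough for the DC=1 pre-onset baseline).
DEFAULT_PRE_MS = 1000.0
#: Correlation time of the membrane noise, ms.
NOISE_TAU_MS = 2.0
#: EL post-stimulus undershoot amplitude (mV) and recovery time constant (ms).
EL_UNDERSHOOT_MV = 2.0
EL_UNDERSHOOT_TAU_MS = 50.0


@dataclass(frozen=True)
class CellParams:
    """Biophysical parameters of one simulated cell.

    ``threshold_theta`` is the firing threshold in mV above rest; ``us_gain``
    converts acoustic intensity into depolarization rate.  P cells attenuate
    the ultrasound gain by ``p_cell_attenuation`` and halve ``tau_slow``,
    reflecting their high-pass membrane behaviour relative to the low-pass
    N cells.
    """

    cell_id: str = "cell0"
    cell_type: str = "N"
    v_rest: float = -40.0
    noise_sigma: float = 0.3
    threshold_theta: float = 8.0
    us_gain: float = 1.0
    tau_slow: float = 300.0
    u_max: float = 12.0
    refractory: float = 10.0
    p_cell_attenuation: float = 0.25
    el_gain: float = 3.0
    el_tau: float = 10.0

    def __post_init__(self) -> None:
        if not (self.tau_slow > 0 and self.u_max > 0):
            raise DomainError("tau_slow and u_max must be positive")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be non-negative")
        if not (0.0 <= self.p_cell_attenuation <= 1.0):
            raise DomainError("p_cell_attenuation must be in [0, 1]")
        for name in ("v_rest", "threshold_theta", "us_gain", "refractory"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"{name} must be finite")

    @property
    def effective_us_gain(self) -> float:
        if self.cell_type == "P":
            return self.us_gain * self.p_cell_attenuation
        return self.us_gain

    @property
    def effective_tau_slow(self) -> float:
        if self.cell_type == "P":
            return self.tau_slow * 0.5
        return self.tau_slow


@dataclass(frozen=True)
class APTemplateParams:
    """Spliced action-potential waveform parameters.

    Amplitude (peak to after-spike trough, mV) and early-repolarization
    half-width (ms) are drawn log-normally per spike; ``(mean, sd)`` are the
    ordinary mean and standard deviation of the distribution.  The waveform
    rises linearly for ``rise_time`` ms to ``rest + A - ahp_depth``, falls
    linearly over twice the half-width to the trough at
    ``rest - ahp_depth``, then relaxes back to the ongoing membrane level
    over ``ahp_recovery`` ms, so the measured peak-to-subsequent-minimum
    amplitude equals the drawn ``A``.
    """

    rise_time: float = 1.0
    ahp_depth: float = 2.0
    ahp_recovery: float = 4.0
    us_amplitude: tuple[float, float] = (64.0, 45.0)
    us_width: tuple[float, float] = (2.35, 0.45)
    el_amplitude: tuple[float, float] = (79.0, 15.0)
    el_width: tuple[float, float] = (2.87, 0.70)

    def draw(self, rng: np.random.Generator, modality: Modality) -> tuple[float, float]:
        """One (amplitude_mV, half_width_ms) draw for the given modality."""
        if modality is Modality.US:
            amp, width = self.us_amplitude, self.us_width
        else:
            amp, width = self.el_amplitude, self.el_width
        return _lognormal(rng, *amp), _lognormal(rng, *width)


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Log-normal draw parameterized by its ordinary mean and SD."""
    if mean <= 0:
        raise DomainError("log-normal mean must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


@dataclass
class SyntheticGroundTruth:
    """Generator-side record of what was actually simulated."""

    spike_times: list[float] = field(default_factory=list)
    spike_amplitudes: list[float] = field(default_factory=list)
    spike_widths: list[float] = field(default_factory=list)
    spike_modalities: list[str] = field(default_factory=list)
    spike_windows: list[int | None] = field(default_factory=list)
    delta_v_true: list[list[float]] = field(default_factory=list)
    responder: bool = False
    u: np.ndarray | None = None

    def spikes_in_window(self, window_id: int) -> list[float]:
        return [
            t
            for t, w in zip(self.spike_times, self.spike_windows)
            if w == window_id
        ]

    def to_record(self) -> dict:
        """JSON-serializable summary (omits the dense u trajectory)."""
        return {
            "spike_times": self.spike_times,
            "spike_amplitudes": self.spike_amplitudes,
            "spike_widths": self.spike_widths,
            "spike_modalities": self.spike_modalities,
            "spike_windows": self.spike_windows,
            "delta_v_true": self.delta_v_true,
            "responder": self.responder,
        }


def default_el_control(current: float = 3.0, duration: float = 0.3) -> StimProtocol:
    """Electrical control pulse interleaved between US windows."""
    return StimProtocol(
        modality=Modality.EL,
        el_current=current,
        el_duration=duration,
        isi=1.0,
    )


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _ar1_noise(rng, n: int, sigma: float, dt: float, tau: float) -> np.ndarray:
    """Stationary Gaussian AR(1) noise with SD sigma and correlation time tau."""
    if sigma == 0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    eps = rng.standard_normal(n)
    x = lfilter([math.sqrt(1 - a * a)], [1.0, -a], eps)
    return sigma * x


def _us_drive(
    n: int,
    dt: float,
    on_segments: list[tuple[float, float]],
    isppa: float,
    gain: float,
    tau_slow: float,
    u_max: float,
) -> np.ndarray:
    """Noise-free slow depolarization u(t), exact exponential stepping."""
    u = np.zeros(n)
    if gain <= 0 or isppa <= 0 or not on_segments:
        return u
    rate_on = gain * isppa / (u_max * 1000.0)  # per ms
    t_idx = 0
    u0 = 0.0
    for start, end in on_segments:
        i0 = int(round(start / dt))
        i1 = int(round(end / dt))
        i0, i1 = max(i0, 0), min(i1, n)
        if i0 > t_idx:  # off-decay up to the burst
            dt_rel = (np.arange(t_idx, i0) - (t_idx - 1)) * dt
            u[t_idx:i0] = u0 * np.exp(-dt_rel / tau_slow)
            u0 = u[i0 - 1]
        if i1 > i0:
            dt_rel = (np.arange(i0, i1) - (i0 - 1)) * dt
            u[i0:i1] = u_max + (u0 - u_max) * np.exp(-rate_on * dt_rel)
            u0 = u[i1 - 1]
        t_idx = i1
    if t_idx < n:
        dt_rel = (np.arange(t_idx, n) - (t_idx - 1)) * dt
        u[t_idx:n] = u0 * np.exp(-dt_rel / tau_slow)
    return u


def _el_drive(
    n: int,
    dt: float,
    onset_ms: float,
    duration_ms: float,
    step_mv: float,
    el_tau: float,
    undershoot_mv: float = EL_UNDERSHOOT_MV,
    undershoot_tau: float = EL_UNDERSHOOT_TAU_MS,
) -> np.ndarray:
    """Noise-free EL step response with post-stimulus undershoot."""
    v = np.zeros(n)
    i_on = int(round(onset_ms / dt))
    i_off = int(round((onset_ms + duration_ms) / dt))
    i_on, i_off = max(i_on, 0), min(i_off, n)
    if i_off > i_on:
        t_rel = (np.arange(i_on, i_off) - i_on) * dt
        v[i_on:i_off] = step_mv * (1.0 - np.exp(-t_rel / el_tau))
    if i_off < n:
        v_off = v[i_off - 1] if i_off > i_on else 0.0
        t_rel = (np.arange(i_off, n) - i_off) * dt
        v[i_off:n] = (v_off + undershoot_mv) * np.exp(-t_rel / el_tau) - (
            undershoot_mv
        ) * np.exp(-t_rel / undershoot_tau)
    return v


def _accept_with_refractory(
    candidate_idx: np.ndarray, refractory_samples: int
) -> list[int]:
    """Greedy earliest-first selection with a minimum index separation."""
    accepted: list[int] = []
    if candidate_idx.size == 0:
        return accepted
    pos = 0
    while pos < candidate_idx.size:
        i = int(candidate_idx[pos])
        accepted.append(i)
        pos = int(np.searchsorted(candidate_idx, i + refractory_samples, side="left"))
    return accepted


def _splice_template(
    d: np.ndarray,
    dt: float,
    i_start: int,
    amplitude: float,
    half_width: float,
    template: APTemplateParams,
) -> int:
    """Write one AP waveform (relative to rest) into d; returns peak index."""
    n = d.size
    n_rise = max(1, int(round(template.rise_time / dt)))
    n_fall = max(1, int(round(2.0 * half_width / dt)))
    n_rec = max(1, int(round(template.ahp_recovery / dt)))
    peak_rel = amplitude - template.ahp_depth
    trough_rel = -template.ahp_depth
    i_peak = min(i_start + n_rise, n - 1)
    i_trough = min(i_peak + n_fall, n - 1)
    i_rec = min(i_trough + n_rec, n - 1)
    start_val = d[i_start]
    end_val = d[i_rec]
    d[i_start : i_peak + 1] = np.linspace(start_val, peak_rel, i_peak - i_start + 1)
    d[i_peak : i_trough + 1] = np.linspace(peak_rel, trough_rel, i_trough - i_peak + 1)
    d[i_trough : i_rec + 1] = np.linspace(trough_rel, end_val, i_rec - i_trough + 1)
    return i_peak


def simulate_membrane(
    protocol: StimProtocol,
    cell: CellParams,
    seed,
    sampling_rate: float = DEFAULT_RATE_KHZ,
    template: APTemplateParams = APTemplateParams(),
    medium: Medium = WATER,
    pre_ms: float = DEFAULT_PRE_MS,
    window_spacing_ms: float = DEFAULT_WINDOW_SPACING_MS,
    tail_ms: float = 700.0,
    el_control: StimProtocol | None = None,
) -> tuple[Trace, SyntheticGroundTruth]:
    """Simulate one recording of ``protocol.n_windows`` stimulation windows.

    With a US protocol, windows start at ``pre_ms + k * window_spacing_ms``;
    if ``el_control`` is given, an electrical control window is interleaved
    halfway between consecutive US onsets.  A fixed seed gives a
    bit-identical trace on re-run.
    """
    for name in ("us_gain", "threshold_theta"):
        if not math.isfinite(getattr(cell, name)):
            raise DomainError(f"non-finite cell parameter {name}")
    rng = _rng_from(seed)
    dt = 1.0 / sampling_rate
    n_windows = protocol.n_windows
    total_ms = pre_ms + n_windows * window_spacing_ms + tail_ms
    n = int(round(total_ms * sampling_rate))

    spacing_s = window_spacing_ms / 1000.0
    main_prot = dataclasses.replace(
        protocol, isi=min(protocol.isi, spacing_s / (2.0 if el_control else 1.0))
    )
    events: list[tuple[float, StimProtocol]] = [
        (pre_ms + k * window_spacing_ms, main_prot) for k in range(n_windows)
    ]
    if el_control is not None:
        ctrl = dataclasses.replace(el_control, isi=spacing_s / 2.0)
        events += [
            (pre_ms + k * window_spacing_ms + window_spacing_ms / 2.0, ctrl)
            for k in range(n_windows)
        ]
    events.sort(key=lambda ev: ev[0])

    # --- noise-free drive relative to rest -------------------------------
    on_segments: list[tuple[float, float]] = []
    isppa = 0.0
    d_sub = np.zeros(n)
    for onset, prot in events:
        if prot.modality is Modality.US:
            isppa = compute_isppa(prot.p_rms, medium)
            on_segments += [(onset + s, onset + e) for s, e in burst_timing(prot)]
        else:
            step = cell.el_gain * (prot.el_current or 0.0)
            d_sub += _el_drive(
                n, dt, onset, (prot.el_duration or 0.0) * 1000.0, step, cell.el_tau
            )
    on_segments.sort()
    d_sub += _us_drive(
        n,
        dt,
        on_segments,
        isppa,
        cell.effective_us_gain,
        cell.effective_tau_slow,
        cell.u_max,
    )

    noise = _ar1_noise(rng, n, cell.noise_sigma, dt, NOISE_TAU_MS)

    # --- threshold crossings -> spike times ------------------------------
    drive = d_sub + noise
    candidates = np.flatnonzero(drive >= cell.threshold_theta)
    refractory_samples = max(1, int(round(cell.refractory * sampling_rate)))
    accepted = _accept_with_refractory(candidates, refractory_samples)

    el_spans = [
        (onset, onset + (prot.el_duration or 0.0) * 1000.0 + 100.0)
        for onset, prot in events
        if prot.modality is Modality.EL
    ]

    def _el_span(t: float) -> int | None:
        for k, (s, e) in enumerate(el_spans):
            if s <= t < e:
                return k
        return None

    spike_idx: list[int] = []
    seen_el_spans: set[int] = set()
    for i in accepted:
        t = i * dt
        span = _el_span(t)
        if span is not None:
            if span in seen_el_spans:  # adaptation: one spike per EL step
                continue
            seen_el_spans.add(span)
        spike_idx.append(i)

    # --- splice AP waveforms ---------------------------------------------
    d = d_sub.copy()
    truth = SyntheticGroundTruth(u=d_sub)
    detection_spans = []
    for wid, (onset, prot) in enumerate(events):
        if prot.modality is Modality.US:
            end = onset + prot.stim_duration + 100.0
        else:
            end = onset + (prot.el_duration or 0.0) * 1000.0 + 100.0
        detection_spans.append((wid, onset, end))

    for i in spike_idx:
        t = i * dt
        modality = Modality.EL if _el_span(t) is not None else Modality.US
        amp, width = template.draw(rng, modality)
        i_peak = _splice_template(d, dt, i, amp, width, template)
        window = next(
            (wid for wid, s, e in detection_spans if s <= i_peak * dt < e), None
        )
        truth.spike_times.append(i_peak * dt)
        truth.spike_amplitudes.append(amp)
        truth.spike_widths.append(width)
        truth.spike_modalities.append(modality.value)
        truth.spike_windows.append(window)

    samples = cell.v_rest + d + noise
    trace = Trace(
        sampling_rate=sampling_rate,
        samples=samples,
        t_start=0.0,
        cell_id=cell.cell_id,
        cell_type=cell.cell_type,
        stim_events=events,
    )

    # --- noise-free per-cycle depolarization ground truth ----------------
    u_trace = Trace(
        sampling_rate=sampling_rate,
        samples=d_sub,
        cell_id=cell.cell_id,
        cell_type=cell.cell_type,
    )
    for onset, prot in events:
        if prot.modality is not Modality.US:
            continue
        schedule = build_schedule(prot, onset)
        dv = [
            float(
                np.median(u_trace.samples[u_trace.index_at(r.start) : u_trace.index_at(r.end)])
                - np.median(u_trace.samples[u_trace.index_at(b.start) : u_trace.index_at(b.end)])
            )
            for b, r in schedule.cycles
        ]
        truth.delta_v_true.append(dv)
    truth.responder = any(
        w is not None
        and truth.spike_modalities[k] == Modality.US.value
        for k, w in enumerate(truth.spike_windows)
    )
    return trace, truth


def generate_cell_population(
    n_cells: int,
    seed,
    cell_type: str = "N",
    theta_mean: float = 6.0,
    theta_sd: float = 3.0,
    gain_mean: float = 1.0,
    gain_sd: float = 0.25,
    **overrides,
) -> list[CellParams]:
    """Draw a population of cells with log-normal threshold and gain spread.

    The wide per-cell firing-threshold distribution produces the large
    inter-cell variability of responsiveness seen experimentally: whether a
    cell is a responder emerges from its threshold relative to the
    depolarization attainable at the tested intensities.
    """
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    rng = _rng_from(seed)
    cells = []
    for i in range(n_cells):
        cells.append(
            CellParams(
                cell_id=f"{cell_type}{i:03d}",
                cell_type=cell_type,
                threshold_theta=_lognormal(rng, theta_mean, theta_sd),
                us_gain=_lognormal(rng, gain_mean, gain_sd),
                **overrides,
            )
        )
    return cells


@dataclass
class ExperimentDataset:
    """In-memory synthetic experiment: traces, ground truth, manifest."""

    traces: list[Trace]
    ground_truths: list[SyntheticGroundTruth]
    manifest: pd.DataFrame

    def write(self, out_dir: str | Path) -> Path:
        """Write trace CSV/JSON pairs, manifest.csv and ground_truth.json."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        paths = []
        for idx, trace in enumerate(self.traces):
            stem = out_dir / f"trace_{idx:04d}"
            write_trace(trace, stem)
            paths.append(stem.with_suffix(".csv").name)
        manifest["file"] = paths
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        gt = {f"trace_{i:04d}": t.to_record() for i, t in enumerate(self.ground_truths)}
        (out_dir / "ground_truth.json").write_text(json.dumps(gt, indent=1) + "\n")
        return out_dir


def generate_experiment(
    protocols: Sequence[StimProtocol],
    population: Sequence[CellParams],
    seed: int,
    el_control: StimProtocol | None = None,
    out_dir: str | Path | None = None,
    **sim_kwargs,
) -> ExperimentDataset:
    """One trace per cell x US protocol, with optional EL control windows.

    Per-trace seeds are derived from ``(seed, trace_index)`` so any trace can
    be regenerated independently of the rest of the dataset.
    """
    if len(protocols) == 0:
        raise DomainError("protocol grid must be non-empty")
    traces, truths, rows = [], [], []
    index = 0
    for cell in population:
        for prot in protocols:
            child_rng = np.random.default_rng(np.random.SeedSequence([seed, index]))
            trace, truth = simulate_membrane(
                prot, cell, child_rng, el_control=el_control, **sim_kwargs
            )
            traces.append(trace)
            truths.append(truth)
            rows.append(
                {
                    "trace_index": index,
                    "cell_id": cell.cell_id,
                    "cell_type": cell.cell_type,
                    "p_rms_kpa": prot.p_rms,
                    "duty_cycle": prot.duty_cycle,
                    "n_windows": prot.n_windows,
                    "n_true_spikes": len(truth.spike_times),
                    "responder": truth.responder,
                }
            )
            index += 1
    dataset = ExperimentDataset(traces, truths, pd.DataFrame(rows))
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
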