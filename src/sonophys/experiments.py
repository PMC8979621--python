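"""Reproducible study harnesses built from the generator and the pipeline.

Each function here wires the synthetic generator to the analysis pipeline
for one self-contained computational experiment: waveform-recovery runs for
the morphometry, the dose-response regression over the full protocol grid,
latency-versus-duty-cycle comparisons, and peristimulus firing counts.
They are used both by the test suite and by the results-reproduction
script, so the numbers those two report come from the same code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acoustics import Modality, StimProtocol, protocol_grid
from .spikes import analyze_trace_spikes
from .stats import RegressionResult, linear_regression
from .subthreshold import analyze_window
from .synthetic_data import (
    CellParams,
    generate_cell_population,
    generate_experiment,
    simulate_membrane,
)

__all__ = [
    "MorphometrySummary",
    "morphometry_recovery",
    "subthreshold_linearity",
    "latency_by_duty_cycle",
    "peristimulus_firing",
]

#: Excitable-cell firing threshold (mV above rest) used in recovery harnesses,
#: low enough that every stimulation window reliably produces spike trains.
_EXCITABLE_THETA = 2.0


@dataclass(frozen=True)
class MorphometrySummary:
    """Sample means of pipeline waveform measurements over many spikes."""

    modality: Modality
    n_spikes: int
    mean_amplitude: float
    mean_duration: float
    mean_ratio: float


def _excitable_cell(i: int, refractory: float) -> CellParams:
    return CellParams(
        cell_id=f"exc{i:03d}",
        threshold_theta=_EXCITABLE_THETA,
        refractory=refractory,
    )


def morphometry_recovery(
    modality: Modality,
    seed: int,
    n_cells: int | None = None,
    sampling_rate: float = 10.0,
) -> MorphometrySummary:
    """Measure AP amplitude/duration over a large set of triggered spikes.

    US mode drives excitable cells with a continuous 20 kPa stimulation so
    each window emits a spike train; EL mode uses suprathreshold current
    steps that evoke one onset-locked spike per window.  All measurements go
    through the standard detection + morphometry pipeline; NaN-duration
    (degenerate) events are dropped from the duration mean only.
    """
    modality = Modality(modality)
    if modality is Modality.US:
        n_cells = 20 if n_cells is None else n_cells
        protocol = StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=1.0)
        # longer refractory spaces the train so waveforms do not overlap
        cells = [_excitable_cell(i, refractory=20.0) for i in range(n_cells)]
    else:
        n_cells = 100 if n_cells is None else n_cells
        protocol = StimProtocol(
            modality=Modality.EL, el_current=4.0, el_duration=0.3, n_windows=3
        )
        cells = [_excitable_cell(i, refractory=10.0) for i in range(n_cells)]

    amplitudes, durations, ratios = [], [], []
    for i, cell in enumerate(cells):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        trace, _ = simulate_membrane(protocol, cell, rng, sampling_rate=sampling_rate)
        for events in analyze_trace_spikes(trace):
            for ev in events:
                if ev.subthreshold:
                    continue
                amplitudes.append(ev.amplitude)
                if math.isfinite(ev.duration) and ev.duration > 0:
                    durations.append(ev.duration)
                    ratios.append(ev.amplitude / ev.duration)
    return MorphometrySummary(
        modality=modality,
        n_spikes=len(amplitudes),
        mean_amplitude=float(np.mean(amplitudes)),
        mean_duration=float(np.mean(durations)),
        mean_ratio=float(np.mean(ratios)),
    )


def subthreshold_linearity(
    seed: int,
    n_cells: int = 24,
    pressures=(8.0, 12.0, 16.0, 20.0),
    duty_cycles=(0.05, 0.5, 1.0),
) -> tuple[RegressionResult, "np.ndarray", "np.ndarray"]:
    """Dose-response regression of mean depolarization on I_spta.

    Simulates the full pressure x duty-cycle grid on a default N-cell
    population, runs the windowed-median pipeline on every stimulation
    window, averages mean DV per protocol, and regresses it on I_spta.
    Returns (regression, ispta_values, mean_dv_values).
    """
    protocols = protocol_grid(pressures, duty_cycles)
    population = generate_cell_population(n_cells, np.random.SeedSequence([seed, 104729]))
    dataset = generate_experiment(protocols, population, seed)
    ispta_to_dv: dict[float, list[float]] = {}
    for trace in dataset.traces:
        for onset, prot in trace.stim_events:
            if prot.modality is not Modality.US:
                continue
            res = analyze_window(trace, prot, onset)
            ispta_to_dv.setdefault(round(res.ispta, 9), []).append(res.mean_delta_v)
    x = np.array(sorted(ispta_to_dv))
    y = np.array([float(np.mean(ispta_to_dv[k])) for k in sorted(ispta_to_dv)])
    return linear_regression(x, y), x, y


def latency_by_duty_cycle(
    seed: int,
    duty_cycles=(0.05, 0.5),
    p_rms: float = 20.0,
    n_cells: int = 1500,
    theta_mean: float = 3.0,
    theta_sd: float = 1.5,
    min_spikes: int = 200,
) -> dict[float, np.ndarray]:
    """Pipeline-measured spike latencies per duty cycle at fixed pressure.

    Uses a moderately excitable population (thresholds of a few mV) so the
    sparse 5% duty cycle still recruits enough cells for a stable latency
    distribution.  Cells are simulated with a single stimulation window
    each; latencies come from the standard detection pipeline.
    """
    latencies: dict[float, list[float]] = {dc: [] for dc in duty_cycles}
    for dc in duty_cycles:
        protocol = StimProtocol(
            modality=Modality.US, p_rms=p_rms, duty_cycle=dc, n_windows=1
        )
        population = generate_cell_population(
            n_cells, np.random.SeedSequence([seed, int(dc * 1000)]),
            theta_mean=theta_mean, theta_sd=theta_sd,
        )
        for i, cell in enumerate(population):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, int(dc * 1000), i])
            )
            trace, _ = simulate_membrane(
                protocol, cell, rng, pre_ms=500.0, window_spacing_ms=900.0,
                tail_ms=400.0,
            )
            for events in analyze_trace_spikes(trace):
                latencies[dc].extend(
                    ev.latency for ev in events if not ev.subthreshold
                )
            if len(latencies[dc]) >= min_spikes and i >= 199:
                break
    return {dc: np.asarray(v) for dc, v in latencies.items()}


def peristimulus_firing(
    seed: int,
    n_cells: int = 30,
    p_rms: float = 20.0,
    duty_cycle: float = 1.0,
) -> tuple[int, int]:
    """True spike counts in pre-stimulus vs. post-stimulus 100 ms intervals.

    Counts generator ground-truth spikes in [onset-100, onset) and in
    [onset+SD, onset+SD+100) over a default population.  With a slow decay
    of the accumulated depolarization, firing persists after the stimulus
    ends while the pre-stimulus baseline stays near-silent.
    """
    protocol = StimProtocol(modality=Modality.US, p_rms=p_rms, duty_cycle=duty_cycle)
    population = generate_cell_population(n_cells, np.random.SeedSequence([seed, 7919]))
    dataset = generate_experiment([protocol], population, seed)
    pre = post = 0
    for trace, truth in zip(dataset.traces, dataset.ground_truths):
        for onset, prot in trace.stim_events:
            if prot.modality is not Modality.US:
                continue
            sd = prot.stim_duration
            for t in truth.spike_times:
                if onset - 100.0 <= t < onset:
                    pre += 1
                elif onset + sd <= t < onset + sd + 100.0:
                    post += 1
    return pre, post
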