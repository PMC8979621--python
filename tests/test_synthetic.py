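"""Generator contracts: determinism, closed forms, populations, datasets."""

import numpy as np
import pytest

from sonophys.acoustics import Modality, StimProtocol, compute_isppa, protocol_grid
from sonophys.errors import DomainError
from sonophys.spikes import analyze_trace_spikes
from sonophys.subthreshold import build_schedule, delta_v, mean_response
from sonophys.synthetic_data import (
    APTemplateParams,
    CellParams,
    _lognormal,
    generate_cell_population,
    generate_experiment,
    simulate_membrane,
)


class TestSimulateMembrane:
    def test_zero_gain_gives_pure_noise(self):
        cell = CellParams(us_gain=0.0, threshold_theta=100.0)
        prot = StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=1.0,
                            n_windows=1)
        trace, truth = simulate_membrane(prot, cell, seed=0)
        dv = mean_response(delta_v(trace, build_schedule(prot, 1000.0)))
        assert abs(dv) < 0.1
        assert np.all(np.abs(trace.samples - cell.v_rest) < 5 * cell.noise_sigma)
        assert truth.spike_times == []

    def test_noise_free_matches_ode_closed_form(self):
        """sigma=0, DC=1: pipeline DV equals the linear-ODE solution at 150 ms."""
        cell = CellParams(noise_sigma=0.0, threshold_theta=100.0, us_gain=1.0)
        for p_rms in (8.0, 20.0):
            prot = StimProtocol(modality=Modality.US, p_rms=p_rms, duty_cycle=1.0,
                                n_windows=1)
            trace, _ = simulate_membrane(prot, cell, seed=1)
            dv = delta_v(trace, build_schedule(prot, 1000.0))[0]
            isppa = compute_isppa(p_rms)
            rate_per_ms = cell.us_gain * isppa / (cell.u_max * 1000.0)
            expected = cell.u_max * (1.0 - np.exp(-rate_per_ms * 150.0))
            assert dv == pytest.approx(expected, abs=1e-3)

    def test_fixed_seed_bit_identical(self):
        cell = CellParams(threshold_theta=4.0)
        prot = StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=0.5)
        t1, g1 = simulate_membrane(prot, cell, seed=77)
        t2, g2 = simulate_membrane(prot, cell, seed=77)
        np.testing.assert_array_equal(t1.samples, t2.samples)
        assert g1.spike_times == g2.spike_times
        assert g1.spike_amplitudes == g2.spike_amplitudes

    def test_depolarization_outlasts_stimulus(self):
        """u decays with tau_slow after the window instead of vanishing."""
        cell = CellParams(noise_sigma=0.0, threshold_theta=100.0)
        prot = StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=1.0,
                            n_windows=1)
        trace, truth = simulate_membrane(prot, cell, seed=0)
        i_end = trace.index_at(1300.0)
        u_end = truth.u[i_end - 1]
        u_100_later = truth.u[trace.index_at(1400.0)]
        assert u_end > 1.0
        assert u_100_later == pytest.approx(u_end * np.exp(-100.0 / 300.0), rel=0.01)

    def test_el_undershoot_below_rest(self):
        """Post-EL membrane dips below the pre-stimulus level for ~100 ms."""
        cell = CellParams(noise_sigma=0.0, threshold_theta=100.0)
        prot = StimProtocol(modality=Modality.EL, el_current=3.0, el_duration=0.3,
                            n_windows=1)
        trace, _ = simulate_membrane(prot, cell, seed=0)
        post = trace.samples[trace.index_at(1320.0):trace.index_at(1400.0)]
        assert np.median(post) < cell.v_rest - 0.3

    def test_non_finite_cell_rejected(self):
        with pytest.raises(DomainError):
            CellParams(us_gain=float("nan"))


class TestTemplateDistributions:
    def test_lognormal_moments_match_nominal(self):
        rng = np.random.default_rng(0)
        draws = np.array([_lognormal(rng, 64.0, 45.0) for _ in range(40_000)])
        assert draws.mean() == pytest.approx(64.0, rel=0.02)
        assert draws.std() == pytest.approx(45.0, rel=0.05)
        assert np.all(draws > 0)

    def test_modality_specific_draws(self):
        rng = np.random.default_rng(1)
        template = APTemplateParams()
        us = np.array([template.draw(rng, Modality.US) for _ in range(4000)])
        el = np.array([template.draw(rng, Modality.EL) for _ in range(4000)])
        assert us[:, 0].mean() == pytest.approx(64.0, abs=3.0)
        assert el[:, 0].mean() == pytest.approx(79.0, abs=3.0)
        assert us[:, 1].mean() == pytest.approx(2.35, abs=0.05)
        assert el[:, 1].mean() == pytest.approx(2.87, abs=0.05)


class TestPopulation:
    def test_single_cell(self):
        cells = generate_cell_population(1, seed=0)
        assert len(cells) == 1
        assert cells[0].cell_type == "N"

    def test_responder_fraction_in_observed_range(self):
        """Across seeds, 40-80% of a 44-cell N population fires to the grid's
        strongest protocols (continuous high-pressure windows)."""
        prot = StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=1.0)
        for seed in (0, 1):
            cells = generate_cell_population(44, seed=seed)
            responders = 0
            for i, cell in enumerate(cells):
                _, truth = simulate_membrane(
                    prot, cell, seed=np.random.default_rng(
                        np.random.SeedSequence([seed, i])))
                responders += truth.responder
            assert 0.4 <= responders / 44 <= 0.8

    def test_p_cells_rarely_spike(self):
        """P cells see attenuated gain, so spiking is a rare event."""
        prot = StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=1.0)
        cells = generate_cell_population(30, seed=3, cell_type="P")
        n_spiking = 0
        for i, cell in enumerate(cells):
            _, truth = simulate_membrane(prot, cell, seed=1000 + i)
            n_spiking += truth.responder
        assert n_spiking <= 3

    def test_invalid_count_rejected(self):
        with pytest.raises(DomainError):
            generate_cell_population(0, seed=0)


class TestExperiment:
    def test_grid_counts(self):
        """4 pressures x 3 DCs x 5 cells -> 60 traces, 180 US windows."""
        grid = protocol_grid()
        cells = generate_cell_population(5, seed=0)
        dataset = generate_experiment(grid, cells, seed=0)
        assert len(dataset.traces) == 60
        n_us_windows = sum(
            sum(1 for _, p in t.stim_events if p.modality is Modality.US)
            for t in dataset.traces
        )
        assert n_us_windows == 180
        assert len(dataset.manifest) == 60

    def test_seeded_regeneration_identical(self):
        grid = protocol_grid(pressures=(20.0,), duty_cycles=(1.0,))
        cells = generate_cell_population(2, seed=5)
        d1 = generate_experiment(grid, cells, seed=9)
        d2 = generate_experiment(grid, cells, seed=9)
        for t1, t2 in zip(d1.traces, d2.traces):
            np.testing.assert_array_equal(t1.samples, t2.samples)

    def test_noise_free_linear_regime_r2_near_one(self):
        """Without noise and far from saturation, DV is exactly linear in I_spta
        at fixed DC."""
        from sonophys.stats import linear_regression
        from sonophys.subthreshold import analyze_window

        grid = protocol_grid(duty_cycles=(1.0,))
        cells = [CellParams(noise_sigma=0.0, threshold_theta=100.0, us_gain=0.02)]
        dataset = generate_experiment(grid, cells, seed=0)
        xs, ys = [], []
        for trace in dataset.traces:
            for onset, prot in trace.stim_events:
                if prot.modality is Modality.US:
                    res = analyze_window(trace, prot, onset)
                    xs.append(res.ispta)
                    ys.append(res.mean_delta_v)
        assert linear_regression(xs, ys).r_squared > 0.999

    def test_ground_truth_consistent_with_detection(self):
        """Detected and true spikes agree on count per window for clean cells."""
        prot = StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=1.0)
        cell = CellParams(threshold_theta=3.0, refractory=25.0)
        trace, truth = simulate_membrane(prot, cell, seed=2)
        per_window = analyze_trace_spikes(trace)
        for wid, events in enumerate(per_window):
            true_in_window = truth.spikes_in_window(wid)
            big = [
                t for t, a in zip(truth.spike_times, truth.spike_amplitudes)
                if t in true_in_window and a >= 25.0
            ]
            det_times = [e.peak_time for e in events]
            for t in big:
                assert min(abs(d - t) for d in det_times) < 1.5

    def test_empty_grid_rejected(self):
        with pytest.raises(DomainError):
            generate_experiment([], generate_cell_population(1, 0), seed=0)

    def test_dataset_write_round_trip(self, tmp_path):
        from sonophys.traces import read_trace

        grid = protocol_grid(pressures=(12.0,), duty_cycles=(0.5,))
        cells = generate_cell_population(1, seed=0)
        dataset = generate_experiment(grid, cells, seed=0, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "ground_truth.json").exists()
        back = read_trace(tmp_path / "trace_0000")
        np.testing.assert_array_equal(back.samples, dataset.traces[0].samples)
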