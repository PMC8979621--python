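# Methods

## The measurement problem

Low-intensity ultrasound depolarizes excitable cells and can trigger action
potentials, but the relevant dose metric and the waveform signature of
US-evoked spikes are subtle: the depolarization accumulates over the
on-time of a pulsed protocol, outlasts the stimulus, and interacts with a
per-cell firing threshold. This package implements the complete analysis
chain for such experiments — dosimetry, stimulus-aligned windowing,
subthreshold statistics, spike morphometry, and the statistical layer — and
pairs it with a synthetic generator so the chain can be validated end to
end with known ground truth.

## Dosimetry

Exposure is summarized by the spatial-peak temporal-average intensity

    I_spta = P_rms² / (ρ c) · DC        [mW/cm²]

with `P_rms` the RMS pressure at the target (kPa), `ρc` the acoustic
impedance of the coupling medium and `DC` the duty cycle; `I_sppa` is the
DC = 1 case. The default medium is water at ρ = 1000 kg/m³,
c = 1482 m/s (≈ 20 °C); both are configurable. These constants make the
standard 4-pressure × 3-DC protocol grid span 0.216 to 26.99 mW/cm², i.e.
0.2–27 mW/cm² at reporting precision. Intensity bins (very low … very
high) use inclusive upper edges at 0.5, 2.5, 5 and 10 mW/cm².

Internally the arithmetic is SI (Pa, W/m²); conversion to kPa and mW/cm²
happens only at the interface, so unit errors cannot compound.

## Windowing and subthreshold statistics

All times are milliseconds and all intervals half-open `[start, end)`;
sample `i` of a trace covers `[t_start + i/rate, t_start + (i+1)/rate)`.

For each stimulation window the schedule builder produces:

* per-cycle (baseline, response) pairs — for pulsed protocols the response
  is the tone burst and the baseline the equal-duration interval
  immediately preceding it (the tail of the previous off period); for
  continuous stimulation a single 300 ms response against the preceding
  300 ms;
* off-interval epochs (the full T-off periods, plus the pre-onset and
  post-offset intervals at DC = 1) used for the baseline-variation
  statistic;
* the spike-counting window: stimulus duration + 100 ms.

Per-cycle depolarization is `ΔV_i = median(response_i) − median(baseline_i)`
(positive = depolarization); window-level response is the arithmetic mean
over cycles. Medians make the estimate robust to occasional spikes riding
on the depolarization. Baseline variation `B_i` is the difference of
consecutive off-interval medians and is the statistic that reveals
accumulation outlasting individual bursts: it is positive during a
stimulation block when the slow component has not decayed between bursts.

The two families of windows deliberately differ in duration (burst-length
baselines for ΔV; full off-intervals, 95/50/300 ms, for B_i) because they
estimate different things: instantaneous burst response versus drift of the
inter-burst floor.

## Spike detection and morphometry

Detection operates per stimulation window. The criterion is a local maximum
exceeding `median(pre-stimulus baseline) + 15 mV`, at least one refractory
interval (default 10 ms) from its neighbours, with a minimum prominence of
10 mV. The prominence requirement is not redundant with the absolute
threshold: a sustained depolarization plateau (e.g. an EL step of +15 mV or
more) would otherwise turn its own noise maxima into "spikes". The baseline
is taken per stimulation, not globally, so slow drift between windows does
not shift the criterion. An optional second pass at a lower threshold flags
small events as `subthreshold`; these are reported but excluded from
success rates.

Measurements per spike:

* **amplitude** — peak value minus the subsequent minimum, searched up to
  the next spike peak. For the last spike of a window the search (and the
  peak-finding segment) extends 20 ms past the counting-window edge: the
  counting window decides *which* spikes are counted, but a repolarization
  that happens to straddle the edge should not corrupt the waveform
  measurement or mask the peak entirely.
* **duration** (early repolarization) — time from the peak to the first
  crossing of `peak − amplitude/2` on the falling flank, linearly
  interpolated between samples. The peak→crossing convention is used
  (rather than crossing→crossing on both flanks) because the rising flank
  is frequently contaminated by the stimulus artifact in low-amplitude
  spikes. Waveforms whose fall never reaches the half level before the
  trough get duration NaN and are flagged rather than guessed.
* **ratio** — amplitude/duration, proportional to the decay-phase slope.
* **latency** — peak time minus stimulation-window onset.

The first suprathreshold spike of each window is tagged `first`, the rest
`following`. Success rate is the fraction of stimulation windows with at
least one suprathreshold spike inside the counting window.

First-order detrending of a signal window (`detrend_window`) is available
and idempotent; it removes slow ramps before waveform measurements when
needed.

## Statistics

* OLS regression (`scipy.stats.linregress`) reporting slope, intercept,
  R² = 1 − SS_res/SS_tot and the slope F-test p-value; constant-y input
  returns slope 0, R² 0 by convention, constant-x input is a degenerate
  design error.
* Kruskal–Wallis with tie correction (`scipy.stats.kruskal`); an
  all-identical pooled sample returns H = 0, p = 1 instead of failing.
* Two-way factorial ANOVA via `statsmodels` OLS + `anova_lm` with Type II
  sums of squares — chosen because trace counts are unbalanced across the
  DC × pressure cells of a real recording campaign, where Type I sums
  depend on term order. Empty design cells raise an error naming the cell;
  designs without replication fall back to the additive model and report
  the interaction as NaN.
* No multiple-testing correction is applied anywhere; pairwise group
  comparisons are plain pairwise Kruskal–Wallis tests on raw p-values.

## The synthetic generator

The generator is a phenomenological integrate-and-threshold model chosen to
reproduce the *structure* of the recorded responses, not their biophysics:

    on-state  (tone burst):  du/dt = g · I_sppa · (1 − u/u_max)
    off-state:               du/dt = −u / τ_slow

with membrane voltage `V = v_rest + u + η`, where η is Gaussian AR(1) noise
(σ = 0.3 mV, 2 ms correlation time). Both phases use the exact exponential
update per segment, so noise-free traces equal the closed-form ODE solution
to machine precision — this is asserted in the tests. A spike is emitted
whenever `u + η` exceeds the per-cell threshold θ outside the refractory
interval; because `u` rises during bursts and persists between them, spike
latencies cluster toward burst ends, shift right with duty cycle, and
firing continues after the stimulus — the qualitative signatures of
accumulation.

Key defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `v_rest` | −40 mV | resting potential of leech mechanosensory somata |
| `us_gain` g | 1.0 mV/(mW/cm²·s) | depolarization rate per unit I_sppa |
| `u_max` | 12 mV | soft saturation ceiling of the slow depolarization |
| `τ_slow` | 300 ms | post-burst decay; makes the effect outlast the stimulus |
| θ population | log-normal, mean 6, SD 3 mV | per-cell firing threshold above rest |
| `noise_sigma` | 0.3 mV | recording + membrane noise |
| refractory | 10 ms | minimum inter-spike interval |
| EL gain / τ | 3 mV/nA, 10 ms | current step → fast step depolarization |
| EL undershoot | 2 mV, 50 ms recovery | post-step hyperpolarization below rest |
| window spacing | 2 s | onset-to-onset spacing of stimulation windows |

`u_max` sits below the 15 mV detection threshold by construction: a
saturated subthreshold plateau must not itself satisfy the spike criterion,
otherwise plateau noise would be detected as firing — a constraint any
consistent choice of (saturation, detection threshold) has to respect.

The population threshold distribution and gain were calibrated once against
three design targets — a responder fraction of a 44-cell N population in
the 0.4–0.8 range under the strongest protocol, a mean-ΔV vs I_spta
regression R² of at least 0.78 over the 12-protocol grid, and success rates
increasing with intensity bin — and then frozen. P cells apply a gain
attenuation (0.25) and a halved τ_slow, implementing their high-pass
membrane behaviour; under the same grid they depolarize weakly and spike
rarely.

Spike waveforms are spliced into the deterministic trace: linear rise
(1 ms) to `v_rest + A − 2 mV`, linear fall over twice the drawn half-width
to a trough at `v_rest − 2 mV`, then recovery to the ongoing membrane
level. Amplitude A and half-width w are drawn per spike from
modality-specific log-normal distributions (US: 64 ± 45 mV, 2.35 ± 0.45 ms;
EL: 79 ± 15 mV, 2.87 ± 0.70 ms), parameterized so that the distribution's
*ordinary* mean and SD equal those values — a truncated normal would bias
the mean, while the log-normal keeps positive support and preserves it.
Because the trough sits 2 mV below rest and everything after the spike
stays above it, the pipeline's peak-to-subsequent-minimum measurement
recovers the drawn A, and the half-width is recovered to within one sample
interval (verified against ground truth in the tests). One deliberate,
realistic exception: US amplitude draws below ≈17 mV produce peaks under
the 15 mV detection criterion and are censored, exactly as small spikes are
censored in a real recording; this biases the measured US amplitude mean
upward by roughly 2 mV relative to the nominal 64 mV.

EL windows evoke a single onset-locked spike when the step clears
threshold — a collapsed model of spike-frequency adaptation during
sustained current injection — followed by the post-stimulus undershoot.

Windows are spaced 2 s apart (against τ_slow = 300 ms, i.e. > 6 time
constants, so windows are independent); the tens-of-seconds
inter-stimulation intervals of a live recording session carry no additional
information for the analysis and would only inflate simulation time.
Per-trace random streams derive from `(seed, trace_index)`, so any trace of
a dataset can be regenerated alone, and a fixed seed yields bit-identical
traces and byte-identical pipeline CSVs.

### What the generator does and does not emulate

It emulates: intensity- and DC-dependent accumulation with saturation,
slow post-stimulus decay, threshold firing with large inter-cell
variability, latency structure, modality-specific waveform statistics, EL
step responses with undershoot. It does not emulate: stimulus artifacts,
electrode drift or seal degradation, bursting dynamics or true refractory
adaptation, channel-level mechanisms (no intramembrane cavitation or
thermal models), or acoustic propagation through the preparation. Passing
tests therefore demonstrate that the *analysis* is correct and calibrated
on data with the reported structure — not that the generator is a
biophysical model of sonicated neurons.

## Problem sizes used by the reproduction script

The waveform-recovery runs measure ≈1000 US spikes (20 excitable cells,
three continuous 20 kPa windows each, 20 ms refractory so trains do not
overlap) and 300 EL spikes (100 cells × 3 suprathreshold steps); at these
sizes the standard errors of the measured means (≈1.4 mV US amplitude,
≈0.015 ms US duration) are several times smaller than the tolerances they
are compared against. The dose-response run simulates the full 12-protocol
grid on 24 default cells (288 traces). Everything completes in well under a
minute on one CPU.

## Known limitations

* The half-width convention (peak → half-level crossing) differs from a
  crossing→crossing width by up to half a rise time for asymmetric spikes;
  sensitivity to this choice is not currently surfaced as an option.
* Amplitude measurement near the counting-window edge uses a fixed 20 ms
  measurement margin; a spike peaking in the last fraction of a
  millisecond of the margin window would still be truncated.
* The two-way ANOVA requires replication for the interaction term; single
  observations per cell silently reduce to the additive model (reported as
  NaN interaction) rather than erroring.
* Success-rate confidence intervals are not computed; at three windows per
  protocol per cell they would be wide, and the intended use is pooling
  across cells.
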