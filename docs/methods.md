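# Methods

## Model and procedure

The package simulates a closed-loop, brain-state-dependent TMS protocol in
discrete 1-s ticks aligned with the analysis cadence. One *section* runs
from a threshold reset to the next stimulus:

1. each analyzing tick computes Coh(β) on the most recent 1-s two-channel
   window and fires iff Coh(β) ≥ current threshold;
2. a stimulus resets the threshold to the calibrated initial value θ₀,
   draws one MEP amplitude at the stimulus-time coherence, and pauses
   analysis for `pause` seconds;
3. without a stimulus the section clock keeps running (wall clock — the
   pause counts toward it) and, once it exceeds `modification_onset`, the
   threshold is loosened by `delta` per second down to `threshold_floor`;
4. a section reaching `recharge_limit` seconds logs a capacitor-recharge
   marker at every multiple of the limit; it has no algorithmic effect.

The comparison is `>=` and the tick ordering is compare-first: the
threshold seen at tick t has decayed max(0, t−1−onset) times, and after
tick t it equals max(floor, θ₀ − delta·max(0, t − onset)) exactly. Event
times are integer seconds.

Calibration selects θ₀ as the `target_count`-th largest of the 180
baseline fragment values. This reproduces "`target_count` crossings in the
baseline" by construction: with distinct values the count of fragments ≥ θ₀
is exactly `target_count`; ties resolve toward more crossings, matching
the ≥ trigger condition. Predicted session time is
n_stimuli · (baseline_duration / target_count) plus one analysis tick per
stimulus — a documented convention, since several conventions reproduce a
"once per ~30 s" prediction equally well.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `dsp.fs` | 500 | Hz | sampling rate of both channels |
| `dsp.filter_low/high/order` | 1 / 30 / 4 | Hz, – | causal Butterworth band-pass applied once to the stream |
| `dsp.seg_len`, `overlap`, `taper` | 250, 0.5, hann | samples, –, – | Welch settings: 3 segments and nine 2-Hz bins per 1-s window |
| `dsp.band` | (14, 30) | Hz | β band, endpoints inclusive |
| `trigger.delta` | 0.05 | 1/s | threshold loosening rate after the onset |
| `trigger.modification_onset` | 30 | s | section time before loosening starts |
| `trigger.pause` | 10 | s | post-stimulus analysis pause |
| `trigger.recharge_limit` | 60 | s | stimulator standby limit (marker only) |
| `trigger.n_stimuli` | 10 | – | stimuli per session |
| `trigger.target_count` | 6 | – | baseline crossings defining θ₀ |
| `synth.mixing_mean`, `drift_amplitude`, `drift_period_s` | 0.8, 0.15, 40 | –, –, s | slow sinusoidal drift of the mixing weight a(t) ∈ [0.65, 0.95] |
| `mep.mu`, `sigma_max`, `sigma_min` | 1.0, 0.6, 0.1 | mV, –, – | MEP level and relative dispersion at Coh(β) = 0 / 1 |
| `stats.alpha` | 0.05 | – | two-sided F-test level |

The Welch segmentation inside a 1-s window is a documented convention: it
is the minimum segmentation giving a non-degenerate MSC at the 1-s cadence
(single-segment MSC is identically 1 and is refused). The β endpoints are
inclusive so the 30-Hz bin center belongs to the band, and the band
summary is the arithmetic mean over in-band bins — resolution-independent,
unlike a trapezoidal area. Per-segment mean removal precedes tapering to
suppress DC leakage the 1-Hz high-pass does not fully remove.

## What the generator emulates, and what it does not

The generator targets *testability*: source and noises share one spectral
envelope (pink background flattened below 1 Hz, plus flat α 8–13 Hz and β
14–30 Hz bands), so the population MSC between the channels is exactly
a(t)⁴ at every frequency with power, and estimator correctness can be
checked against a closed form. The sinusoidal drift of a(t) gives
reproducible threshold-crossing structure rather than realistic coherence
dynamics. It does **not** emulate artifacts, nonstationary spectra,
volume-conduction asymmetries between hemispheres, or any biophysics of
MEP generation — the MEP model is a direct encoding of the hypothesis
(dispersion linear in coherence, direction only). Passing tests therefore
demonstrate that the *machinery* behaves as specified under known ground
truth, not that real recordings would show the same effect sizes.

## Numerical choices

- **Estimator bias.** With K = 3 Welch segments per 1-s window the MSC
  estimate is biased upward by order (1−C)²/K_eff (≈ 0.4 for independent
  channels). Per-window values are therefore treated as what the online
  system sees, not as unbiased coherence; ground-truth recovery tests use
  whole-record estimates (hundreds of segments), where the residual bias
  is well inside 3 Monte-Carlo SEs of the replicate mean.
- Filtering is causal (`sosfilt` on second-order sections) because the
  modelled system is online; a zero-phase variant exists but is off by
  default. A common linear filter on both channels cancels in the MSC
  ratio, so filtering does not disturb the a⁴ ground truth.
- MSC values are not clipped; construction asserts no overshoot beyond
  1 + 1e-12. The session loop clamps Coh(β) into [0, 1] before the
  trigger comparison.
- Ties in threshold selection return the smallest order statistic giving
  at least `target_count` crossings. `count_below_threshold` uses strict
  `<`, the complement of the `>=` trigger condition.
- MEP draws are truncated at 0 mV (amplitudes are magnitudes); at the
  default dispersions the truncation correction is negligible.
- Degenerate inputs error out rather than warn: zero-variance channels,
  sub-2-segment windows, out-of-range coherence, baselines that are not a
  whole number of seconds, session records exhausted before `n_stimuli`
  (the partial event log rides on the exception).
- Seed fan-out: one master seed spawns sub-seeds (via `SeedSequence`, kept
  below 2³¹) for the baseline record, session record, MEP draws, and
  control intervals, so conditions and ablations share noise realizations.

## Problem sizes

Stochastic checks use sizes chosen to keep Monte-Carlo error well below
the asserted margins: 8 replicate 120-s records per mixing level for
ground-truth recovery; 50 replicate participant pairs (each: 180-s
baseline, triggered + control + no-modification sessions, 10 stimuli) for
the direction-of-effect medians; 10,000 replicates at n = 10 for F-test
type-I calibration; 1,500 s cap per no-modification session, whose event
log may legitimately be partial (without decay there is no liveness
guarantee — partial logs with ≥ 2 events still contribute intervals).

## Design choices where the design was open

- **Threshold selection** is an order statistic (exact, deterministic)
  rather than a search over candidate thresholds; both reproduce the
  6-in-180 target, the order statistic uniquely and reproducibly.
- **The 30-s onset clock** reads wall time from the last stimulus (or
  session start), so the 10-s pause counts toward it.
- **Control intervals** are integer seconds uniform on [25, 35]; the
  granularity is unstated in the protocol being modelled, and integer
  ticks match the 1-s analysis cadence.
- **Threshold floor 0** guarantees liveness of the modified condition.
- **Ablation semantics**: disabling modification freezes the threshold at
  θ₀; everything else (pause, reset, recharge markers) is unchanged.

## Known limitations

- Per-window Coh(β) at the 1-s cadence is a high-variance, upward-biased
  statistic; thresholds calibrated on it are estimator-specific and would
  shift under different Welch settings.
- The synthetic MEP model has no refractoriness, history dependence, or
  amplitude–coherence *level* coupling — only dispersion coupling — so
  mean-amplitude comparisons between conditions are uninformative here.
- Sessions are tick-discretized; hardware latencies between threshold
  crossing and stimulus delivery are not modelled.
- EDF input assumes two channels at the configured sampling rate and
  performs no artifact rejection, re-referencing, or montage handling.
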