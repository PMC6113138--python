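# Methods

This note documents the models, conventions and numerical choices behind
`mouseeg`. The package implements the standard analysis chain for
pharmaco-EEG biomarker studies in mice — auditory ERPs with sensory gating,
basal and evoked gamma/theta oscillations, the 40 Hz auditory steady-state
response (ASSR), and mismatch negativity (MMN) — together with a
synthetic-EEG generator that provides ground truth for every readout and a
mixed-model statistical layer for within-subject treatment contrasts.

## Stimulation protocols

Protocols are deterministic event tables (0-based sample indices at the
session sampling rate, default 1000 Hz):

* **Paired clicks** — `n_pairs` pairs, clicks 0.5 s apart within a pair,
  10 s silence after each pair (both configurable). The reference session
  is 300 pairs. Labels alternate `click1`/`click2`.
* **Click trains (ASSR)** — 2 s trains of clicks at 40 Hz, 30 s inter-train
  interval, 100 trains in the reference session. One `train_onset` event
  per train; constituent clicks are child events.
* **Oddball (MMN)** — cycles of `deviant_period − 1` standards followed by
  one deviant (deviant fraction exactly `1/deviant_period`; 5% for the
  every-20th design), 50 ms tones with a 0.5 s inter-stimulus interval.
  With the flip-flop design the standard and deviant tone frequencies
  (9/12 kHz) swap at the session midpoint, so each frequency serves as
  standard in exactly one half.

The deviant position is deterministic (every Nth tone). Timelines carry no
randomness, so event tables are bit-reproducible from their parameters.

## Synthetic EEG generator

Recordings have two cortical channels plus a trigger channel, in µV.
The generative model is additive:

* **Background**: pink (PSD ∝ 1/f) or white noise, default sd 15 µV, plus
  stationary band-limited Gaussian noise floors in gamma (35–80 Hz, sd
  8 µV) and theta (4–12 Hz, sd 12 µV) that realize *basal* oscillatory
  power. Band noise is normalized to its target sd per realization, so
  variance knobs map onto measured power without sampling slack.
* **ERP deflections**: Gaussian bumps named P1 (+60 µV at 20 ms, sd 6 ms),
  N1 (−120 µV at 40 ms, sd 8 ms), P80 (+50 µV) and P120 (+35 µV) — the
  murine P20/N40/P80/P120 family. Absolute amplitudes are conventions (the
  only anchored constraint is the ≥100 µV P1N1 inclusion floor, which the
  defaults satisfy at 180 µV); only relative changes matter to the
  measures. Per-trial jitter: latency N(0, 1.5 ms), amplitude ×(1 +
  N(0, 0.08)).
* **Sensory gating**: the N1 of `click2` is scaled by `gating_factor`
  (default 0.5, i.e. intact gating with S2/S1 = 0.5).
* **Evoked oscillations**: Gaussian-windowed bursts time-locked to clicks —
  a 50 Hz burst (25 µV, center 20 ms, sd 10 ms) inside the gamma window and
  an 8 Hz burst (40 µV, center 100 ms, sd 35 ms) inside the theta window.
* **ASSR**: during each train a 40 Hz sinusoid (30 µV) with a per-trial
  phase offset ~ N(0, σ); σ defaults to 0.4 rad, giving a baseline ITC
  near e^(−σ²/2) ≈ 0.92.
* **MMN**: the deviant's N1 is scaled by `mmn_deviant_n1_scale` (default
  1.8), producing a negative deviant-minus-standard difference wave.
* **Animals and drugs**: each animal carries one persistent multiplicative
  gain, 1 + N(0, 0.15), across all its treatments (the random-intercept
  structure of the within-subject design). Drug effects are multiplicative
  changes to the generative parameters (`n1_scale`, `basal_gamma_scale`
  and `evoked_gamma_scale` in the power sense, `assr_amp_scale`,
  `theta_scale`, `mmn_scale`, plus an additive phase-jitter term). The
  bundled high-dose antagonist preset (N1 ×0.5, basal gamma ×2.5, evoked
  gamma ×0.4, theta ×0.5, ASSR amplitude ×0.5, jitter +0.8 rad, MMN ×0.5)
  mirrors the direction pattern expected of an NMDA-receptor antagonist.

Trigger pulses are 10 ms, +500 µV rectangles at every trial-level event;
recovery uses a +250 µV rising-edge threshold and is exact for
simulator-written files. A master seed spawns independent substreams for
noise, per-trial jitter and artifact injection, so a background-only render
plus a noise-free render add up sample-for-sample to the full render, and
cohort cells are reproducible yet independent.

What the generator does *not* emulate: biophysical cortical dynamics,
electrode geometry, movement or chewing artifacts beyond an optional
amplitude-outlier knob, non-stationary drug pharmacokinetics within a
session, and latency shifts under drug. Passing tests therefore demonstrate
that the *analysis chain* recovers known generative structure — not that
real mouse EEG satisfies these models.

## Analysis conventions

* **ERP**: 1200 ms epochs (200 ms pre / 1000 ms post), per-trial baseline
  subtraction of the pre-stimulus mean, trial averaging on the mean of the
  two cortical channels. N1 = minimum between 30–50 ms (ties to the
  earliest sample); P1 = maximum between 15–30 ms (the paper names P20 but
  states no window; 15–30 ms is the package's choice). Gating ratio is
  S2/S1 = |N1(click2)|/|N1(click1)| so that gating disruption increases the
  readout. Inclusion screen: P1N1 ≥ 100 µV.
* **Artifact rejection**: peak-to-peak > 800 µV on any channel within an
  epoch (no published criterion exists; 800 µV is conservative for a
  signal with a 100 µV inclusion floor). The mask is reported, never
  silently applied.
* **Morlet decomposition**: complex Morlet with c = 5 cycles
  (σ_t = c/2πf), gamma layers at 35…80 Hz in 1 Hz steps (46 layers), theta
  4…12 Hz. Kernels are normalized to unit gain at their own center
  frequency, so layer power is A²/4 for a sinusoid of amplitude A and a
  pure tone peaks exactly at its own layer; an equal-energy normalization
  would tilt gain ∝ f^(−1/2) and shift tone peaks one layer down.
  Coefficients whose ±5σ support crosses the epoch edge are marked invalid
  and excluded from window means (no zero-padding bias). The transform is
  FFT-based convolution, verified against a direct time-domain convolution
  oracle to ≤1e−6 relative error.
* **Basal vs. evoked power**: basal = mean layer power in a 400 ms bin
  ending 2.6 s before each first click (bin placed [−3.0, −2.6] s);
  evoked = mean band power in a window anchored at the measured P1 peak
  (gamma P1±25 ms; theta P1−20..+180 ms) minus basal, in the power domain
  (phase discarded). Evoked power can be negative. Oscillation epochs are
  cut −1200..+1400 ms so the 4 Hz wavelet support stays inside the epoch.
  Optional normalization divides by the mean band power over the whole
  recording, computed spectrally (Parseval identity), applied after the
  basal subtraction (switchable).
* **ASSR**: zero-phase 2nd-order Butterworth band-pass 35–45 Hz
  (forward–backward), 2.8 s epochs (400 ms pre, 2 s trial, 400 ms post).
  Power = 40 Hz layer power summed over the 2 s trial window, averaged
  across trials. ITC(t) = |mean over trials of coef(t)/|coef(t)||, in
  [0, 1]; zero-magnitude coefficients are excluded with a count. The scalar
  ITC is the time-mean over the trial window (median switchable).
* **MMN**: each deviant is paired with the last preceding standard in its
  block, so equal trial counts enter both averages; epochs are −50..300 ms
  (longer epochs would fold the next tone of the 0.55 s sequence into the
  averages). The difference wave's most negative point in 20–100 ms is the
  peak; the MMN magnitude is the trapezoidal AUC over peak ±25 ms (µV·ms,
  signed; |AUC| reported alongside). Robust-MMN screen:
  |N1(standard)|/|N1(deviant)| ≥ 0.5 (the ratio's formula is not published;
  the N1-amplitude reading is this package's documented choice).
* **Statistics**: per parameter, a linear mixed model with treatment fixed
  and a per-animal random intercept (REML, statsmodels). Contrasts are each
  dose minus vehicle-at-baseline plus washout minus baseline. Wald
  statistics are referred to a t distribution with the
  randomized-complete-block residual df ((a−1)(n−1) when balanced), which
  reproduces exact paired-ANOVA inference at small n; type-I error at the
  Bonferroni-adjusted level was verified by simulation (1000 null cohorts
  of 12 animals). If the mixed fit fails to converge the equivalent
  fixed-effects animal-block analysis is used, with a warning. Bonferroni
  families divide 0.05 by (number of doses × number of parameters) per
  protocol — ERP 6 parameters, ASSR 2, MMN 1; washout-vs-baseline is a
  return-to-baseline check tested at 0.05 without correction.

## EDF round-trip

Recordings are stored as plain EDF (not EDF+): 16-bit samples, 1 s data
records, physical unit µV with a symmetric per-channel physical range just
covering the data, so the quantization step is (2·max|x|)/65535 and
round-trip error is at most half a step. Event tables travel as a
tab-separated sidecar (`<stem>.events.tsv`), since a plain pulse channel
cannot carry stimulus identity; for isochronous oddball sessions labels are
only recoverable from the sidecar/protocol, while paired-click and train
sessions are self-describing through their inter-onset intervals
(±5 sample tolerance).

## Problem sizes

The demo cohort used by the end-to-end direction-pattern check is a
scaled-down recording day chosen so that a full cohort (12 animals ×
3 treatments × 3 protocols) renders and analyzes in well under a minute:
30 click pairs with a 4 s inter-pair gap, 20 trains with a 3 s inter-train
interval, and 16 oddball cycles of period 10. Reference-scale sessions are
used where a quantity depends on them: the 300-epoch segmentation check
runs the full 300-pair session, the ITC-vs-jitter closed-form comparison
uses 500 trials, and the mixed-model calibration runs 1000 null cohorts.

## Known limitations

* Generative and analysis windows share conventions (e.g. the N1 is a
  Gaussian centered at 40 ms and searched in 30–50 ms); the tests do not
  probe misspecified latencies beyond the per-trial jitter.
* The evoked = total − basal subtraction assumes stationary basal power
  across the session; slow drifts would bias it.
* P80/P120 are rendered but not quantified (no published windows).
* The fixed-effects fallback reports the same contrasts but ignores
  between-animal variance in the intercept; for balanced within-subject
  designs the contrast inference coincides.
* EDF storage clips nothing but quantizes: signals re-read from disk differ
  from the in-memory render by up to half a 16-bit step.
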