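# Methods

This note documents the models, conventions, and parameter choices behind
`szmarkers`, the reasoning where the design was genuinely open, and what the
synthetic tests do and do not establish about clinical data.

## Signal model and preprocessing

A seizure is three contiguous segments of a channels × samples microvolt
matrix sharing one sampling rate and channel set: preictal baseline (target
120 s), ictal period (annotated electrographic onset to offset, 0-based
half-open sample interval `[onset, offset)`), and postictal window (target
120 s). Shorter pre/postictal context is accepted and flagged, never padded.

Preprocessing order is fixed: downsample → noisy-channel removal →
common average reference → filtering.

* **Downsampling** to 256 Hz uses polyphase resampling with a Kaiser (β = 5)
  anti-aliasing filter; output length is `floor(N·256/fs)`. Upsampling is
  refused.
* **Noisy-channel detection** runs on the preictal baseline: per channel,
  the log of the 95th percentile of |amplitude|; channels whose robust
  z-score across channels exceeds 5 are removed one at a time (worst first,
  statistics re-estimated after each removal) until stable or 20 % of
  channels are gone. The robust z-score uses the normal-consistent MAD
  (×1.4826): the statistic is estimated across only a few dozen channels,
  and an unscaled small-sample MAD denominator fires on ordinary sampling
  variation (~1 % of perfectly clean channels in simulation). Channels with
  amplitude range below 10⁻⁶ of the median channel range are removed as
  flat. All channels flagged is an error (uninterpretable recording). In
  cohort mode the union of channels flagged on any of a patient's seizures
  is removed from all of that patient's seizures. A manual exclude list is
  available for channels identified by visual inspection.
* **Re-referencing** subtracts the instantaneous across-channel mean.
* **Filtering**: Butterworth order 4, applied forward–backward
  (`sosfiltfilt`, zero phase, length-preserving): band-stops at 50 ± 1 and
  100 ± 1 Hz, then a 0.5–100 Hz band-pass. The upper band edge is clipped to
  `0.99 · fs/2` so the nominal 100 Hz edge remains legal at a 128 Hz
  Nyquist; a stop band touching Nyquist degenerates into a low-pass.

## Base features

1-s non-overlapping epochs (trailing partial epoch discarded). Line length
is the raw sum of absolute first differences (windows have fixed length, so
normalization is a constant absorbed by the log transform). Energy is the
sum of squares. Band power is computed from a single-taper periodogram of
the 1-s window — a 1-s window at 1-Hz resolution leaves no room for Welch
sub-windowing or multitapering, and a Hann taper curbs leakage. The
`scaling='spectrum'` periodogram is divided by the taper's noise-power gain
(`N·Σw² / (Σw)²`, 1.5 for Hann, 1 for a rectangular window) so the summed
bins estimate the true in-band power under either taper; with the
rectangular taper the six bands plus out-of-band remainder partition the
signal's mean-square power exactly (Parseval), which the tests verify.
Band edges are half-open `[low, high)` except high-γ, closed at the 100-Hz
global band-pass edge.

## Peak markers

`ln(max_c P95_t)` per feature matrix, with `P95` the linear-interpolation
percentile (the default convention of mainstream numerical environments,
including R). Natural log fixes the scale. A pathological all-zero feature
matrix is floored at `ln(10⁻¹²)` with a warning flag, keeping the marker
finite and ordered below any physical value.

## Imprint and spatial markers

Baseline median and MAD per (channel, feature) from the preictal 1-s epochs
(warning below 30 epochs). The MAD divisor is **unscaled** (no 1.4826
factor) — the 5-MAD detection threshold is calibrated to that convention,
and both are config-exposed. A zero MAD (constant baseline) is replaced by
`max(10⁻¹², 10⁻⁶·|median|)` and flagged. Abnormality is two-sided
(`|value − median| / MAD`); a one-sided mode exists.

A cell is a candidate detection when any of the eight feature scores exceeds
5. The cleanup that suppresses spurious detections keeps a cell only inside
a run of ≥ `min_run` consecutive flagged epochs on its channel and clears
channels with fewer than `min_channel_total` flagged epochs overall. The
defaults (`min_run = 4`, `min_channel_total = 4`) are calibrated on the null
model rather than chosen ad hoc: band powers of a 1-s periodogram are
chi-square statistics with few degrees of freedom, so the 5-MAD threshold
has a percent-level null exceedance per cell on any Gaussian-derived
background, and short persistence rules retain a large fraction of null
channels (a 2-epoch rule kept ~35 % in simulation). Four seconds of
persistence brings the null channel-detection rate over a 2-min baseline to
~2 % while leaving sensitivity at 1.0 in simulation — electrographic seizure
activity is sustained rhythmic activity, whereas the transients the step
targets (noise, isolated spikes) last well under 4 s. Consequence: a channel
recruited for fewer than 4 s cannot enter the imprint.

Spatial markers from the imprint: proportion of channels ever flagged;
maximum simultaneous proportion; time to maximum recruitment (start of the
**earliest** epoch attaining the maximum — "time to" reads as first
attainment); and that time over the ictal duration. An empty imprint yields
zero proportions and **missing** (NaN) timing markers: zero would fake
instant recruitment.

## Suppression markers

Signal range (max − min) per channel in 0.5-s non-overlapping windows.
A postictal window is suppressed when its range falls below the 5th
percentile (linear interpolation) of that channel's preictal ranges
(warning below 20 preictal windows). The proportion-suppressed series starts
1 s after seizure offset (buffer) and runs to a 120-s horizon.

Durations: threshold the series (majority 0.5 — the literal reading of
"majority"; partial 0.1 — the exact partial criterion is not numerically
fixed anywhere authoritative, so it is config-exposed), take a centered
2.5-s moving sum of the binary state (zero-padded ends), call the state
active while ≥ 3 of 5 windows are above threshold, and measure from the
first active window within a 5-s grace period after the buffer to the first
inactive window thereafter. Never active within the grace period → 0
(suppression starting later than 5 s after offset is not counted toward the
duration; an open design point, flagged here). Durations cap at 120 s,
meaning "at least 120 s". Degenerate-input caveat: with
partial ≤ majority threshold the partial-state set is a superset of the
majority set, yet on adversarial profiles an isolated early partial episode
can end before majority suppression begins, making partial < majority under
the first-episode rule; on postictal-shaped (decaying) profiles both
durations anchor at the same episode and the expected ordering holds.
Strength is the median of the proportion-suppressed series over the full
horizon. Reported durations are `ln(duration + 1 s)` so zero stays finite;
the 1-s offset is part of the definition.

## Evaluation statistics

* **Rank-sum effect size**: Mann–Whitney U via average ranks, normal
  approximation with tie correction and a 0.5 continuity correction toward
  the mean (the default of the statistical environments this mirrors;
  config-exposed), `r = |Z|/√N` in [0, 1], categories at 0.1/0.3/0.5.
  Verified against exact enumeration of all 252 splits at n₁ = n₂ = 5.
* **ROC AUC**: 100 evenly spaced thresholds on the [0, 1] probability scale
  (scores min–max scaled first if outside), trapezoidal area with corner
  points added; within 0.01 of the rank-based closed form `U/(n₁n₂)`.
* **Circular–linear rank correlation**: circular ranks
  `θᵢ = 2π·rank(tᵢ)/n` of time of day, linear ranks of the marker, and
  `ρ = √R²` of the multiple correlation of the linear ranks on
  `(cos θ, sin θ)` — ρ ∈ [0, 1] by construction, invariant to 24-h shifts
  and to monotone transforms of the marker. The permutation test (default
  1000 permutations, vectorized, seeded) uses the add-one estimator
  `p = (1 + #{ρ_perm ≥ ρ}) / (1 + n_perm)`, so p is never exactly 0 and its
  floor is 1/1001. All-tied marker values make ρ undefined → missing.
  The estimator construction is one of several in the circular-statistics
  literature; it is the documented, oracle-tested choice here.
* **Longitudinal correlation**: Spearman ρ (average-rank ties, two-tailed
  t-approximation p) of marker against time since the patient's first
  recorded seizure; absolute value reported as strength.
* Cohort evaluation inclusion rules: type contrast requires ≥ 5 seizures
  with ≥ 2 of each type; circadian and longitudinal analyses require ≥ 20
  seizures. Excluded patients are listed, not silently dropped. No
  multiple-testing correction across markers: p-values are for reference
  and visualization, not patient stratification.
* Hierarchical mixed-effects logistic regression (random intercept/slope
  model comparison) is delegated to external statistical tooling by design;
  the long-format export carries everything such fits need.

## Synthetic data

The generator is phenomenological — no neural-mass dynamics; it emulates the
*statistical signatures* each marker family measures, with ground truth.

* **Background**: per-channel pink noise (PSD ∝ 1/f, spectral exponent 1),
  SD 50 µV — realistic iEEG amplitude scale, and a 1/f baseline makes the
  band-power MAD thresholds meaningfully heavy-tailed. Native rate 512 Hz so
  the 256-Hz downsampler is exercised on every path.
* **Ictal activity**: on a chosen fraction of channels from their
  recruitment times, a θ oscillation (6 Hz ± 10 % per channel, random phase,
  0.3-amplitude second harmonic, slow amplitude jitter, 0.5-s onset ramp) at
  `ictal_gain` (default 8) × background SD. θ was chosen so one specific
  band-power marker should dominate, giving marker-ordering tests a signed
  prediction. The added components are made **zero-sum across the montage**
  (their across-channel mean is subtracted from the currently recruited
  channels) — the montage analog of differential recordings of a shared
  source — so common-average re-referencing does not redistribute ictal
  energy into unrecruited channels. Without this, CAR leakage alone exceeds
  the 5-MAD threshold in non-recruited channels at realistic gains and
  channel counts, and channel-level specificity is unmeasurable.
* **Suppression**: postictal background of a chosen channel fraction scaled
  by `suppression_gain` (default 0.02) for `suppression_len` seconds, with a
  1-s recovery ramp.
* **Line noise**: optional 50-Hz contamination with per-channel phase.
* **Cohorts**: monotone event times with 6–18-h gaps (clock time falls out
  of the same process, covering the 24-h cycle over a multi-day stay); two
  seizure-type subpopulations — focal-like (ictal 40 ± 5 s, 60 % of channels
  recruited, suppression 30 ± 5 s on 70 % of channels) and subclinical-like
  (15 ± 3 s, 15 % recruited, 0.4× gain, no suppression). Ictal gain is
  modulated as `g₀·(1 + A·cos(2π(t − φ)/24 h))` (acrophase 03:00), drifts
  linearly with days since the first seizure, and carries 10 % log-normal
  jitter. `simulate_cohort_markers` is a marker-level fast path drawing
  marker tables directly from the same modulation model (peak markers scale
  as ln gain and 2·ln gain with 0.3-SD log-scale biological variability) —
  used where thousands of cohorts are needed (type-I error and power
  calibration of the rank-based circadian test, which is invariant to the
  monotone marker ← gain map), while full-signal cohorts exercise the
  pipeline end to end.
* Determinism: one seed fixes every realization bit-identically.

**What the synthetic tests do not show**: real iEEG has non-stationary
baselines, correlated channels, artifacts that are neither flat nor simply
high-amplitude, seizure dynamics far richer than a gated θ oscillation, and
montage-dependent reference effects. Passing recovery tests demonstrates the
algorithms implement their definitions and are calibrated on their null
model — not that the markers are clinically valid; that validation requires
clinical recordings and labels.

## Problem sizes

Test and acceptance simulations are sized for a single CPU: imprint-recovery
runs use 50 seizures (C = 20, gain 8) with the postictal window shortened to
10 s (suppression is not measured there); suppression runs use 8 channels
and a 10-s ictal phase (the imprint is not measured there); statistical
calibration uses 1000 null datasets and 200 power cohorts at the marker
level. The conditions each check pins (gain, channel counts, programmed
durations, thresholds) are never scaled.

## Known limitations

* EDF writing is not provided (reading via MNE is); the loop-closing on-disk
  dialect is a delimited text matrix with an annotation sidecar.
* The noise-detection and imprint-cleanup rules are explicit, config-driven
  re-specifications; their exact clinical-pipeline counterparts may differ.
* Suppression beginning more than 5 s after seizure offset yields duration
  0 rather than a mid-series measurement.
* No electrode-geometry awareness: markers are channel-set dependent, and
  channel counts/coverage differ across patients; within-patient
  comparisons are the intended use.
* FeatureMatrix export is CSV only; no HDF5 serialization.
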