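# Methods

## Signal model and pipeline

An IBI sequence X = {x_j}, j = 1..n (ms) is treated as an irregular time
series: beat j carries value x_j at its onset time t_j = Σ_{k≤j} x_k,
measured from session start. Windows are half-open, [k·w, (k+1)·w) with
w = 120 s by default, so each beat belongs to exactly one window and a
trailing partial window is dropped. Note one consequence of anchoring a beat
at the *end* of its interval: a constant-1000 ms 30-minute session puts 119
beats in the first window and 120 in each of the remaining fourteen.

Within a window the sequence is linearly interpolated onto a uniform grid at
R = 4 Hz spanning [t_1, t_n], giving ⌊(t_n − t_1)·R⌋ + 1 points (≈ 477 for a
2-minute window), mean-subtracted, and zero-padded to the next power of two
(512). Linear interpolation is the default because it is deterministic and
cannot overshoot on short segments; a cubic spline is available through
`PipelineConfig.interpolation`.

The spectrum is the unnormalised one-sided periodogram: P_j = |X̂_j|² at
f_j = R·j/N for j = 0..N/2, with X̂ the DFT of the padded series. No
normalisation constant is applied — every quantity consumed downstream is a
ratio of band sums, which is invariant to a common scale. The chosen
convention is recorded in each spectrum's metadata. Mean subtraction before
padding matters: padding zeros onto a series still carrying its ~1000 ms
level would inject a large step transient across all bands, whereas after
centring, the padding continues the series at its mean level and only the
(discarded) DC bin is affected.

Band powers are LF = Σ P_f for f ∈ [0.04, 0.15) Hz and HF = Σ P_f for
f ∈ [0.15, 0.40] Hz. The LF interval is half-open so a bin landing exactly
on the shared 0.15 Hz edge is counted once (in HF); with both bands closed,
total power in [0.04, 0.40] would not equal LF + HF. LHR = LF/HF; a zero HF
raises an explicit error rather than returning infinity.

### Windowing and leakage

The default taper is rectangular (none). With 512 points at 4 Hz a pure tone
well inside a band keeps ≥ 95% of its non-DC power in that band, but within
about 1.5 bins (~0.012 Hz) of a band edge, sidelobe leakage across the edge
exceeds 5%. A Hann taper (`fft_window: hann`) reduces edge leakage to < 4%
at the cost of a wider main lobe. The localization guarantees in the test
suite are therefore stated for interior tones (≥ 0.05 Hz from an edge).

### PPG beat detection

When starting from raw PPG rather than IBIs, baseline drift is removed with
a centred moving average (default 1 s) and beats are local maxima of the
detrended signal subject to a 300 ms refractory period (HR ≤ 200 bpm) and a
prominence of at least 25% of the detrended peak-to-peak range. Peak times
are quantized to the sample grid, so IBI accuracy is limited to ±1 sample
per edge. All three parameters live in `PeakDetectionConfig`.

## Curve indicators

For the per-segment LHR curve (length m ≥ 3 for peak analysis):

* **LHSD** — sample standard deviation (ddof = 1). The n−1 denominator is
  the natural choice for a small-m dispersion estimate; it is configurable
  only in the sense that callers can compute their own.
* **LHP** — count of strict local maxima; a plateau counts once, at its
  first index, when its level exceeds both flanks; endpoints are never
  peaks. No prominence filter is applied: 2-minute averaging has already
  smoothed the curve, and a threshold would introduce a free parameter the
  model definition does not have. LHP ≤ ⌊(m−1)/2⌋ always.
* **LHA** — mean over peaks of (peak value − mean of the nearest local
  minima on each side), with the curve endpoint standing in for a missing
  interior minimum. This is a prominence-style peak-to-valley excursion:
  oscillation size, not absolute level. LHA = 0 exactly when LHP = 0.

All three are invariant to adding a constant to the curve; LHSD and LHA
scale linearly under positive scaling while LHP is unchanged. These
invariances are enforced by property tests.

Group routing thresholds LHSD at 1.47: strictly below is low-score,
otherwise (including exactly 1.47) high-score.

## Score model, fitting, evaluation

G′ = α/LHSD + β·LHP + γ·LHA + ε. Fitting is ordinary least squares on the
design matrix (1/LHSD, LHP, LHA, 1) — the model is linear in its
transformed features, the intended sample sizes are tiny (tens), and no
regularisation is part of the model definition. A rank-deficient design
raises rather than silently pseudo-inverting. R² is reported with the fit.

Predictions are *not* clamped to [0, 100] by default; metrics are computed
on the raw linear output, with clamping available as a flag. Class accuracy
bins scores as ⌊score/width⌋ with width 10 or 20; a score of exactly 100
joins the top class so the partition has exactly 100/width cells. MAE ≤ RMSE
holds for every report (Jensen), and 5-class accuracy ≥ 10-class accuracy
because the coarser partition merges whole decades.

NRS levels for reporting: ≤ 30 very_low, ≤ 50 low, ≤ 70 moderate, ≤ 100
high, with non-integer scores bucketed by ≤ on the upper edges.

## Synthetic data

`generate_session` emulates a session as additive sinusoidal modulation of
interval length: beat k at cumulative time t_k has

x_k = base + A_LF(t_k)·sin(2π f_LF t_k) + A_HF(t_k)·sin(2π f_HF t_k) + η_k,

with per-segment amplitude schedules, η Gaussian (SD 5 ms by default), base
800 ms (75 bpm, a seated adult), a 30-minute duration and 2-minute segments.
Defaults place the tones at 0.10 and 0.30 Hz — mid-band on both sides — with
equal 30 ms amplitudes. Intervals below 200 ms (300 bpm) abort generation as
unphysiological. This "IPFM-lite" model is the simplest generator whose
in-band spectral content is known analytically; it does **not** reproduce
respiratory sinus arrhythmia coupling, baroreflex feedback, ectopic beats,
or PPG motion artefacts, so passing tests demonstrate correctness of the
*analysis chain*, not robustness to real-world signal pathology.

`generate_lhr_curve` composes a monotone ramp with single-point spikes:
spike count fixes LHP exactly; spike height and ramp rise are solved by a
closed loop (amplitude correction alternating with bisection on the measured
SD) until LHSD and LHA are within 5% of target. Targets below the dispersion
floor implied by the requested peaks, or requiring a ramp steep enough to
destroy peaks, raise as infeasible.

`generate_dataset` draws LHSD ~ U[0.5, 3], LHP ~ U{0..7}, LHA ~ U[0, 4]
(the spread seen on short LHR curves) and scores them through the linear
model plus optional Gaussian noise; scores are clipped to [0, 100] only at
the sample boundary, and for both bundled presets the noiseless scores over
these ranges lie strictly inside the interval, so ordinary-least-squares
recovery tests are exact and unbiased. Every generator is a pure function of
its spec and seed.

## Numerical choices and degenerate inputs

* FFT vs direct DFT: the periodogram equals a brute-force O(N²) DFT to
  1e-9 relative tolerance (tested for all power-of-two N ≤ 64), and
  two-sided power satisfies Parseval against N·Σx² to 1e-6.
* Segments with fewer than 30 beats (a ≈15 bpm floor for a 2-minute window)
  are excluded with a warning; a session whose every segment fails is a
  data-quality error, distinct from malformed input.
* Fewer than 2 beats cannot be interpolated; fewer than 3 curve points have
  no interior to host a peak; empty evaluation inputs are rejected.
* Routing changes prediction only when LHSD crosses 1.47 (grid-scanned in
  tests at 0.01 resolution).

## Problem sizes

Test and acceptance workloads use 30-minute sessions (~2,300 beats),
512-point FFTs, 15-point curves, 50-sample noiseless fits and up to
5,000-sample noisy fits — sizes chosen to match the protocol the package
models while keeping every check exact or tightly seeded.

## Known limitations

* The bundled coefficient presets come from a small private dataset of
  36 sessions; they are shipped for reproducibility of the method, not as
  population-calibrated constants, and should be refitted for any new
  cohort, device, or game genre.
* The LHSD = 1.47 routing threshold is similarly cohort-specific and
  configurable.
* Spectral estimates assume the 2-minute window is stationary; strong
  intra-window trends bias LF upward.
* The half-open band convention and unnormalised periodogram are internal
  conventions: absolute LF/HF values in ms² are not comparable across tools
  that normalise differently, though LHR is.
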