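# Methods

This note documents the models, estimators and numerical choices behind
fatiguekit, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the problem was genuinely open.

## Fatigue states and calibrations

Three states on the Borg RPE scale are modeled: A (RPE 8, very relaxed),
B (RPE 13, slightly tired), C (RPE 18, very tired). For each state the
generators target published normalized indicator levels, shipped in
`fatiguekit/data/default_calibrations.yaml`:

* EMG, per muscle (vastus lateralis, rectus femoris, vastus medialis):
  ARV, IEMG, RMS in normalized amplitude units, MPF and MF in Hz. With
  fatigue the amplitude indicators rise and the spectral indicators fall.
* ECG, per state: heart rate (beats/min), HF band power (ms²), and the
  LF/HF ratio.

**Why LF is derived, not set.** The published indicator table is internally
inconsistent: the quoted LF/HF means (1.28 / 0.98 / 0.92) do not equal the
quotient of the quoted LF and HF means (1.573 / 1.376 / 1.258), and no
bivariate (LF, HF) distribution with the quoted means and SDs can produce
the quoted mean ratio (matching would require a correlation above 1).
Since the ratio is the quantity used to index autonomic balance, the
calibration stores HF and LF/HF and derives LF = (LF/HF)·HF
(A: 93.25, B: 65.24, C: 57.49 ms²). The ordering across states (both LF
and LF/HF fall with fatigue) is preserved.

## Synthetic EMG

Model: zero-mean Gaussian noise whose one-sided spectrum is a Gaussian bump
of width σ = 15 Hz, truncated below 20 Hz (the hardware high-pass band
edge). The bump center is found by fixed-point iteration so that the
**discrete-grid spectral centroid equals the target MPF exactly**; the
realization is then amplitude-scaled so the **realized RMS equals the
target exactly**. This matches the constraints the fatigue physiology
imposes (amplitude up, spectrum down with fatigue) with the simplest
controllable mechanism.

Consequences to be aware of:

* ARV/IEMG follow from Gaussianity (ARV = √(2/π)·RMS ≈ 0.80·RMS) and MF ≈
  MPF for the symmetric bump, so the published ARV/IEMG/MF columns are
  *not* independently reproducible from synthesized signals; they are used
  by the Gaussian feature-dataset path instead. Only RMS and MPF are
  treated as signal-level calibration targets.
* Per-seed recovery: RMS is exact by construction; the MPF estimate
  (Welch, 1 s Hann segments, 50% overlap) scatters ~0.4 Hz per 10 s
  recording around the target with negligible bias.

Defaults: 10 s recordings at 1000 Hz (≥ 500 Hz enforced; the band must
clear Nyquist).

## Synthetic ECG

Beat morphology is a fixed sum-of-five-Gaussians PQRST template (R
amplitude 1 mV, sharp 11 ms R wave, physiologic P/Q/S/T offsets). Beats
are placed by integrating a continuous RR tachogram

    RR(t) [ms] = mean RR + x_LF(t) + x_HF(t),

where each x is Gaussian noise with exactly band-limited support
(0.04–0.15 Hz and 0.15–0.40 Hz on the 4 Hz generation grid) and its
realized variance scaled **exactly** to the calibrated band power in ms².
Because beats sample the tachogram more densely where RR is short, the
beat-averaged RR would sit slightly below the time-averaged mean; the
realized intervals are rescaled (~0.02%) so the beat train carries the
calibrated mean RR exactly. True R-peak times are stored in the signal
metadata as construction ground truth for detector tests.

Not emulated: beat-morphology variability, ectopy/artifact beats,
respiratory sinus arrhythmia coupling to an explicit respiration signal,
amplitude modulation with posture. Passing tests therefore demonstrate
correctness of the processing chain on idealized rhythms, not detector
robustness to pathological ECG.

Contaminants (both generators): additive baseline drift (default 0.3 Hz
sinusoid; anything below 3 Hz allowed), 50 Hz mains tone, and band-limited
3–14 Hz motion-artifact noise, each with a configurable amplitude.

## Preprocessing

* **EMG high-pass**: 4th-order Butterworth at 20 Hz, applied
  forward-backward (zero phase; attenuation effectively doubled). The
  single 20 Hz edge removes both sub-Hz drift and 3–14 Hz motion
  artifacts, since useful sEMG energy lies at 20–150 Hz.
* **Mains notch**: second-order IIR notch, Q = 20, zero-phase. A high-Q
  notch rings for ~Q/(πf₀) s, so filtfilt uses 3 s edge padding; residual
  50 Hz leakage is then < 3.2% in RMS while 35/65 Hz pass within 1 dB.
* **Median filter**: exact order-statistics filter, window L = 2K+1,
  reflect padding at the edges, ties handled naturally by the sorted
  multiset (odd L ⇒ unique median). The incremental implementation keeps
  the window sorted across steps — delete the outgoing sample and
  binary-search-insert the incoming one — so each step costs O(log L)
  comparisons (plus an O(L) memmove) instead of an O(L log L) re-sort.
  An instrumented counter verifies ≈ 2·log₂L comparisons per sample, and
  the output is asserted bit-identical to a naive per-window full sort.
* **ECG baseline removal**: subtract the median-filtered baseline
  estimate; the default 0.6 s window is far wider than a QRS complex, so
  the running median tracks drift but steps over beats. Measured on
  synthetic recordings: sub-1 Hz drift power suppressed to < 1%, R-peak
  amplitudes preserved within 5%.

## Feature extraction

EMG per analysis window: ARV = mean |x| (the printed defining integrals of
ARV/IEMG omit the rectification, under which both would vanish for
zero-mean EMG; the rectified forms are the standard definitions and the
only reading consistent with positive published values), IEMG = ARV·T
exactly, RMS, and from the Welch PSD the centroid MPF and the half-power
split MF (smallest grid frequency whose cumulative power reaches half the
total, ties resolved by ≥). MF is implemented as the conventional median
frequency; the printed formula reads as a power, which cannot be the Hz
quantity that decreases with fatigue.

ECG: R peaks by a Pan–Tompkins-style chain (5–18 Hz zero-phase band-pass,
derivative, squaring, 150 ms moving integration, running signal/noise
levels with threshold N + 0.25(S − N), 200 ms refractory period), with
each detection refined to the waveform apex. RR intervals outside
250–2000 ms are discarded (count logged). HR = 60000 / mean RR.

HRV band powers: the RR series is resampled at 4 Hz by cubic spline,
linearly detrended, and Welch-estimated with Hann windows of 64 s at 75%
overlap and a 4× zero-padded FFT; LF and HF are rectangle-rule band
integrals (the 0.15 Hz edge belongs to HF). These settings were calibrated
against the generator's known band-limited ground truth: on 120 s records
the LF band spans only ~7 raw spectral bins, and naive settings (50%
overlap, unpadded) under-measure LF by ~10%. With the chosen settings the
LF/HF ratio estimator is approximately unbiased; its per-seed scatter
(~25%) is physical — a 2 min record holds fewer than five 25 s LF cycles —
which is why recovery checks average over ≥30 seeds and why a 120 s
minimum duration is enforced (shorter requests raise an error naming the
minimum).

## LSTM classifier

Exact gated recurrence (forget/input/output sigmoids, tanh candidate,
multiplicative cell update), two stacked layers of 10 and 20 units,
classification from the final step's top-layer hidden state through an
affine softmax (max-subtracted for stability). Loss is mean cross-entropy
with probabilities clipped at 1e−12 (with a warning). Gradients are exact
backpropagation through time, validated against central finite differences
with a normalized error < 1e−5 (the comparison uses an absolute floor of
1e−4 in the denominator so finite-difference noise on ~1e−7-magnitude
gradients is not amplified).

Training: plain full-batch gradient descent — no momentum or adaptive
optimizer, to keep the update rule elementary — with global gradient-norm
clipping at 5.0 and a default learning rate of 1.0 on min-max-normalized
features. A rate of 1.0 drives the training loss below 0.1 within ~100
epochs on the default dataset; rates below ~0.3 do not converge within the
200-epoch budget for this architecture and batch size. Weight
initialization is uniform(−0.1, 0.1) from the stated seed; training itself
draws no randomness, so (data, seed) reproduces losses and weights
bit-for-bit. Inputs are min-max scaled to [0, 1] per feature with
statistics fit on training data only.

## Experiment pipeline

The default composition is 30/28/28 training samples (states A/B/C) and 25
test samples split 9/8/8. Feature domains select columns: time = {RMS,
HR}, frequency = {MPF, LF, HF}, combined = all five. Each dataset sample
is a seq_len × 5 matrix (default seq_len 10, one vector per 1 s window);
the fast path draws a sequence-level mean from the state's indicator
distribution (the published means and SDs) and jitters each time step
around it with half the state SD, while a config switch synthesizes full
signals and extracts features instead. Domain comparisons reuse the same
generated splits (verified by a hash over sample IDs and the full feature
matrices). An optional scikit-learn RBF-SVM baseline can be scored on the
same splits; it is explicitly non-core.

Because the calibrated class distributions are well separated relative to
their SDs, the synthetic classification task is easier than the field
task: held-out accuracy is typically 96–100%, comfortably above the
published LSTM accuracies, and the combined-domain run dominates the
single-domain runs. This validates the pipeline mechanics, not clinical
performance.

## Problem sizes

Recovery checks use 10 s EMG at 1000 Hz and 120 s ECG at 500 Hz; the
reproduction script averages EMG indicators over 30 seeds and ECG
indicators over 60 seeds (the LF/HF estimator carries most of the
across-seed variance), and reports classifier accuracy as the median over
5 replicate seeds of full 200-epoch trainings.

## Known limitations

* The EMG model is stationary within a recording; no motor-unit
  recruitment dynamics, no within-recording fatigue drift.
* MF ≈ MPF by construction (symmetric spectrum), unlike real sEMG whose
  skewed spectrum puts MF well below MPF.
* The HRV chain assumes sinus rhythm; no ectopic-beat correction beyond
  the 250–2000 ms interval gate.
* An adaptive (LMS-style) motion-artifact filter for ECG is sometimes
  mentioned in this application area but has no specified algorithm here;
  it is intentionally not implemented.
* The published experiment also lists a larger 124/37 split alongside the
  86/25 composition; both are expressible through the config, the default
  is the 86/25 composition.
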