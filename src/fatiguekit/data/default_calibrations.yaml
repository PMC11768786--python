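# Default per-state calibration targets for the synthetic generators.
# Values are "mean, sd" pairs of published normalized indicator levels for
# three fatigue states: A (RPE 8, very relaxed), B (RPE 13, slightly tired),
# C (RPE 18, very tired).
#
# EMG: normalized amplitude units (arv, iemg, rms) and Hz (mpf, mf).
# ECG: hr in beats/min, hf band power in ms^2, lf_hf dimensionless.
# The LF band power is derived as lf = lf_hf * hf so generated recordings are
# self-consistent in the LF/HF ratio (the published LF column — 114.62/91.58/
# 78.62 ms^2 — is not mutually consistent with the published HF and LF/HF
# columns; see docs/methods.md).

emg:
  vastus_lateralis:
    A: {arv: [7.63, 0.26], iemg: [23.62, 1.35], rms: [22.62, 4.25], mpf: [125.68, 5.36], mf: [64.26, 2.47]}
    B: {arv: [12.29, 1.14], iemg: [36.58, 2.46], rms: [52.14, 6.11], mpf: [87.06, 4.24], mf: [48.62, 4.38]}
    C: {arv: [15.26, 1.14], iemg: [43.26, 4.33], rms: [71.45, 4.63], mpf: [62.78, 3.34], mf: [36.85, 1.47]}
  rectus_femoris:
    A: {arv: [3.86, 0.29], iemg: [12.65, 0.78], rms: [13.57, 2.24], mpf: [61.58, 2.45], mf: [33.45, 1.65]}
    B: {arv: [5.32, 0.28], iemg: [16.47, 0.88], rms: [27.65, 2.32], mpf: [58.47, 2.14], mf: [28.96, 1.36]}
    C: {arv: [7.28, 0.55], iemg: [21.65, 1.17], rms: [34.85, 3.21], mpf: [55.41, 2.57], mf: [27.68, 1.20]}
  vastus_medialis:
    A: {arv: [5.24, 0.57], iemg: [17.45, 1.28], rms: [15.47, 2.11], mpf: [61.47, 4.47], mf: [33.25, 1.68]}
    B: {arv: [7.54, 0.31], iemg: [25.35, 1.25], rms: [36.51, 3.21], mpf: [57.65, 4.11], mf: [27.63, 1.45]}
    C: {arv: [11.41, 0.57], iemg: [33.21, 3.31], rms: [55.47, 3.29], mpf: [53.57, 3.54], mf: [25.87, 1.57]}

ecg:
  A: {hr: [65.23, 6.12], hf: [72.85, 35.64], lf_hf: [1.28, 0.68]}
  B: {hr: [95.87, 8.25], hf: [66.57, 32.14], lf_hf: [0.98, 0.57]}
  C: {hr: [126.57, 6.87], hf: [62.49, 25.76], lf_hf: [0.92, 0.54]}
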