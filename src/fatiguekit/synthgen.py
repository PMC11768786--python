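"""Synthetic surface-EMG and ECG generation calibrated to fatigue states.

The subject recordings behind the published indicator tables are not
available, so this module synthesizes signals whose *measured* indicators
reproduce the calibrated per-state targets:

* EMG: zero-mean Gaussian noise, spectrally shaped by a Gaussian band bump
  whose discrete-spectrum centroid is placed exactly at the target mean power
  frequency (MPF), then amplitude-scaled so the realized RMS equals the
  target.  With fatigue the bump slides down in frequency and the gain rises,
  emulating the slowing/growing sEMG of a tiring muscle.
* ECG: a fixed sum-of-Gaussians PQRST beat template placed at R-R intervals
  drawn from a tachogram = mean RR + two band-limited Gaussian processes
  (0.04-0.15 Hz and 0.15-0.4 Hz), each variance-scaled exactly to the
  calibrated LF/HF band power in ms^2.

Both generators optionally inject the interference the preprocessing stage
must remove: sub-Hz baseline drift, 50 Hz mains, and 3-14 Hz motion-artifact
noise.  Feature *datasets* for classifier training are drawn directly from
the per-state indicator distributions (fast path) or produced by full signal
synthesis + feature extraction (config switch).

Everything is deterministic given (calibration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    NO_CONTAMINANTS,
    ContaminantSpec,
    ECGStateCalibration,
    EMGStateCalibration,
    FatigueState,
    default_ecg_calibration,
    default_emg_calibration,
)
from .signal import SampledSignal

#: Feature order of every sequence sample: time-domain (RMS, HR) and
#: frequency-domain (MPF, LF, HF) indicators.
FEATURE_NAMES = ("rms", "mpf", "hr", "lf", "hf")

EMG_DEFAULT_FS = 1000.0
ECG_DEFAULT_FS = 500.0
TACHOGRAM_FS = 4.0

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

# sEMG spectral bump width; keeps each fatigue state's energy inside the
# 20-150 Hz surface-EMG band while leaving the states clearly separated.
EMG_BAND_SIGMA_HZ = 15.0
EMG_LOW_CUT_HZ = 20.0


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if x.size else 0.0


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float, hi: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a flat spectrum restricted to [lo, hi] Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    mask = (freqs >= lo) & (freqs < hi)  # half-open: adjacent bands stay disjoint
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    if sd == 0:
        raise ValueError(f"band [{lo}, {hi}] Hz contains no spectral support at n={n}, fs={fs}")
    return x / sd


def _emg_band_shape(freqs: np.ndarray, target_mpf: float, sigma: float,
                    f_lo: float) -> np.ndarray:
    """Gaussian spectral bump whose centroid on this grid equals target_mpf.

    The bump is truncated below ``f_lo`` (the hardware high-pass band edge),
    which skews its centroid, so the center is solved by fixed-point
    iteration rather than placed at the target directly.
    """
    fc = target_mpf
    shape = None
    for _ in range(100):
        shape = np.exp(-0.5 * ((freqs - fc) / sigma) ** 2)
        shape[freqs < f_lo] = 0.0
        centroid = float(np.sum(freqs * shape) / np.sum(shape))
        err = target_mpf - centroid
        if abs(err) < 1e-9:
            break
        fc += err
    return shape


def _add_contaminants(x: np.ndarray, fs: float, spec: ContaminantSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Additively inject drift / mains / motion interference."""
    t = np.arange(x.size) / fs
    out = x.copy()
    if spec.drift_amplitude > 0:
        out += spec.drift_amplitude * np.sin(2 * np.pi * spec.drift_freq * t + rng.uniform(0, 2 * np.pi))
    if spec.mains_amplitude > 0:
        out += spec.mains_amplitude * np.sin(2 * np.pi * spec.mains_freq * t + rng.uniform(0, 2 * np.pi))
    if spec.motion_amplitude > 0:
        lo, hi = spec.motion_band
        out += spec.motion_amplitude * _bandlimited_noise(rng, x.size, fs, lo, hi)
    return out


def generate_emg(cal: EMGStateCalibration, duration: float = 10.0,
                 fs: float = EMG_DEFAULT_FS,
                 contaminants: ContaminantSpec = NO_CONTAMINANTS,
                 seed: int = 0) -> SampledSignal:
    """Synthesize one surface-EMG recording for a calibrated fatigue state.

    The clean component is band-shaped Gaussian noise with spectrum centroid
    at ``cal.target_mpf`` and realized RMS exactly ``cal.target_rms``.

    Raises
    ------
    ValueError
        If ``fs`` is too low for the calibrated spectral band (Nyquist).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 500:
        raise ValueError("EMG sampling rate must be >= 500 Hz")
    if fs / 2 <= cal.target_mpf + 2 * EMG_BAND_SIGMA_HZ:
        raise ValueError(
            f"fs={fs} Hz violates Nyquist for an EMG band centered at "
            f"{cal.target_mpf} Hz (need fs/2 > {cal.target_mpf + 2 * EMG_BAND_SIGMA_HZ} Hz)")
    rng = np.random.default_rng(seed)
    n = round(duration * fs)
    meta = {"state": cal.state.label, "muscle": cal.muscle, "seed": seed}
    if cal.target_rms == 0:
        return SampledSignal(np.zeros(n), fs, "emg", meta)

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = _emg_band_shape(freqs, cal.target_mpf, EMG_BAND_SIGMA_HZ, EMG_LOW_CUT_HZ)
    spec = np.fft.rfft(rng.standard_normal(n)) * np.sqrt(shape)
    x = np.fft.irfft(spec, n)
    x *= cal.target_rms / _rms(x)
    x = _add_contaminants(x, fs, contaminants, rng)
    return SampledSignal(x, fs, "emg", meta)


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

# PQRST beat morphology: (offset from R in s, Gaussian width in s, amplitude in mV)
_PQRST = (
    (-0.200, 0.040, 0.12),   # P
    (-0.028, 0.010, -0.12),  # Q
    (0.000, 0.011, 1.00),    # R
    (0.028, 0.010, -0.20),   # S
    (0.250, 0.060, 0.30),    # T
)
_TEMPLATE_HALF_WIDTH_S = 0.45


def ecg_from_peak_times(peak_times: np.ndarray, fs: float, duration: float,
                        amplitude: float = 1.0) -> SampledSignal:
    """Render an ECG waveform with a PQRST beat centered at each R-peak time."""
    n = round(duration * fs)
    x = np.zeros(n)
    for p in np.asarray(peak_times, float):
        i0 = max(0, int(np.floor((p - _TEMPLATE_HALF_WIDTH_S) * fs)))
        i1 = min(n, int(np.ceil((p + _TEMPLATE_HALF_WIDTH_S) * fs)) + 1)
        if i1 <= i0:
            continue
        t_rel = np.arange(i0, i1) / fs - p
        beat = np.zeros(t_rel.size)
        for off, width, amp in _PQRST:
            beat += amp * np.exp(-0.5 * ((t_rel - off) / width) ** 2)
        x[i0:i1] += amplitude * beat
    return SampledSignal(x, fs, "ecg", {"r_peak_times": np.asarray(peak_times, float)})


def rr_tachogram(cal: ECGStateCalibration, duration: float, seed: int,
                 fs_tach: float = TACHOGRAM_FS):
    """Continuous-time RR tachogram (ms) on a uniform grid.

    RR(t) = mean RR + an LF-band and an HF-band Gaussian process, each
    variance-scaled exactly to the calibrated band power.
    """
    rng = np.random.default_rng(seed)
    n = round(duration * fs_tach) + 1
    t = np.arange(n) / fs_tach
    mean_rr = 60000.0 / cal.mean_hr
    rr = np.full(n, mean_rr)
    for power, (lo, hi) in ((cal.lf_power, LF_BAND), (cal.hf_power, HF_BAND)):
        if power > 0:
            rr += np.sqrt(power) * _bandlimited_noise(rng, n, fs_tach, lo, hi)
    np.clip(rr, 250.0, 2000.0, out=rr)
    return t, rr


def generate_ecg(cal: ECGStateCalibration, duration: float = 120.0,
                 fs: float = ECG_DEFAULT_FS,
                 contaminants: ContaminantSpec = NO_CONTAMINANTS,
                 seed: int = 0) -> SampledSignal:
    """Synthesize one ECG recording for a calibrated fatigue state.

    The true R-peak times are recorded in ``meta["r_peak_times"]`` so tests
    can score detectors against construction ground truth.

    Raises
    ------
    ValueError
        If the duration cannot support the requested targets (< 10 s for
        heart rate; < one LF cycle when HRV band powers are calibrated).
    """
    if duration < 10.0:
        raise ValueError("ECG duration must be >= 10 s for a stable heart-rate target")
    if (cal.lf_power > 0 or cal.hf_power > 0) and duration < 1.0 / LF_BAND[0]:
        raise ValueError(
            f"HRV band-power calibration needs duration >= {1.0 / LF_BAND[0]:.0f} s (one LF cycle)")
    rng = np.random.default_rng(seed)
    t_tach, rr = rr_tachogram(cal, duration, seed=rng.integers(2**31))
    peaks = []
    t = 0.4
    while t <= duration - 0.4:
        peaks.append(t)
        t += np.interp(t, t_tach, rr) / 1000.0
    peaks = np.array(peaks)
    if peaks.size >= 2:
        # beats sample the tachogram more densely where RR is short, which
        # would bias the beat-averaged RR below the prescribed mean; rescale
        # the realized intervals (a ~0.02% stretch) so the beat train carries
        # the calibrated mean RR exactly.
        intervals = np.diff(peaks)
        intervals *= (60.0 / cal.mean_hr) / intervals.mean()
        peaks = peaks[0] + np.concatenate([[0.0], np.cumsum(intervals)])
    sig = ecg_from_peak_times(peaks, fs, duration)
    sig.samples = _add_contaminants(sig.samples, fs, contaminants, rng)
    sig.meta.update({"state": cal.state.label, "seed": seed,
                     "mean_rr_ms": 60000.0 / cal.mean_hr})
    return sig


# ---------------------------------------------------------------------------
# Feature datasets for the classifier
# ---------------------------------------------------------------------------


@dataclass
class SequenceSample:
    """One classifier input: a T x 5 feature-matrix sequence plus its label."""

    features: np.ndarray  # (seq_len, 5) columns per FEATURE_NAMES
    label: FatigueState
    sample_id: str = ""

    def __post_init__(self):
        self.features = np.asarray(self.features, float)
        if self.features.ndim != 2 or self.features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"features must be (T, {len(FEATURE_NAMES)})")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")


def _state_feature_moments(state, muscle):
    """Per-state (mean, sd) vectors in FEATURE_NAMES order."""
    emg = default_emg_calibration(state, muscle)
    ecg = default_ecg_calibration(state)
    lf_mean = ecg.lf_power
    # LF sd propagated from the ratio sd at fixed HF (dominant term).
    lf_sd = ecg.sd_lf_hf * ecg.hf_power
    means = np.array([emg.target_rms, emg.target_mpf, ecg.mean_hr, lf_mean, ecg.hf_power])
    sds = np.array([emg.sd_rms, emg.sd_mpf, ecg.sd_hr, lf_sd, ecg.sd_hf])
    return means, sds


def generate_feature_dataset(counts, seq_len: int = 10, seed: int = 0,
                             muscle: str = "vastus_lateralis",
                             mode: str = "gaussian",
                             within_sd_frac: float = 0.5,
                             id_prefix: str = "s"):
    """Draw a labeled collection of :class:`SequenceSample`.

    Parameters
    ----------
    counts
        Per-class sample counts, either a mapping ``{FatigueState: int}`` or
        a length-3 sequence ordered A, B, C.
    seq_len
        Time steps per sample (one feature vector per 1 s analysis window).
    mode
        ``"gaussian"`` (default): each sample draws a sequence-level mean
        from the state's indicator distribution, then per-step values jitter
        around it with ``within_sd_frac`` of the state SD.  ``"signal"``:
        full signal synthesis + feature extraction (slow; see docs).

    Returns
    -------
    list of SequenceSample
    """
    if isinstance(counts, dict):
        counts = {s: counts[s] for s in FatigueState}
    else:
        counts = dict(zip(FatigueState, counts))
    for state, c in counts.items():
        if c < 1:
            raise ValueError(f"count for state {state.label} must be >= 1, got {c}")
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    if mode not in ("gaussian", "signal"):
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    samples = []
    for state in FatigueState:
        means, sds = _state_feature_moments(state, muscle)
        for i in range(counts[state]):
            sid = f"{id_prefix}_{state.label}{i:03d}"
            if mode == "gaussian":
                seq_mean = np.clip(rng.normal(means, sds), 0.0, None)
                feats = rng.normal(seq_mean, within_sd_frac * sds, size=(seq_len, 5))
                feats = np.clip(feats, 0.0, None)
            else:
                feats = _features_from_signals(state, muscle, seq_len,
                                               int(rng.integers(2**31)))
            samples.append(SequenceSample(feats, state, sid))
    return samples


def _features_from_signals(state, muscle, seq_len, seed):
    """Signal-path dataset sample: synthesize, extract, assemble T x 5."""
    from .ecg_features import detect_r_peaks, heart_rate, hrv_band_powers
    from .emg_features import estimate_psd, mpf, rms
    from .preprocess import remove_ecg_baseline

    rng = np.random.default_rng(seed)
    emg_cal = default_emg_calibration(state, muscle)
    ecg_cal = default_ecg_calibration(state)
    # per-sample (subject-level) targets drawn from the state's distribution
    emg_cal = EMGStateCalibration(
        muscle=muscle, state=state,
        target_arv=emg_cal.target_arv, sd_arv=emg_cal.sd_arv,
        target_iemg=emg_cal.target_iemg, sd_iemg=emg_cal.sd_iemg,
        target_rms=max(rng.normal(emg_cal.target_rms, emg_cal.sd_rms), 1.0),
        sd_rms=emg_cal.sd_rms,
        target_mpf=float(np.clip(rng.normal(emg_cal.target_mpf, emg_cal.sd_mpf), 25.0, 145.0)),
        sd_mpf=emg_cal.sd_mpf,
        target_mf=emg_cal.target_mf, sd_mf=emg_cal.sd_mf)
    ecg_cal = ECGStateCalibration(
        state=state,
        mean_hr=max(rng.normal(ecg_cal.mean_hr, ecg_cal.sd_hr), 40.0),
        sd_hr=ecg_cal.sd_hr,
        hf_power=max(rng.normal(ecg_cal.hf_power, ecg_cal.sd_hf), 5.0),
        sd_hf=ecg_cal.sd_hf,
        lf_hf=max(rng.normal(ecg_cal.lf_hf, ecg_cal.sd_lf_hf), 0.1),
        sd_lf_hf=ecg_cal.sd_lf_hf)

    emg = generate_emg(emg_cal, duration=float(seq_len), seed=int(rng.integers(2**31)))
    ecg = generate_ecg(ecg_cal, duration=120.0, seed=int(rng.integers(2**31)))
    clean = remove_ecg_baseline(ecg)
    rr = detect_r_peaks(clean)
    hr = heart_rate(rr)
    bands = hrv_band_powers(rr)
    n_win = round(emg.fs)
    feats = np.empty((seq_len, 5))
    for t in range(seq_len):
        win = emg.samples[t * n_win:(t + 1) * n_win]
        feats[t, 0] = rms(win)
        feats[t, 1] = mpf(estimate_psd(win, emg.fs))
        feats[t, 2] = hr
        feats[t, 3] = bands.lf
        feats[t, 4] = bands.hf
    return feats


def dataset_to_frame(samples):
    """Long-format table: sample_id, t, rms, mpf, hr, lf, hf, label."""
    import pandas as pd

    rows = []
    for s in samples:
        for t in range(s.features.shape[0]):
            rows.append({"sample_id": s.sample_id, "t": t,
                         **dict(zip(FEATURE_NAMES, s.features[t])),
                         "label": s.label.label})
    return pd.DataFrame(rows)


def dataset_from_frame(df):
    """Inverse of :func:`dataset_to_frame`."""
    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("t")
        feats = grp[list(FEATURE_NAMES)].to_numpy(float)
        label = FatigueState.from_label(grp["label"].iloc[0])
        samples.append(SequenceSample(feats, label, str(sid)))
    return samples
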