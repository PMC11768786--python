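"""Time- and frequency-domain EMG fatigue indicators.

Per analysis window the five standard sEMG indicators are computed:

* ARV  — average rectified value, mean of |x|;
* IEMG — integrated EMG, the rectified area |x| summed over the window
  (so IEMG = ARV * T identically);
* RMS  — root mean square;
* MPF  — mean power frequency, the centroid of the power spectral density;
* MF   — median frequency, the half-power split of the PSD.

The amplitude indicators (RMS, ARV, IEMG) rise and the spectral indicators
(MPF, MF) fall as a muscle fatigues.  The PSD is a Welch-averaged
periodogram (1 s Hann segments, 50% overlap by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal import SampledSignal


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided power spectral density on an ascending frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    df: float

    @property
    def total_power(self) -> float:
        return float(np.sum(self.power) * self.df)


@dataclass(frozen=True)
class EMGFeatureSet:
    """The five indicators for one analysis window."""

    arv: float
    iemg: float
    rms: float
    mpf: float
    mf: float


def _window_array(window) -> np.ndarray:
    x = window.samples if isinstance(window, SampledSignal) else np.asarray(window, float)
    if x.size == 0:
        raise ValueError("empty analysis window")
    return x


def arv(window) -> float:
    """Average rectified value: (1/N) * sum |x_i|."""
    return float(np.mean(np.abs(_window_array(window))))


def iemg(window, fs: float) -> float:
    """Integrated EMG: sum |x_i| / fs = ARV * T (amplitude * s)."""
    x = _window_array(window)
    return float(np.sum(np.abs(x)) / fs)


def rms(window) -> float:
    """Root mean square: sqrt((1/N) * sum x_i^2)."""
    return float(np.sqrt(np.mean(np.square(_window_array(window)))))


def estimate_psd(window, fs: float | None = None, segment_s: float = 1.0,
                 overlap: float = 0.5) -> PSDEstimate:
    """Welch PSD (Hann taper) of one analysis window.

    Total integrated power matches the signal variance (Parseval) up to the
    estimator's leakage.  Raises if the window is shorter than one segment.
    """
    if isinstance(window, SampledSignal):
        fs = window.fs
        x = window.samples
    else:
        if fs is None:
            raise ValueError("fs is required when the window is a bare array")
        x = np.asarray(window, float)
    nperseg = round(segment_s * fs)
    if x.size < nperseg:
        raise ValueError(
            f"window of {x.size} samples is shorter than one {nperseg}-sample PSD segment")
    freqs, power = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                             noverlap=round(overlap * nperseg), detrend="constant")
    return PSDEstimate(freqs, power, float(freqs[1] - freqs[0]))


def mpf(psd: PSDEstimate) -> float:
    """Mean power frequency: the PSD centroid, integral(f*PSD)/integral(PSD)."""
    total = np.sum(psd.power)
    if total <= 0:
        raise ValueError("MPF undefined for an all-zero PSD")
    return float(np.sum(psd.freqs * psd.power) / total)


def mf(psd: PSDEstimate) -> float:
    """Median frequency: smallest grid frequency whose cumulative power
    reaches half the total (ties resolved by >=)."""
    total = np.sum(psd.power)
    if total <= 0:
        raise ValueError("MF undefined for an all-zero PSD")
    cum = np.cumsum(psd.power)
    idx = int(np.searchsorted(cum, 0.5 * total))
    return float(psd.freqs[idx])


def extract_features(window, fs: float | None = None, **psd_kwargs) -> EMGFeatureSet:
    """All five indicators for one window."""
    if isinstance(window, SampledSignal):
        fs = window.fs
        x = window.samples
    else:
        x = np.asarray(window, float)
    psd = estimate_psd(x, fs, **psd_kwargs)
    return EMGFeatureSet(arv=arv(x), iemg=iemg(x, fs), rms=rms(x),
                         mpf=mpf(psd), mf=mf(psd))


def feature_table(signal: SampledSignal, window_s: float = 1.0):
    """Windowed feature table with columns t, arv, iemg, rms, mpf, mf.

    Windows are non-overlapping, ``window_s`` seconds each; a trailing
    partial window is dropped.
    """
    import pandas as pd

    n_win = round(window_s * signal.fs)
    rows = []
    for k in range(signal.n // n_win):
        x = signal.samples[k * n_win:(k + 1) * n_win]
        f = extract_features(x, signal.fs, segment_s=min(1.0, window_s))
        rows.append({"t": k * window_s, "arv": f.arv, "iemg": f.iemg,
                     "rms": f.rms, "mpf": f.mpf, "mf": f.mf})
    return pd.DataFrame(rows)
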