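"""Uniformly sampled single-channel biosignals and their on-disk text format.

A :class:`SampledSignal` is the unit every stage of the pipeline consumes and
produces: a 1-D float array, a sampling rate in Hz, and a ``kind`` tag
(``"emg"`` or ``"ecg"``).  Signals round-trip through a two-column delimited
text file (``time_s, value``) whose header comment carries the metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_KINDS = ("emg", "ecg")


@dataclass
class SampledSignal:
    """A uniformly sampled biosignal.

    Parameters
    ----------
    samples : ndarray
        Signal values; mV for ECG, normalized amplitude units for EMG.
    fs : float
        Sampling rate in Hz.
    kind : str
        ``"emg"`` or ``"ecg"``.
    meta : dict
        Free-form provenance (seed, fatigue state, ground-truth R-peak
        times for synthetic ECG, ...).  Never required by consumers.
    """

    samples: np.ndarray
    fs: float
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def replace(self, samples: np.ndarray) -> "SampledSignal":
        """New signal with the same rate/kind/meta but different samples."""
        return SampledSignal(np.asarray(samples, float), self.fs, self.kind, dict(self.meta))

    # -- text I/O -----------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write as ``time_s,value`` rows with a ``#``-comment metadata header."""
        extras = " ".join(
            f"{k}={v}" for k, v in self.meta.items() if np.isscalar(v) or isinstance(v, str)
        )
        header = f"fs={self.fs} kind={self.kind}" + (f" {extras}" if extras else "")
        data = np.column_stack([self.times, self.samples])
        np.savetxt(path, data, delimiter=",", header=header + "\ntime_s,value")

    @classmethod
    def from_csv(cls, path) -> "SampledSignal":
        meta: dict = {}
        fs = None
        kind = None
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for token in line[1:].split():
                    if "=" not in token:
                        continue
                    key, val = token.split("=", 1)
                    if key == "fs":
                        fs = float(val)
                    elif key == "kind":
                        kind = val
                    else:
                        meta[key] = val
        data = np.loadtxt(path, delimiter=",")
        t, x = data[:, 0], data[:, 1]
        if fs is None:
            dt = np.median(np.diff(t))
            fs = 1.0 / dt
        if kind is None:
            raise ValueError(f"{path}: header does not declare kind=emg|ecg")
        return cls(x, fs, kind, meta)
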