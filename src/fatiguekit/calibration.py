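"""Fatigue states and the calibration targets of the synthetic generators.

Three exercise-fatigue states are used throughout, indexed by the Borg rate
of perceived exertion (RPE): A (RPE 8, very relaxed), B (RPE 13, slightly
tired) and C (RPE 18, very tired).  For each state the generators are
calibrated to published normalized EMG indicator levels (per muscle:
ARV, IEMG, RMS, MPF, MF) and ECG indicator levels (heart rate, HRV
low-/high-frequency band powers and their ratio).  The defaults ship in
``data/default_calibrations.yaml`` and can be overridden from any YAML file
with the same layout.

Note on the ECG low-frequency band: the calibration stores HF power and the
LF/HF ratio and derives LF = (LF/HF) * HF, so that the generated recordings
are self-consistent in the quantity (the ratio) that indexes autonomic
balance.  See docs/methods.md for why LF is derived rather than set directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import yaml


class FatigueState(enum.Enum):
    """Exercise-fatigue state; the A/B/C <-> RPE 8/13/18 mapping is fixed."""

    A = ("A", 8, "very relaxed")
    B = ("B", 13, "slightly tired")
    C = ("C", 18, "very tired")

    def __init__(self, label: str, rpe: int, description: str):
        self.label = label
        self.rpe = rpe
        self.description = description

    @classmethod
    def from_label(cls, label: str) -> "FatigueState":
        return cls[label.upper()]


MUSCLES = ("vastus_lateralis", "rectus_femoris", "vastus_medialis")


@dataclass(frozen=True)
class EMGStateCalibration:
    """Per-muscle, per-state EMG indicator targets (normalized units, Hz)."""

    muscle: str
    state: FatigueState
    target_arv: float
    sd_arv: float
    target_iemg: float
    sd_iemg: float
    target_rms: float
    sd_rms: float
    target_mpf: float
    sd_mpf: float
    target_mf: float
    sd_mf: float

    def __post_init__(self):
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}")
        if self.target_rms < self.target_arv or self.target_arv < 0:
            raise ValueError("calibration requires target_rms >= target_arv >= 0")
        if self.target_rms > 0 and not (20.0 <= self.target_mpf <= 150.0):
            raise ValueError("target_mpf must lie in the 20-150 Hz surface-EMG energy band")
        for name in ("sd_arv", "sd_iemg", "sd_rms", "sd_mpf", "sd_mf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ECGStateCalibration:
    """Per-state ECG targets: HR (beats/min), HF power (ms^2), LF/HF ratio."""

    state: FatigueState
    mean_hr: float
    sd_hr: float
    hf_power: float
    sd_hf: float
    lf_hf: float
    sd_lf_hf: float

    @property
    def lf_power(self) -> float:
        """LF band power in ms^2, derived so that LF/HF equals the target ratio."""
        return self.lf_hf * self.hf_power

    def __post_init__(self):
        if self.mean_hr <= 0:
            raise ValueError("mean_hr must be positive")
        if self.hf_power < 0 or self.lf_hf < 0:
            raise ValueError("band powers must be non-negative")


@dataclass(frozen=True)
class ContaminantSpec:
    """Additive interference injected by the generators.

    Baseline drift is a sub-few-Hz sinusoid (respiration/electrode wander),
    mains is a 50 Hz tone, and motion artifact is band-limited noise in the
    3-14 Hz range.  Amplitudes are in the signal's own units; an amplitude
    of zero (the default) disables that contaminant.
    """

    drift_amplitude: float = 0.0
    drift_freq: float = 0.3
    mains_amplitude: float = 0.0
    mains_freq: float = 50.0
    motion_amplitude: float = 0.0
    motion_band: tuple = (3.0, 14.0)

    def __post_init__(self):
        if min(self.drift_amplitude, self.mains_amplitude, self.motion_amplitude) < 0:
            raise ValueError("contaminant amplitudes must be >= 0")
        if not (0 < self.drift_freq < 3.0):
            raise ValueError("baseline drift frequency must lie below 3 Hz")

    @property
    def any_enabled(self) -> bool:
        return max(self.drift_amplitude, self.mains_amplitude, self.motion_amplitude) > 0


NO_CONTAMINANTS = ContaminantSpec()


def _load_yaml(path=None) -> dict:
    if path is None:
        ref = resources.files("fatiguekit") / "data" / "default_calibrations.yaml"
        with ref.open() as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_emg_calibrations(path=None) -> dict:
    """Load EMG calibrations keyed by ``(muscle, FatigueState)``."""
    raw = _load_yaml(path)["emg"]
    out = {}
    for muscle, states in raw.items():
        for label, v in states.items():
            state = FatigueState.from_label(label)
            out[(muscle, state)] = EMGStateCalibration(
                muscle=muscle,
                state=state,
                target_arv=v["arv"][0], sd_arv=v["arv"][1],
                target_iemg=v["iemg"][0], sd_iemg=v["iemg"][1],
                target_rms=v["rms"][0], sd_rms=v["rms"][1],
                target_mpf=v["mpf"][0], sd_mpf=v["mpf"][1],
                target_mf=v["mf"][0], sd_mf=v["mf"][1],
            )
    return out


def load_ecg_calibrations(path=None) -> dict:
    """Load ECG calibrations keyed by ``FatigueState``."""
    raw = _load_yaml(path)["ecg"]
    out = {}
    for label, v in raw.items():
        state = FatigueState.from_label(label)
        out[state] = ECGStateCalibration(
            state=state,
            mean_hr=v["hr"][0], sd_hr=v["hr"][1],
            hf_power=v["hf"][0], sd_hf=v["hf"][1],
            lf_hf=v["lf_hf"][0], sd_lf_hf=v["lf_hf"][1],
        )
    return out


def default_emg_calibration(state: FatigueState, muscle: str = "vastus_lateralis") -> EMGStateCalibration:
    return load_emg_calibrations()[(muscle, state)]


def default_ecg_calibration(state: FatigueState) -> ECGStateCalibration:
    return load_ecg_calibrations()[state]
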