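"""IMU signal preparation: filtering, cycle normalization, and scaling.

The six pelvis-IMU channels (three linear accelerations, three angular
velocities) are low-pass filtered, resampled onto the 101-point gait cycle
and linearly scaled to [-1, 1] channel-wise.  The scaling statistics are
fitted on the training split only and kept for inversion at inference;
validation/test values outside the training range are deliberately not
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from .balance import GaitEvents, N_CYCLE

__all__ = [
    "NormalizedTrial",
    "ChannelScaler",
    "butterworth_lowpass",
    "prepare_trial",
]

IMU_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")
OUTPUT_CHANNELS = ("sagittal_ia", "frontal_ia")


@dataclass
class NormalizedTrial:
    """One gait cycle ready for model training.

    ``imu`` holds the 6 x 101 filtered, cycle-normalized (unscaled) IMU
    matrix; ``target_ia`` the 2 x 101 ground-truth inclination angles in
    degrees (rows sagittal, frontal), ``target_rcia`` their rates of change
    in deg/s.  Scaled copies are produced on demand by a ChannelScaler.
    """

    imu: np.ndarray
    target_ia: np.ndarray
    target_rcia: np.ndarray
    events: GaitEvents
    cycle_duration_s: float
    subject_id: str
    group: str
    trial_id: str = ""
    stance_side: str = "right"

    def __post_init__(self) -> None:
        self.imu = np.asarray(self.imu, float)
        self.target_ia = np.asarray(self.target_ia, float)
        self.target_rcia = np.asarray(self.target_rcia, float)
        if self.imu.shape != (6, N_CYCLE):
            raise ValueError(f"imu must be 6 x {N_CYCLE}, got {self.imu.shape}")
        if self.target_ia.shape != (2, N_CYCLE):
            raise ValueError(f"target_ia must be 2 x {N_CYCLE}")
        if self.target_rcia.shape != (2, N_CYCLE):
            raise ValueError(f"target_rcia must be 2 x {N_CYCLE}")
        if self.group not in ("old", "young"):
            raise ValueError("group must be 'old' or 'young'")
        if self.cycle_duration_s <= 0:
            raise ValueError("cycle_duration_s must be positive")


def butterworth_lowpass(
    signal: np.ndarray,
    rate_hz: float,
    cutoff_hz: float = 15.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase fourth-order Butterworth low-pass filter.

    Applied forward and backward (``filtfilt``) so the passband stays
    phase-aligned with the balance targets; the composed magnitude response
    is the squared single-pass response.  Works on the last axis.
    """
    if cutoff_hz >= rate_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {rate_hz / 2} Hz")
    b, a = butter(order, cutoff_hz, btype="low", fs=rate_hz)
    return filtfilt(b, a, np.asarray(signal, float), axis=-1)


@dataclass
class ChannelScaler:
    """Per-channel linear map to [-1, 1] fitted on the training split.

    ``x -> 2 (x - min) / (max - min) - 1`` per channel; inversion is exact.
    Holds statistics for the 6 input channels and the 2 output channels.
    """

    input_min: np.ndarray = field(default=None)
    input_max: np.ndarray = field(default=None)
    output_min: np.ndarray = field(default=None)
    output_max: np.ndarray = field(default=None)

    @classmethod
    def fit(cls, trials: list[NormalizedTrial]) -> "ChannelScaler":
        """Fit channel ranges over a list of (training) trials."""
        if not trials:
            raise ValueError("cannot fit a scaler on an empty training set")
        X = np.stack([t.imu for t in trials])          # (n, 6, 101)
        Y = np.stack([t.target_ia for t in trials])    # (n, 2, 101)
        sc = cls(
            input_min=X.min(axis=(0, 2)), input_max=X.max(axis=(0, 2)),
            output_min=Y.min(axis=(0, 2)), output_max=Y.max(axis=(0, 2)),
        )
        for names, lo, hi in ((IMU_CHANNELS, sc.input_min, sc.input_max),
                              (OUTPUT_CHANNELS, sc.output_min, sc.output_max)):
            flat = np.isclose(hi, lo)
            if flat.any():
                bad = [n for n, f in zip(names, flat) if f]
                raise ValueError(f"constant channel(s) cannot be scaled: {bad}")
        return sc

    @staticmethod
    def _apply(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        return 2.0 * (x - lo[:, None]) / (hi - lo)[:, None] - 1.0

    @staticmethod
    def _invert(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        return (x + 1.0) / 2.0 * (hi - lo)[:, None] + lo[:, None]

    def scale_inputs(self, imu: np.ndarray) -> np.ndarray:
        return self._apply(np.asarray(imu, float), self.input_min, self.input_max)

    def unscale_inputs(self, imu: np.ndarray) -> np.ndarray:
        return self._invert(np.asarray(imu, float), self.input_min, self.input_max)

    def scale_outputs(self, ia: np.ndarray) -> np.ndarray:
        return self._apply(np.asarray(ia, float), self.output_min, self.output_max)

    def unscale_outputs(self, ia: np.ndarray) -> np.ndarray:
        return self._invert(np.asarray(ia, float), self.output_min, self.output_max)

    @property
    def output_gain(self) -> np.ndarray:
        """deg per scaled unit, per output channel (for rate conversions)."""
        return (self.output_max - self.output_min) / 2.0

    # -- plain-text serialization ------------------------------------------
    def save(self, path: str | Path) -> None:
        lines = ["channel\tmin\tmax"]
        for names, lo, hi in ((IMU_CHANNELS, self.input_min, self.input_max),
                              (OUTPUT_CHANNELS, self.output_min, self.output_max)):
            for n, a, b in zip(names, lo, hi):
                lines.append(f"{n}\t{float(a)!r}\t{float(b)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ChannelScaler":
        rows = {}
        for line in Path(path).read_text().splitlines()[1:]:
            name, lo, hi = line.split("\t")
            rows[name] = (float(lo), float(hi))
        return cls(
            input_min=np.array([rows[n][0] for n in IMU_CHANNELS]),
            input_max=np.array([rows[n][1] for n in IMU_CHANNELS]),
            output_min=np.array([rows[n][0] for n in OUTPUT_CHANNELS]),
            output_max=np.array([rows[n][1] for n in OUTPUT_CHANNELS]),
        )


def prepare_trial(
    imu_raw: np.ndarray,
    events: GaitEvents,
    target_ia: np.ndarray,
    target_rcia: np.ndarray,
    rate_hz: float = 100.0,
    cutoff_hz: float = 15.0,
    subject_id: str = "",
    group: str = "young",
    trial_id: str = "",
    stance_side: str = "right",
) -> NormalizedTrial:
    """Filter and cycle-normalize a raw 6-channel IMU record into a trial.

    ``imu_raw`` is (6, n_samples) at ``rate_hz``; ``events`` index into it.
    Cycle normalization of the inputs uses the same (force-plate derived)
    events as the targets; IMU-only event detection is an integration hook
    deliberately left to the caller.
    """
    imu_raw = np.asarray(imu_raw, float)
    if imu_raw.ndim != 2 or imu_raw.shape[0] != 6:
        raise ValueError("imu_raw must be (6, n_samples)")
    filtered = butterworth_lowpass(imu_raw, rate_hz, cutoff_hz)
    from .balance import normalize_cycle
    imu = np.stack([normalize_cycle(ch, events) for ch in filtered])
    return NormalizedTrial(
        imu=imu, target_ia=target_ia, target_rcia=target_rcia,
        events=events, cycle_duration_s=events.cycle_duration_s,
        subject_id=subject_id, group=group, trial_id=trial_id,
        stance_side=stance_side,
    )
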