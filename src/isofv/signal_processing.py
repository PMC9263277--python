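"""Torque-time trace processing: filtering, isokinetic-window detection, peak extraction.

The processing chain mirrors standard isokinetic dynamometry practice: traces
sampled at 500 Hz are low-pass filtered with a zero-phase second-order
Butterworth filter (5 Hz cutoff), the isokinetic plateau of each repetition is
located from the velocity channel, the peak filtered torque is taken per
repetition, and the best peak among the final repetitions of the set is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import (
    InsufficientRepetitionsError,
    InvalidParameterError,
    MalformedInputError,
    NoPlateauError,
)

__all__ = [
    "TorqueTrace",
    "IsokineticWindow",
    "RepetitionPeak",
    "IsometricResult",
    "lowpass_filter",
    "detect_isokinetic_window",
    "extract_repetition_peaks",
    "select_best_peak",
    "isometric_peak",
    "best_peak_from_trace",
]

#: Relative tolerance on time-grid uniformity (1 part in 1e6).
_GRID_RTOL = 1e-6

#: Minimum plateau duration accepted as an isokinetic window (seconds).
MIN_PLATEAU_S = 0.05


@dataclass(frozen=True)
class TorqueTrace:
    """A sampled torque-time record with optional velocity/angle channels.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing on a uniform grid.
    torque
        Torque in newton-meters, same length as ``time``, finite everywhere.
    sampling_rate
        Nominal sampling rate in hertz.
    protocol_velocity
        Commanded angular velocity in degrees/second (0 for isometric trials).
    task_label
        Task identifier, ``"KE"`` (knee extension) or ``"KF"`` (knee flexion).
    angular_velocity, angle
        Optional channels in degrees/second and degrees.
    """

    time: np.ndarray
    torque: np.ndarray
    sampling_rate: float
    protocol_velocity: float = 0.0
    task_label: str = "KE"
    angular_velocity: np.ndarray | None = None
    angle: np.ndarray | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        torque = np.asarray(self.torque, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "torque", torque)
        for name in ("angular_velocity", "angle"):
            ch = getattr(self, name)
            if ch is not None:
                object.__setattr__(self, name, np.asarray(ch, dtype=float))
        if time.ndim != 1 or torque.shape != time.shape:
            raise MalformedInputError("time and torque must be 1-D arrays of equal length")
        if time.size < 2:
            raise MalformedInputError("trace needs at least 2 samples")
        if not np.all(np.isfinite(torque)):
            raise MalformedInputError("torque contains non-finite samples")
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise MalformedInputError("time must be strictly increasing")
        if self.task_label not in ("KE", "KF"):
            raise MalformedInputError(f"task_label must be 'KE' or 'KF', got {self.task_label!r}")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (span plus one sample period)."""
        return float(self.time[-1] - self.time[0]) + 1.0 / self.sampling_rate

    def is_uniform(self) -> bool:
        dt = np.diff(self.time)
        return bool(np.all(np.abs(dt - dt.mean()) <= _GRID_RTOL * max(dt.mean(), 1e-30)))


@dataclass(frozen=True)
class IsokineticWindow:
    """Half-open [start_index, end_index) run of near-constant achieved velocity."""

    start_index: int
    end_index: int
    achieved_velocity: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise MalformedInputError("window indices must satisfy 0 <= start < end")


@dataclass(frozen=True)
class RepetitionPeak:
    """Peak torque of one repetition's isokinetic window (repetition_index is 1-based)."""

    repetition_index: int
    peak_torque: float
    peak_sample_index: int


@dataclass(frozen=True)
class IsometricResult:
    """Peak of an isometric trial, with a flag when the hold was shorter than required."""

    peak_torque: float
    short_duration: bool = False


def lowpass_filter(trace: TorqueTrace, cutoff: float = 5.0, order: int = 2) -> TorqueTrace:
    """Zero-phase Butterworth low-pass filter of the torque channel.

    Applied forward-backward so peak timing is preserved; DC gain is exactly 1.
    Returns a new trace on the identical time grid.
    """
    nyquist = trace.sampling_rate / 2.0
    if cutoff <= 0 or cutoff >= nyquist:
        raise InvalidParameterError(
            f"cutoff must be in (0, Nyquist={nyquist:g} Hz), got {cutoff:g}"
        )
    if order < 1:
        raise InvalidParameterError(f"order must be >= 1, got {order}")
    if not trace.is_uniform():
        raise MalformedInputError("time grid is not uniform; cannot filter")
    if trace.n_samples < 3 * (order + 1):
        raise MalformedInputError(
            f"trace too short to filter: {trace.n_samples} < {3 * (order + 1)} samples"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=trace.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.torque)
    return replace(trace, torque=filtered)


def _velocity_channel(trace: TorqueTrace, cutoff: float, order: int) -> np.ndarray:
    """Achieved angular velocity: measured channel, or angle differentiated then filtered."""
    if trace.angular_velocity is not None:
        return trace.angular_velocity
    if trace.angle is None:
        raise MalformedInputError("trace has neither an angular_velocity nor an angle channel")
    # central differences, then the same zero-phase low-pass as the torque channel
    raw = np.gradient(trace.angle, trace.time)
    sos = sps.butter(order, cutoff, btype="low", fs=trace.sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, raw)


def detect_isokinetic_window(
    trace: TorqueTrace,
    tolerance_fraction: float = 0.05,
    min_duration_s: float = MIN_PLATEAU_S,
    velocity_filter_cutoff: float = 5.0,
    velocity_filter_order: int = 2,
) -> list[IsokineticWindow]:
    """Locate one isokinetic plateau per repetition.

    A window is a maximal run of samples whose achieved velocity lies within
    ``tolerance_fraction`` of the protocol velocity and lasts at least
    ``min_duration_s``. Windows are returned in temporal order.
    """
    if trace.protocol_velocity <= 0:
        raise InvalidParameterError("detect_isokinetic_window requires protocol_velocity > 0")
    vel = np.abs(_velocity_channel(trace, velocity_filter_cutoff, velocity_filter_order))
    target = trace.protocol_velocity
    mask = np.abs(vel - target) <= tolerance_fraction * target

    min_len = max(2, int(round(min_duration_s * trace.sampling_rate)))
    windows: list[IsokineticWindow] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, stop in edges.reshape(-1, 2):
        if stop - start >= min_len:
            windows.append(
                IsokineticWindow(
                    start_index=int(start),
                    end_index=int(stop),
                    achieved_velocity=float(vel[start:stop].mean()),
                )
            )
    if not windows:
        raise NoPlateauError(
            f"no isokinetic plateau found at protocol velocity {target:g} deg/s "
            f"(tolerance {tolerance_fraction:.0%}, min duration {min_duration_s * 1e3:.0f} ms)"
        )
    return windows


def extract_repetition_peaks(
    trace: TorqueTrace, windows: Sequence[IsokineticWindow]
) -> list[RepetitionPeak]:
    """Peak torque per isokinetic window. Expects an already-filtered trace."""
    if len(windows) == 0:
        raise InvalidParameterError("windows must be non-empty")
    ordered = sorted(windows, key=lambda w: w.start_index)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start_index < prev.end_index:
            raise MalformedInputError("isokinetic windows overlap")
    peaks = []
    for i, w in enumerate(ordered, start=1):
        if w.end_index > trace.n_samples:
            raise MalformedInputError("window extends past end of trace")
        seg = trace.torque[w.start_index : w.end_index]
        k = int(np.argmax(seg))
        peaks.append(
            RepetitionPeak(
                repetition_index=i,
                peak_torque=float(seg[k]),
                peak_sample_index=w.start_index + k,
            )
        )
    return peaks


def select_best_peak(
    peaks: Sequence[RepetitionPeak], consider_last: int = 4
) -> RepetitionPeak:
    """Best (maximum) peak among the final ``consider_last`` repetitions.

    Ties break toward the earlier repetition, so the result is deterministic.
    """
    if consider_last < 1:
        raise InvalidParameterError("consider_last must be >= 1")
    if len(peaks) < consider_last:
        raise InsufficientRepetitionsError(
            f"need at least {consider_last} repetitions, got {len(peaks)}"
        )
    ordered = sorted(peaks, key=lambda p: p.repetition_index)
    tail = ordered[-consider_last:]
    best = tail[0]
    for p in tail[1:]:
        if p.peak_torque > best.peak_torque:
            best = p
    return best


def isometric_peak(trace: TorqueTrace, min_hold_s: float = 3.0) -> IsometricResult:
    """Maximum filtered torque of an isometric trial.

    Traces shorter than ``min_hold_s`` are flagged (warning-level), not rejected.
    """
    if trace.protocol_velocity != 0:
        raise InvalidParameterError("isometric_peak requires protocol_velocity == 0")
    short = trace.duration < min_hold_s
    if short:
        warnings.warn(
            f"isometric trial lasted {trace.duration:.2f} s < {min_hold_s:g} s",
            UserWarning,
            stacklevel=2,
        )
    return IsometricResult(peak_torque=float(np.max(trace.torque)), short_duration=short)


def best_peak_from_trace(
    trace: TorqueTrace,
    cutoff: float = 5.0,
    order: int = 2,
    tolerance_fraction: float = 0.05,
    consider_last: int = 4,
) -> float:
    """Full chain for one trace: filter, locate windows, extract peaks, select best.

    For isometric traces (protocol_velocity == 0) returns the filtered trial maximum.
    """
    filtered = lowpass_filter(trace, cutoff=cutoff, order=order)
    if trace.protocol_velocity == 0:
        return isometric_peak(filtered).peak_torque
    windows = detect_isokinetic_window(filtered, tolerance_fraction=tolerance_fraction)
    peaks = extract_repetition_peaks(filtered, windows)
    return select_best_peak(peaks, consider_last=min(consider_last, len(peaks))).peak_torque
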