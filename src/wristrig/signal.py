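"""Raw-count conversion, low-pass filtering, flexion extraction and windowing.

The gyroscope reports signed 16-bit counts on a ±2000 °/s full scale; counts
convert to angular velocity as ``omega = raw / 2**15 * 2000``.  The sensor is
worn so that passive wrist *flexion* drives the y-axis angular velocity
negative, so rigidity features are computed on the negative arcades only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from .profiles import GYRO_FULL_SCALE_DPS, RAW_FULL_SCALE

__all__ = [
    "AngularVelocitySignal",
    "SignalWindow",
    "FlexionSamples",
    "convert_raw_to_angular_velocity",
    "moving_average_filter",
    "extract_flexion_samples",
    "window_stream",
]


@dataclass(frozen=True)
class AngularVelocitySignal:
    """Multi-axis angular-velocity trace in °/s at a fixed sampling rate."""

    sampling_rate_hz: float
    omega_x: np.ndarray
    omega_y: np.ndarray
    omega_z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("omega_x", "omega_y", "omega_z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.omega_y)
        if len(self.omega_x) != n or len(self.omega_z) != n:
            raise ValueError("axis traces must have equal length")
        for name in ("omega_x", "omega_y", "omega_z"):
            arr = getattr(self, name)
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    def __len__(self) -> int:
        return len(self.omega_y)

    def axis(self, name: str) -> np.ndarray:
        try:
            return {"x": self.omega_x, "y": self.omega_y, "z": self.omega_z}[name]
        except KeyError:
            raise ValueError(f"unknown axis {name!r}; expected one of x, y, z") from None


@dataclass(frozen=True)
class SignalWindow:
    """One contiguous, non-overlapping block of samples from a session."""

    start_index: int
    axis_data: dict[str, np.ndarray] = field(repr=False)

    @property
    def length(self) -> int:
        return len(next(iter(self.axis_data.values())))

    def axis(self, name: str) -> np.ndarray:
        try:
            return self.axis_data[name]
        except KeyError:
            raise ValueError(f"unknown axis {name!r}") from None


@dataclass(frozen=True)
class FlexionSamples:
    """Flexion-phase samples of one trace: magnitudes plus source indices.

    Arcade boundaries (sign changes of the raw trace) are recoverable from
    gaps in ``indices``; ``arcade_slices`` groups the retained samples into
    contiguous runs, one per flexion arcade.
    """

    magnitudes: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        if len(self.magnitudes) != len(self.indices):
            raise ValueError("magnitudes and indices must align")

    @property
    def arcade_slices(self) -> list[slice]:
        if self.indices.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(self.indices) > 1) + 1
        bounds = np.concatenate([[0], breaks, [self.indices.size]])
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def convert_raw_to_angular_velocity(
    raw: npt.ArrayLike,
) -> np.ndarray | float:
    """Convert raw gyroscope counts to angular velocity in °/s.

    The conversion is ``raw / 2**15 * 2000`` applied elementwise; it is linear
    and odd, and maps the full-scale count 2**15 to exactly 2000 °/s.  Counts
    outside [-32768, 32768] are rejected.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size and (arr.min() < -RAW_FULL_SCALE or arr.max() > RAW_FULL_SCALE):
        raise ValueError(
            f"raw gyroscope count outside [{-RAW_FULL_SCALE}, {RAW_FULL_SCALE}]"
        )
    out = arr / RAW_FULL_SCALE * GYRO_FULL_SCALE_DPS
    return float(out) if np.isscalar(raw) or out.ndim == 0 else out


def moving_average_filter(signal: npt.ArrayLike, width: int = 4) -> np.ndarray:
    """Causal trailing moving average used for non-movement noise reduction.

    ``out[i]`` is the mean of ``signal[max(0, i-width+1) .. i]`` — the first
    ``width-1`` samples average a growing prefix so output length equals
    input length.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        return x.copy()
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - width + 1, 0)
    return (csum[idx + 1] - csum[lo]) / (idx - lo + 1)


def extract_flexion_samples(signal: npt.ArrayLike) -> FlexionSamples:
    """Retain the strictly negative (flexion-direction) samples of a trace.

    Sensor orientation makes flexion negative along y; magnitudes are
    returned rectified together with the original sample indices, so arcade
    boundaries remain recoverable.
    """
    x = np.asarray(signal, dtype=float)
    idx = np.flatnonzero(x < 0)
    return FlexionSamples(magnitudes=-x[idx], indices=idx)


def window_stream(
    signal: AngularVelocitySignal, window_size: int
) -> tuple[list[SignalWindow], int]:
    """Split a session into contiguous non-overlapping fixed-length windows.

    Returns the complete windows in order plus the residual sample count
    (trailing samples too few to form a window; reported, never classified).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    n = len(signal)
    n_windows = n // window_size
    windows = []
    for k in range(n_windows):
        sl = slice(k * window_size, (k + 1) * window_size)
        windows.append(
            SignalWindow(
                start_index=k * window_size,
                axis_data={
                    "x": signal.omega_x[sl],
                    "y": signal.omega_y[sl],
                    "z": signal.omega_z[sl],
                },
            )
        )
    return windows, n - n_windows * window_size
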