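import numpy as np
import pytest

from wristrig.profiles import PipelineConfig
from wristrig.signal import AngularVelocitySignal, SignalWindow


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()  # v2 profile: 50 Hz, 200-sample windows


def make_arcade(amplitude: float, length: int = 40) -> np.ndarray:
    """Rectified half-sine flexion arcade (strictly positive interior)."""
    phase = (np.arange(length) + 0.5) / length
    return amplitude * np.sin(np.pi * phase)


def make_flexion_window(
    amplitudes, length: int = 200, arcade_len: int = 40
) -> SignalWindow:
    """A y-axis window holding one negative half-sine arcade per amplitude."""
    y = np.zeros(length)
    slot = length // len(list(amplitudes))
    for k, amp in enumerate(amplitudes):
        y[k * slot : k * slot + arcade_len] = -make_arcade(amp, arcade_len)
    return SignalWindow(
        start_index=0,
        axis_data={"x": np.zeros(length), "y": y, "z": np.zeros(length)},
    )


@pytest.fixture
def two_arcade_window() -> SignalWindow:
    return make_flexion_window([10.0, 20.0])


def make_signal(y, sampling_rate_hz: float = 50.0) -> AngularVelocitySignal:
    y = np.asarray(y, dtype=float)
    return AngularVelocitySignal(
        sampling_rate_hz=sampling_rate_hz,
        omega_x=np.zeros_like(y),
        omega_y=y,
        omega_z=np.zeros_like(y),
    )
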