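"""Synthetic surgical-session generator with labelled flexion windows.

Real intra-operative recordings are not publicly available, so this module
generates angular-velocity sessions carrying the statistical structure the
calibration method assumes:

* each window holds a few passive wrist-flexion arcades — negative
  half-sine pulses on the y-axis;
* arcade peak amplitude grows linearly with the rigidity-improvement label
  ``r``:  A(r) = base · (1 + gain · r/80), so a 0→80 % improvement raises
  the peak velocity from ≈15 to ≈33 °/s at the defaults, matching the
  reported rigid vs non-rigid mean-peak scale;
* cogwheel artefacts appear as interior raised-cosine dips; their count per
  window is Poisson with a mean that decreases linearly in ``r`` through
  the observed anchors (2.6 at 40 %, 1.2 at 80 %);
* the x-axis carries a fraction of the flexion movement plus noise, the
  z-axis noise only (only y is pronounced during passive flexion);
* everything is reproducible from one seed, with per-window substreams so
  window k is independent of how many windows precede it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .profiles import PROFILES
from .signal import AngularVelocitySignal

__all__ = [
    "SimulationConfig",
    "SyntheticSession",
    "cogwheel_rate",
    "generate_session",
    "generate_labelled_windows",
]

#: Printed per-window cogwheel-count anchors (label %, mean count).
COGWHEEL_ANCHORS = ((40.0, 2.6), (80.0, 1.2))


def cogwheel_rate(improvement: float) -> float:
    """Expected cogwheel artefacts per window, linear through the anchors."""
    (r0, c0), (r1, c1) = COGWHEEL_ANCHORS
    rate = c0 + (c1 - c0) * (improvement - r0) / (r1 - r0)
    return max(rate, 0.0)


class SimulationConfig(BaseModel):
    """Defaults define the simulated study conditions; seed fixes the path."""

    improvement_schedule: tuple[tuple[int, int], ...] = Field(
        default=((0, 20), (40, 20), (50, 20), (60, 20), (70, 20), (80, 20)),
        description="sequence of (improvement %, n_windows)",
    )
    base_peak_amplitude: float = Field(default=15.0, gt=0, description="°/s at r=0")
    amplitude_gain: float = Field(
        default=1.2, ge=0, description="fractional peak increase per 80% improvement"
    )
    arcade_rate: float = Field(default=0.75, gt=0, description="flexions per second")
    arcade_duty: float = Field(
        default=0.6, gt=0, le=1, description="fraction of each flexion slot in motion"
    )
    notch_depth_range: tuple[float, float] = (0.4, 0.5)
    notch_width_s: float = Field(default=0.08, gt=0)
    noise_sd: float = Field(default=0.05, ge=0, description="°/s, per-sample Gaussian")
    x_leak: float = Field(default=0.25, ge=0, description="flexion fraction on x-axis")
    device_profile: str = "v2"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.device_profile not in PROFILES:
            raise ValueError(f"unknown device profile {self.device_profile!r}")
        lo, hi = self.notch_depth_range
        if not (0 < lo <= hi < 1):
            raise ValueError("notch_depth_range must satisfy 0 < lo <= hi < 1")
        return self


@dataclass(frozen=True)
class SyntheticSession:
    """A generated session plus its per-window ground truth."""

    signal: AngularVelocitySignal
    window_labels: np.ndarray
    injected_cogwheel_counts: np.ndarray
    valid: np.ndarray
    config: SimulationConfig

    @property
    def n_windows(self) -> int:
        return len(self.window_labels)


def _amplitude(cfg: SimulationConfig, improvement: float) -> float:
    return cfg.base_peak_amplitude * (1.0 + cfg.amplitude_gain * improvement / 80.0)


def _make_window(
    cfg: SimulationConfig, improvement: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """One window of clean (noise-free) y-axis flexion; returns (trace, n_notches)."""
    profile = PROFILES[cfg.device_profile]
    n = profile.window_size
    fs = profile.sampling_rate_hz
    n_arcades = max(1, round(cfg.arcade_rate * n / fs))
    slot = n // n_arcades
    arc_len = max(8, int(round(cfg.arcade_duty * slot)))
    amp = _amplitude(cfg, improvement)

    # Build each arcade as a rectified half-sine, dips multiplied in later.
    arcades: list[np.ndarray] = []
    starts: list[int] = []
    for k in range(n_arcades):
        jitter = rng.integers(0, max(1, slot - arc_len))
        starts.append(k * slot + int(jitter))
        phase = (np.arange(arc_len) + 0.5) / arc_len
        arcades.append(amp * np.sin(np.pi * phase))

    # Candidate notch slots: disjoint interior stretches of each arcade, so
    # distinct injected artefacts remain distinct interior oscillations.
    width = max(3, int(round(cfg.notch_width_s * fs)))
    slots: list[tuple[int, int]] = []  # (arcade index, start sample)
    for a in range(n_arcades):
        lo, hi = int(0.35 * arc_len), int(0.65 * arc_len)
        for s in range((hi - lo) // width):
            slots.append((a, lo + s * width))
    n_notches = min(int(rng.poisson(cogwheel_rate(improvement))), len(slots))
    for pick in rng.permutation(len(slots))[:n_notches]:
        a, c = slots[pick]
        depth = rng.uniform(*cfg.notch_depth_range)
        k = np.arange(width)
        dip = depth * 0.5 * (1.0 - np.cos(2.0 * np.pi * (k + 0.5) / width))
        arcades[a][c : c + width] *= 1.0 - dip

    trace = np.zeros(n)
    for start, arc in zip(starts, arcades):
        trace[start : start + len(arc)] += arc
    return -trace, n_notches  # flexion is negative on y


def generate_session(config: SimulationConfig) -> SyntheticSession:
    """Generate a full session following the improvement schedule.

    Windows are emitted in schedule order; each window draws from its own
    deterministic substream of the session seed.
    """
    profile = PROFILES[config.device_profile]
    y_parts, x_parts, z_parts = [], [], []
    labels, notch_counts = [], []
    widx = 0
    for improvement, n_windows in config.improvement_schedule:
        for _ in range(n_windows):
            rng = np.random.default_rng([config.seed, widx])
            clean_y, n_notches = _make_window(config, improvement, rng)
            n = len(clean_y)
            y = clean_y + rng.normal(0.0, config.noise_sd, n)
            x = config.x_leak * clean_y + rng.normal(0.0, config.noise_sd, n)
            z = rng.normal(0.0, config.noise_sd, n)
            y_parts.append(y)
            x_parts.append(x)
            z_parts.append(z)
            labels.append(improvement)
            notch_counts.append(n_notches)
            widx += 1
    signal = AngularVelocitySignal(
        sampling_rate_hz=profile.sampling_rate_hz,
        omega_x=np.concatenate(x_parts),
        omega_y=np.concatenate(y_parts),
        omega_z=np.concatenate(z_parts),
    )
    return SyntheticSession(
        signal=signal,
        window_labels=np.asarray(labels, dtype=float),
        injected_cogwheel_counts=np.asarray(notch_counts, dtype=int),
        valid=np.ones(len(labels), dtype=bool),
        config=config,
    )


def _invert_quadratic(coef: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Descriptor abscissae where the truth quadratic hits each target label."""
    a, b, c = coef
    if a == 0.0:
        if b == 0.0:
            raise ValueError("degenerate truth polynomial")
        return (targets - c) / b
    disc = b**2 - 4.0 * a * (c - targets)
    if np.any(disc < 0):
        raise ValueError("truth quadratic cannot reach every class label")
    roots_plus = (-b + np.sqrt(disc)) / (2.0 * a)
    roots_minus = (-b - np.sqrt(disc)) / (2.0 * a)
    for roots in (roots_plus, roots_minus):
        d = np.diff(roots)
        if np.all(d > 0) or np.all(d < 0):
            return roots
    raise ValueError("no monotone branch covers the class labels")


def generate_labelled_windows(
    truth_coefficients,
    class_set,
    n_per_class: int,
    noise_sd: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw labelled descriptor values around a known truth quadratic.

    For each class label the noiseless descriptor abscissa is the point
    where the truth quadratic ``label = aφ² + bφ + c`` attains that label
    (monotone branch); values are that abscissa plus Gaussian noise.
    A warning is raised when the truth is non-monotone over the generated
    range (ambiguous classification regime).

    Returns ``(values, labels, valid)``.
    """
    import warnings

    coef = np.asarray(truth_coefficients, dtype=float)
    classes = np.asarray(sorted(class_set), dtype=float)
    centers = _invert_quadratic(coef, classes)
    rng = np.random.default_rng(seed)
    values = np.concatenate(
        [center + rng.normal(0.0, noise_sd, n_per_class) for center in centers]
    )
    a, b, _ = coef
    if a != 0.0:
        vertex = -b / (2.0 * a)
        if values.min() < vertex < values.max():
            warnings.warn(
                "truth quadratic is non-monotone over the generated descriptor "
                "range; classification regime is ambiguous",
                stacklevel=2,
            )
    labels = np.repeat(classes, n_per_class)
    return values, labels, np.ones(values.size, dtype=bool)
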