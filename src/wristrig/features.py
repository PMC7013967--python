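"""Per-window angular-velocity features: μω, μp and the cogwheel count δ.

Every rigidity descriptor is built from three window-level features of the
rectified flexion trace:

* ``mu_omega`` — mean flexion angular-velocity magnitude (°/s); non-smooth
  movement (plateaus, cogwheel interruptions) lowers it;
* ``mu_peak`` — mean of the flexion peak magnitudes (°/s), one or more per
  flexion arcade;
* ``delta`` — number of cogwheel-rigidity artefacts: ratchet-like interior
  oscillations within an arcade.

Peaks are the highest values between two valleys of the rectified signal
within a margin (default 0.2 °/s): a local maximum only counts if it rises
at least the margin above the preceding confirmed valley *and* drops at
least the margin to the following one, so sub-margin ripple never creates
additional peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from sklearn.base import BaseEstimator, TransformerMixin

from .signal import FlexionSamples, SignalWindow, extract_flexion_samples

__all__ = [
    "PeakSet",
    "WindowFeatures",
    "detect_peaks",
    "mean_angular_velocity",
    "mean_peak",
    "count_cogwheel_artefacts",
    "combine_axes",
    "window_features",
    "WindowFeatureExtractor",
]

DEFAULT_PEAK_MARGIN = 0.2
DEFAULT_DIP_THRESHOLD = 0.2


@dataclass(frozen=True)
class PeakSet:
    """Detected flexion peaks and the valleys that confirm them."""

    peak_values: np.ndarray
    peak_indices: np.ndarray
    valley_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.peak_values)


@dataclass(frozen=True)
class WindowFeatures:
    """The (μω, μp, δ) feature triple of one window on one axis/combination."""

    mu_omega: float
    mu_peak: float
    delta: int
    axis: str = "y"


def detect_peaks(
    magnitudes: npt.ArrayLike, margin: float = DEFAULT_PEAK_MARGIN
) -> PeakSet:
    """Hysteresis peak detection on a rectified (non-negative) sequence.

    A peak is confirmed once the signal has risen ``margin`` above the
    running minimum and subsequently fallen ``margin`` below the running
    maximum; sequence boundaries act as valleys.  Plateaus keep the first
    index of the extreme value.
    """
    x = np.asarray(magnitudes, dtype=float)
    peaks: list[int] = []
    valleys: list[int] = []
    if x.size == 0:
        return PeakSet(np.empty(0), np.empty(0, int), np.empty(0, int))

    mn, mn_pos = x[0], 0
    mx, mx_pos = x[0], 0
    look_for_max = False  # an initial rise of >= margin is required first
    for i in range(x.size):
        v = x[i]
        if look_for_max:
            if v > mx:
                mx, mx_pos = v, i
            elif v < mx - margin:
                peaks.append(mx_pos)
                mn, mn_pos = v, i
                look_for_max = False
        else:
            if v < mn:
                mn, mn_pos = v, i
            elif v > mn + margin:
                valleys.append(mn_pos)
                mx, mx_pos = v, i
                look_for_max = True
    if peaks and not look_for_max:
        valleys.append(mn_pos)  # trailing valley after the last confirmed peak
    peak_idx = np.asarray(peaks, dtype=int)
    return PeakSet(
        peak_values=x[peak_idx] if peak_idx.size else np.empty(0),
        peak_indices=peak_idx,
        valley_indices=np.asarray(valleys, dtype=int),
    )


def mean_angular_velocity(flexion_magnitudes: npt.ArrayLike) -> float:
    """Mean flexion angular-velocity magnitude μω; 0 for an empty window."""
    x = np.asarray(flexion_magnitudes, dtype=float)
    return float(x.mean()) if x.size else 0.0


def mean_peak(peaks: PeakSet) -> float:
    """Mean peak magnitude μp; 0 when no peak was confirmed."""
    return float(peaks.peak_values.mean()) if len(peaks) else 0.0


def count_cogwheel_artefacts(
    flexion: FlexionSamples,
    dip_threshold: float = DEFAULT_DIP_THRESHOLD,
) -> int:
    """Count cogwheel-rigidity artefacts δ over the arcades of a window.

    Within each flexion arcade, every interior oscillation — a local minimum
    rebounding by at least ``dip_threshold`` on both sides — counts as one
    artefact; equivalently, an arcade carrying ``k`` confirmed peaks at this
    threshold contributes ``k - 1`` artefacts.  Smooth single-peak arcades
    contribute none.
    """
    total = 0
    for sl in flexion.arcade_slices:
        peaks = detect_peaks(flexion.magnitudes[sl], margin=dip_threshold)
        if len(peaks) > 1:
            total += len(peaks) - 1
    return total


def combine_axes(
    omega: dict[str, npt.ArrayLike] | "object", axes: tuple[str, ...]
) -> np.ndarray:
    """Per-sample Euclidean norm over the selected axes, signed for flexion.

    Returns √(Σᵢ ωᵢ²) with the sign taken from the y-axis (flexion negative),
    so the combined trace flows through the same flexion extraction as a
    single-axis trace.
    """
    if not axes:
        raise ValueError("at least one axis is required")
    getter = omega.axis if hasattr(omega, "axis") else lambda a: omega[a]
    stack = np.vstack([np.asarray(getter(a), dtype=float) for a in axes])
    norm = np.sqrt((stack**2).sum(axis=0))
    sign_src = np.asarray(getter("y"), dtype=float)
    return np.where(sign_src < 0, -norm, norm)


#: Axis-combination names understood by the feature extractor.
AXIS_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "x": ("x",),
    "y": ("y",),
    "z": ("z",),
    "norm2": ("x", "y"),
    "norm3": ("x", "y", "z"),
}


def _axis_trace(window: SignalWindow, axis: str) -> np.ndarray:
    try:
        combo = AXIS_COMBINATIONS[axis]
    except KeyError:
        raise ValueError(
            f"unknown axis {axis!r}; expected one of {sorted(AXIS_COMBINATIONS)}"
        ) from None
    if len(combo) == 1:
        return window.axis(combo[0])
    return combine_axes(window, combo)


def window_features(
    window: SignalWindow,
    axis: str = "y",
    peak_margin: float = DEFAULT_PEAK_MARGIN,
    dip_threshold: float = DEFAULT_DIP_THRESHOLD,
) -> WindowFeatures:
    """Extract the (μω, μp, δ) triple from one window on one axis.

    Peak detection runs on the full-length rectified trace (zero outside
    flexion samples) so arcade boundaries act as zero valleys; μω averages
    the flexion samples only; δ is counted arcade by arcade.
    """
    trace = _axis_trace(window, axis)
    flexion = extract_flexion_samples(trace)
    rectified = np.zeros(len(trace))
    rectified[flexion.indices] = flexion.magnitudes
    peaks = detect_peaks(rectified, margin=peak_margin)
    return WindowFeatures(
        mu_omega=mean_angular_velocity(flexion.magnitudes),
        mu_peak=mean_peak(peaks),
        delta=count_cogwheel_artefacts(flexion, dip_threshold=dip_threshold),
        axis=axis,
    )


class WindowFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping signal windows to feature dictionaries.

    ``transform`` takes a sequence of :class:`~wristrig.signal.SignalWindow`
    and returns a list of ``{axis: WindowFeatures}`` dictionaries covering
    the requested axes/combinations, ready for descriptor computation in an
    sklearn pipeline.
    """

    def __init__(
        self,
        axes: tuple[str, ...] = ("y",),
        peak_margin: float = DEFAULT_PEAK_MARGIN,
        dip_threshold: float = DEFAULT_DIP_THRESHOLD,
    ):
        self.axes = axes
        self.peak_margin = peak_margin
        self.dip_threshold = dip_threshold

    def fit(self, X, y=None):  # noqa: D102 - stateless
        for axis in self.axes:
            if axis not in AXIS_COMBINATIONS:
                raise ValueError(f"unknown axis {axis!r}")
        return self

    def transform(self, X) -> list[dict[str, WindowFeatures]]:
        return [
            {
                axis: window_features(
                    w,
                    axis=axis,
                    peak_margin=self.peak_margin,
                    dip_threshold=self.dip_threshold,
                )
                for axis in self.axes
            }
            for w in X
        ]
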