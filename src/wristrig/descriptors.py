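"""The signal-descriptor catalogue mapping window features to scalars.

A descriptor φ condenses one window's features (μω, μp, δ — per axis where
needed) into a single scalar that is then calibrated against the medical
rigidity-improvement label.  The catalogue is closed: the base product
descriptor φy = μωy·μpy, its variants used by the multi-baseline model
(φI–φIV), the multi-axis forms (φnorm2, φnorm3, φxy, φxyz, φ̄), the
cogwheel-corrected forms (φ1–φ8) and the reduced-window production
descriptor φR ≡ φy.

Windows with no detected flexion (μω = 0) are short-circuited to 0 and
flagged unclassifiable; log-based forms fall back to 0 with a warning flag
for non-positive inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .features import WindowFeatures

__all__ = [
    "DescriptorSpec",
    "DescriptorValue",
    "DESCRIPTOR_NAMES",
    "compute_descriptor",
    "compute_descriptors",
    "DescriptorComputer",
]

#: Axes/combinations whose features each descriptor consumes.
_AXES_REQUIRED: dict[str, tuple[str, ...]] = {
    "phi_y": ("y",),
    "phi_I": ("y",),
    "phi_II": ("y",),
    "phi_III": ("y",),
    "phi_IV": ("y",),
    "phi_norm2": ("norm2",),
    "phi_norm3": ("norm3",),
    "phi_xy": ("x", "y"),
    "phi_xyz": ("x", "y", "z"),
    "phi_bar": ("x", "y", "z"),
    "phi_1": ("y",),
    "phi_2": ("y",),
    "phi_3": ("y",),
    "phi_4": ("y",),
    "phi_5": ("y",),
    "phi_6": ("y",),
    "phi_7": ("y",),
    "phi_8": ("y",),
    "phi_R": ("y",),
}

DESCRIPTOR_NAMES: tuple[str, ...] = tuple(_AXES_REQUIRED)


@dataclass(frozen=True)
class DescriptorSpec:
    """A named descriptor from the closed catalogue.

    ``sigma`` is the dimensionless width of the Gaussian ratio penalty and
    is consumed only by ``phi_IV``.
    """

    name: str
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in _AXES_REQUIRED:
            raise ValueError(
                f"unknown descriptor {self.name!r}; "
                f"catalogue: {', '.join(DESCRIPTOR_NAMES)}"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def axes_required(self) -> tuple[str, ...]:
        return _AXES_REQUIRED[self.name]


@dataclass(frozen=True)
class DescriptorValue:
    """A descriptor evaluation for one window."""

    spec: DescriptorSpec
    value: float
    window_index: int = 0
    valid: bool = True
    warning: str | None = field(default=None, compare=False)


def _phi(f: WindowFeatures) -> float:
    return f.mu_omega * f.mu_peak


def compute_descriptor(
    features: dict[str, WindowFeatures] | WindowFeatures,
    spec: DescriptorSpec,
    window_index: int = 0,
) -> DescriptorValue:
    """Evaluate one descriptor formula on one window's features.

    ``features`` maps axis/combination names to their feature triples; a
    bare :class:`WindowFeatures` is accepted for y-only descriptors.
    """
    if isinstance(features, WindowFeatures):
        features = {features.axis: features}
    missing = [a for a in spec.axes_required if a not in features]
    if missing:
        raise ValueError(f"descriptor {spec.name} requires axis features {missing}")

    def out(value: float, valid: bool = True, warning: str | None = None):
        return DescriptorValue(spec, float(value), window_index, valid, warning)

    primary = features[spec.axes_required[0] if spec.name.startswith("phi_norm") else "y"]
    # No detected flexion on the driving axis: the window is unclassifiable.
    if primary.mu_omega == 0.0:
        return out(0.0, valid=False, warning="no flexion detected (mu_omega = 0)")

    name = spec.name
    if name in ("phi_y", "phi_I", "phi_R"):
        return out(_phi(primary))
    if name == "phi_II":
        return out(min(primary.mu_omega, primary.mu_peak))
    if name == "phi_III":
        mw, mp = primary.mu_omega, primary.mu_peak
        if mw <= 0 or mp <= 0:
            return out(0.0, warning="non-positive input to log form")
        s = mw + mp
        return out(mw**2 * math.log2(s / mw) + mp**2 * math.log2(s / mp))
    if name == "phi_IV":
        mw, mp = primary.mu_omega, primary.mu_peak
        if mw <= 0 or mp <= 0:
            return out(0.0, warning="non-positive input to log form")
        return out(_phi(primary) * math.exp(-math.log(mp / mw) ** 2 / (2 * spec.sigma**2)))
    if name in ("phi_norm2", "phi_norm3"):
        return out(_phi(primary))
    if name in ("phi_xy", "phi_xyz", "phi_bar"):
        axes = {"phi_xy": ("x", "y"), "phi_xyz": ("x", "y", "z"), "phi_bar": ("x", "y", "z")}[name]
        mp_y = features["y"].mu_peak  # the printed forms pair every axis with μpy
        total = sum(features[a].mu_omega * mp_y for a in axes)
        return out(total / 3.0 if name == "phi_bar" else total)

    mw, mp, d = primary.mu_omega, primary.mu_peak, primary.delta
    phi = mw * mp
    table = {
        "phi_1": phi**2 - d,
        "phi_2": phi**2 + d,
        "phi_3": phi - d**2,
        "phi_4": phi + d**2,
        "phi_5": phi - d,
        "phi_6": phi + d,
        "phi_7": mw * (mp - d),
        "phi_8": mw * (mp + d),
    }
    return out(table[name])


def compute_descriptors(
    feature_dicts: list[dict[str, WindowFeatures]],
    spec: DescriptorSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a descriptor over many windows.

    Returns ``(values, valid)`` arrays aligned with the input windows.
    """
    results = [
        compute_descriptor(f, spec, window_index=i) for i, f in enumerate(feature_dicts)
    ]
    return (
        np.array([r.value for r in results]),
        np.array([r.valid for r in results], dtype=bool),
    )


class DescriptorComputer(TransformerMixin, BaseEstimator):
    """Transformer evaluating one catalogue descriptor per window.

    Consumes the feature dictionaries produced by
    :class:`~wristrig.features.WindowFeatureExtractor` and emits an
    ``(n_windows, 1)`` column of descriptor values (unclassifiable windows
    evaluate to 0), so it can sit between the feature extractor and the
    calibration regressor in a pipeline.
    """

    def __init__(self, name: str = "phi_R", sigma: float = 1.0):
        self.name = name
        self.sigma = sigma

    def _spec(self) -> DescriptorSpec:
        return DescriptorSpec(self.name, self.sigma)

    def fit(self, X, y=None):  # noqa: D102 - stateless
        self._spec()
        return self

    def transform(self, X) -> np.ndarray:
        values, _ = compute_descriptors(list(X), self._spec())
        return values.reshape(-1, 1)
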