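"""Quadratic calibration of a signal descriptor against rigidity improvement.

The calibration procedure: windows carry a medical label — the experts'
agreed rigidity-improvement percentage on a discrete decile scale — and a
descriptor value.  Valid windows are grouped by label, the per-class mean
descriptor is computed, and a second-order polynomial

    improvement% = a·φ² + b·φ + c

is least-squares fitted through the (mean descriptor, label) points.
Classification evaluates the quadratic at a new window's descriptor value
and clamps to [0, 80]; the output is deliberately continuous (a discrete
scale modelled by a continuous function), never snapped back to the decile
grid.  Training error is estimated by leave-one-out cross-validation, with
both an exhaustive mode (every window held out once) and a seeded
Monte-Carlo mode.

Two class sets are in use: the original full decile scale 0–80 % and the
later restricted set {0, 40, 50, 60, 70, 80} (intermediate improvements
below 40 % proved hard for examiners to discriminate).  A baseline-gated
variant keeps two calibrations — for low (UPDRS 1–2) and high (UPDRS 3)
baseline rigidity — selected by the pre-stimulation assessment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import numpy.typing as npt
from pydantic import BaseModel
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .descriptors import DESCRIPTOR_NAMES

__all__ = [
    "FULL_CLASS_SET",
    "RESTRICTED_CLASS_SET",
    "class_means",
    "fit_quadratic",
    "RigidityCalibration",
    "BaselineGatedCalibration",
    "loocv_training_error",
    "LoocvResult",
    "RigidityModelFile",
]

#: Original decile label scale (first calibration).
FULL_CLASS_SET: tuple[int, ...] = (0, 10, 20, 30, 40, 50, 60, 70, 80)
#: Restricted label scale used by the later calibrations.
RESTRICTED_CLASS_SET: tuple[int, ...] = (0, 40, 50, 60, 70, 80)

CLAMP_RANGE = (0.0, 80.0)


def class_means(
    values: npt.ArrayLike,
    labels: npt.ArrayLike,
    valid: npt.ArrayLike | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean descriptor value per medical-label class (valid windows only).

    Returns ``(class_labels, means)`` sorted by label.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape:
        raise ValueError("values and labels must align")
    mask = np.ones_like(x, dtype=bool) if valid is None else np.asarray(valid, bool)
    x, y = x[mask], y[mask]
    if x.size == 0:
        raise ValueError("no valid windows to average")
    classes = np.unique(y)
    means = np.array([x[y == c].mean() for c in classes])
    return classes, means


def fit_quadratic(
    mean_values: npt.ArrayLike, class_labels: npt.ArrayLike
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares quadratic through the (class-mean descriptor, label) points.

    Returns ``(coefficients (a, b, c), residuals per point)``.  Requires at
    least three distinct descriptor abscissae.
    """
    x = np.asarray(mean_values, dtype=float)
    y = np.asarray(class_labels, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("quadratic fit needs >= 3 distinct class-mean points")
    coef = np.polyfit(x, y, 2)
    return coef, np.polyval(coef, x) - y


class RigidityCalibration(RegressorMixin, BaseEstimator):
    """Quadratic class-mean calibration of descriptor vs improvement %.

    Parameters
    ----------
    class_set : tuple of int
        The admissible medical-label classes.  Labels outside the set are
        rejected at fit time.
    clamp : (float, float)
        Prediction range; evaluations outside are clipped.

    Attributes
    ----------
    coef_ : ndarray (3,)
        Quadratic coefficients ``(a, b, c)`` of improvement = aφ² + bφ + c.
    class_labels_, class_means_ : ndarray
        The per-class mean descriptor points the fit went through.
    residuals_ : ndarray
        Fit residual at each class-mean point (percentage points).
    """

    def __init__(
        self,
        class_set: Sequence[int] = RESTRICTED_CLASS_SET,
        clamp: tuple[float, float] = CLAMP_RANGE,
    ):
        self.class_set = class_set
        self.clamp = clamp

    def _validate_X(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("X must be a 1-d descriptor-value array or (n, 1) column")
        return x

    def fit(self, X, y, valid: npt.ArrayLike | None = None) -> "RigidityCalibration":
        x = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        unknown = set(np.unique(y)) - set(float(c) for c in self.class_set)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} outside class set {tuple(self.class_set)}")
        labels, means = class_means(x, y, valid)
        coef, resid = fit_quadratic(means, labels)
        self.class_labels_ = labels
        self.class_means_ = means
        self.coef_ = coef
        self.residuals_ = resid
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        x = self._validate_X(X)
        lo, hi = self.clamp
        return np.clip(np.polyval(self.coef_, x), lo, hi)

    def classify(self, descriptor_value: float, valid: bool = True) -> float | None:
        """Classify a single window; ``None`` for an unclassifiable window."""
        if not valid:
            return None
        return float(self.predict([descriptor_value])[0])


class BaselineGatedCalibration(BaseEstimator):
    """Two calibrations gated by the pre-stimulation baseline rigidity.

    The low-baseline model serves patients with rigidity UPDRS 1 or 2, the
    high-baseline model UPDRS 3.  UPDRS 4 has no calibration (no such
    patients were observed) and raises.
    """

    def __init__(
        self,
        class_set: Sequence[int] = RESTRICTED_CLASS_SET,
        clamp: tuple[float, float] = CLAMP_RANGE,
    ):
        self.class_set = class_set
        self.clamp = clamp

    def fit(self, X, y, baseline_updrs: npt.ArrayLike = None) -> "BaselineGatedCalibration":
        if baseline_updrs is None:
            raise ValueError("baseline_updrs is required to split the regimes")
        updrs = np.asarray(baseline_updrs, dtype=int)
        x = np.asarray(X, dtype=float).reshape(len(updrs), -1)
        y = np.asarray(y, dtype=float)
        low = np.isin(updrs, (1, 2))
        high = updrs == 3
        if not low.any() or not high.any():
            raise ValueError("both baseline regimes need training windows")
        self.low_model_ = RigidityCalibration(self.class_set, self.clamp).fit(x[low], y[low])
        self.high_model_ = RigidityCalibration(self.class_set, self.clamp).fit(x[high], y[high])
        return self

    def select_model(self, baseline_updrs: int) -> RigidityCalibration:
        check_is_fitted(self, "low_model_")
        if baseline_updrs in (1, 2):
            return self.low_model_
        if baseline_updrs == 3:
            return self.high_model_
        raise ValueError(
            f"unsupported baseline regime: UPDRS {baseline_updrs} "
            "(calibrations exist for UPDRS 1-2 and 3 only)"
        )

    def predict(self, X, baseline_updrs: int = 3) -> np.ndarray:
        return self.select_model(baseline_updrs).predict(X)


@dataclass(frozen=True)
class LoocvResult:
    """Leave-one-out training-error estimate in percentage points."""

    mean_error: float
    sd_error: float
    n_evaluated: int
    n_skipped: int
    mode: str


def loocv_training_error(
    values: npt.ArrayLike,
    labels: npt.ArrayLike,
    class_set: Sequence[int] = RESTRICTED_CLASS_SET,
    valid: npt.ArrayLike | None = None,
    mode: Literal["exhaustive", "monte-carlo"] = "exhaustive",
    iterations: int = 5000,
    seed: int | None = None,
    clamp: tuple[float, float] = CLAMP_RANGE,
) -> LoocvResult:
    """Leave-one-out cross-validated training error of the calibration.

    Each iteration holds out one valid window, recomputes the class means
    without it, refits the quadratic and records |prediction − label| at the
    held-out descriptor value.  ``exhaustive`` mode visits every valid
    window exactly once; ``monte-carlo`` mode draws ``iterations`` random
    holdouts from a seeded generator.  Iterations whose holdout collapses a
    class (leaving < 3 class-mean points) are skipped and counted.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    mask = np.ones_like(x, dtype=bool) if valid is None else np.asarray(valid, bool)
    idx_valid = np.flatnonzero(mask)
    if idx_valid.size < 2:
        raise ValueError("LOOCV needs at least two valid windows")

    if mode == "exhaustive":
        holdouts = idx_valid
    elif mode == "monte-carlo":
        rng = np.random.default_rng(seed)
        holdouts = rng.choice(idx_valid, size=iterations, replace=True)
    else:
        raise ValueError(f"unknown LOOCV mode {mode!r}")

    errors = []
    n_skipped = 0
    for i in holdouts:
        keep = mask.copy()
        keep[i] = False
        try:
            labels_k, means_k = class_means(x, y, keep)
            coef, _ = fit_quadratic(means_k, labels_k)
        except ValueError:
            n_skipped += 1
            continue
        pred = float(np.clip(np.polyval(coef, x[i]), *clamp))
        errors.append(abs(pred - y[i]))
    if not errors:
        raise ValueError("every LOOCV iteration collapsed a class")
    arr = np.asarray(errors)
    return LoocvResult(
        mean_error=float(arr.mean()),
        sd_error=float(arr.std(ddof=0)),
        n_evaluated=len(arr),
        n_skipped=n_skipped,
        mode=mode,
    )


class TrainingError(BaseModel):
    mean: float
    sd: float


class RigidityModelFile(BaseModel):
    """On-disk JSON schema of a fitted calibration."""

    descriptor: str
    coefficients: tuple[float, float, float]
    class_set: tuple[int, ...]
    baseline_regime: Literal["single", "low", "high"] = "single"
    window_size: int
    sampling_rate_hz: float
    sigma: float = 1.0
    training_error: TrainingError | None = None
    seed: int | None = None

    def model_post_init(self, __context) -> None:
        if self.descriptor not in DESCRIPTOR_NAMES:
            raise ValueError(f"unknown descriptor {self.descriptor!r}")

    @classmethod
    def from_estimator(
        cls,
        est: RigidityCalibration,
        descriptor: str,
        window_size: int,
        sampling_rate_hz: float,
        baseline_regime: str = "single",
        sigma: float = 1.0,
        training_error: LoocvResult | None = None,
        seed: int | None = None,
    ) -> "RigidityModelFile":
        check_is_fitted(est, "coef_")
        te = (
            TrainingError(mean=training_error.mean_error, sd=training_error.sd_error)
            if training_error
            else None
        )
        return cls(
            descriptor=descriptor,
            coefficients=tuple(float(c) for c in est.coef_),
            class_set=tuple(int(c) for c in est.class_labels_),
            baseline_regime=baseline_regime,
            window_size=window_size,
            sampling_rate_hz=sampling_rate_hz,
            sigma=sigma,
            training_error=te,
            seed=seed,
        )

    def to_estimator(self) -> RigidityCalibration:
        est = RigidityCalibration(class_set=self.class_set)
        est.coef_ = np.asarray(self.coefficients, dtype=float)
        est.class_labels_ = np.asarray(self.class_set, dtype=float)
        est.class_means_ = np.full(len(self.class_set), np.nan)
        est.residuals_ = np.full(len(self.class_set), np.nan)
        est.n_features_in_ = 1
        return est

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "RigidityModelFile":
        return cls.model_validate(json.loads(Path(path).read_text()))
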