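"""Intra-operative session workflow: metadata, training runs and streaming
classification of every complete window as it arrives.

Signal conditioning order is fixed: convert → low-pass filter → flexion
mask → window.  The best-improvement display considers valid windows only;
clinician-flagged invalid windows are logged but never drive the display.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .descriptors import DescriptorSpec, compute_descriptors
from .features import WindowFeatureExtractor, WindowFeatures
from .io import read_session_csv
from .model import (
    RigidityCalibration,
    RigidityModelFile,
    loocv_training_error,
)
from .profiles import PipelineConfig
from .signal import AngularVelocitySignal, moving_average_filter, window_stream

__all__ = [
    "StimulationRecord",
    "SessionMetadata",
    "filter_session",
    "windows_table",
    "run_classify_stream",
    "run_train",
]


class StimulationRecord(BaseModel):
    voltage: float
    depth: float | None = None
    site: str = ""
    kind: Literal["micro", "macro"] = "macro"
    note: str | None = None


class SessionMetadata(BaseModel):
    """Surgery bookkeeping recorded alongside the signal."""

    patient_id: str
    examiner: str | None = None
    rigidity_updrs: int = Field(ge=1, le=4)
    tremor_updrs: int | None = Field(default=None, ge=0)
    stimulations: list[StimulationRecord] = Field(default_factory=list)

    @staticmethod
    def best_improvement(log: pd.DataFrame) -> float | None:
        """Best improvement over the valid classified windows of a log."""
        ok = log[log["valid"]]
        return None if ok.empty else float(ok["prediction"].max())


def filter_session(
    signal: AngularVelocitySignal, width: int = 4
) -> AngularVelocitySignal:
    """Apply the moving-average low-pass filter to every axis."""
    return AngularVelocitySignal(
        sampling_rate_hz=signal.sampling_rate_hz,
        omega_x=moving_average_filter(signal.omega_x, width),
        omega_y=moving_average_filter(signal.omega_y, width),
        omega_z=moving_average_filter(signal.omega_z, width),
    )


def _required_axes(descriptor: str, sigma: float) -> tuple[str, ...]:
    return DescriptorSpec(descriptor, sigma).axes_required


def windows_table(
    signal: AngularVelocitySignal,
    labels: Sequence[float],
    config: PipelineConfig,
    valid: Sequence[bool] | None = None,
    axes: tuple[str, ...] = ("x", "y", "z"),
    baseline_updrs: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Build a labelled-window feature table from a session.

    One row per complete window with per-axis ``mu_omega_<axis>``,
    ``mu_peak_<axis>`` and ``delta_<axis>`` columns — the on-disk training
    format consumed by :func:`run_train`.
    """
    filtered = filter_session(signal, config.filter_width)
    windows, _ = window_stream(filtered, config.window_size)
    if len(windows) != len(labels):
        raise ValueError(
            f"{len(windows)} complete windows but {len(labels)} labels"
        )
    extractor = WindowFeatureExtractor(
        axes=axes, peak_margin=config.peak_margin, dip_threshold=config.dip_threshold
    ).fit([])
    feats = extractor.transform(windows)
    rows = []
    for i, d in enumerate(feats):
        row: dict = {"window_index": i, "label": labels[i]}
        row["valid"] = bool(valid[i]) if valid is not None else True
        if baseline_updrs is not None:
            row["baseline_updrs"] = int(baseline_updrs[i])
        for axis, f in d.items():
            row[f"mu_omega_{axis}"] = f.mu_omega
            row[f"mu_peak_{axis}"] = f.mu_peak
            row[f"delta_{axis}"] = f.delta
        rows.append(row)
    return pd.DataFrame(rows)


def _features_from_table(
    df: pd.DataFrame, axes: tuple[str, ...]
) -> list[dict[str, WindowFeatures]]:
    missing = [
        col
        for axis in axes
        for col in (f"mu_omega_{axis}", f"mu_peak_{axis}", f"delta_{axis}")
        if col not in df.columns
    ]
    if missing:
        raise ValueError(f"training table missing required columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            {
                axis: WindowFeatures(
                    mu_omega=float(row[f"mu_omega_{axis}"]),
                    mu_peak=float(row[f"mu_peak_{axis}"]),
                    delta=int(row[f"delta_{axis}"]),
                    axis=axis,
                )
                for axis in axes
            }
        )
    return out


def run_train(
    data: str | Path | pd.DataFrame,
    descriptor: str,
    class_set: Sequence[int],
    config: PipelineConfig | None = None,
    split_baseline: bool = False,
    sigma: float = 1.0,
    loocv_mode: Literal["exhaustive", "monte-carlo"] = "exhaustive",
    loocv_iterations: int = 5000,
    seed: int | None = None,
) -> dict[str, RigidityModelFile]:
    """Train calibration model(s) from a labelled-window feature table.

    Returns ``{"single": model}`` or, with ``split_baseline``,
    ``{"low": ..., "high": ...}`` keyed by baseline regime.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(data) if not isinstance(data, pd.DataFrame) else data
    for col in ("label", "valid"):
        if col not in df.columns:
            raise ValueError(f"training table missing required column {col!r}")
    axes = _required_axes(descriptor, sigma)
    feats = _features_from_table(df, axes)
    spec = DescriptorSpec(descriptor, sigma)
    values, feat_valid = compute_descriptors(feats, spec)
    valid = feat_valid & df["valid"].to_numpy(bool)
    labels = df["label"].to_numpy(float)

    def _fit(sel: np.ndarray, regime: str) -> RigidityModelFile:
        est = RigidityCalibration(class_set=tuple(class_set)).fit(
            values[sel], labels[sel], valid=valid[sel]
        )
        ok = sel & valid
        err = loocv_training_error(
            values[ok],
            labels[ok],
            class_set=tuple(class_set),
            mode=loocv_mode,
            iterations=loocv_iterations,
            seed=seed,
        )
        return RigidityModelFile.from_estimator(
            est,
            descriptor=descriptor,
            window_size=config.window_size,
            sampling_rate_hz=config.sampling_rate_hz,
            baseline_regime=regime,  # type: ignore[arg-type]
            sigma=sigma,
            training_error=err,
            seed=seed,
        )

    everything = np.ones(len(df), dtype=bool)
    if not split_baseline:
        return {"single": _fit(everything, "single")}
    if "baseline_updrs" not in df.columns:
        raise ValueError("baseline split requested but no baseline_updrs column")
    updrs = df["baseline_updrs"].to_numpy(int)
    return {
        "low": _fit(np.isin(updrs, (1, 2)), "low"),
        "high": _fit(updrs == 3, "high"),
    }


def run_classify_stream(
    session: str | Path | AngularVelocitySignal,
    model: RigidityModelFile,
    config: PipelineConfig | None = None,
    invalid_windows: Sequence[int] = (),
) -> pd.DataFrame:
    """Classify every complete window of a session, in arrival order.

    The log carries one row per window — descriptor value, clamped
    prediction, validity and the running best improvement over valid
    windows.  The model's acquisition profile must match the session's.
    """
    config = config or PipelineConfig()
    if (
        model.window_size != config.window_size
        or model.sampling_rate_hz != config.sampling_rate_hz
    ):
        raise ValueError(
            f"profile mismatch: model expects {model.window_size} samples @ "
            f"{model.sampling_rate_hz} Hz, session provides {config.window_size} "
            f"samples @ {config.sampling_rate_hz} Hz"
        )
    if not isinstance(session, AngularVelocitySignal):
        session = read_session_csv(session, sampling_rate_hz=config.sampling_rate_hz)
    filtered = filter_session(session, config.filter_width)
    windows, residual = window_stream(filtered, config.window_size)

    spec = DescriptorSpec(model.descriptor, model.sigma)
    extractor = WindowFeatureExtractor(
        axes=spec.axes_required,
        peak_margin=config.peak_margin,
        dip_threshold=config.dip_threshold,
    ).fit([])
    est = model.to_estimator()

    flagged = set(int(i) for i in invalid_windows)
    rows = []
    best = None
    values, feat_valid = compute_descriptors(extractor.transform(windows), spec)
    for i, (value, ok) in enumerate(zip(values, feat_valid)):
        ok = bool(ok) and i not in flagged
        pred = est.classify(float(value), valid=ok)
        if ok and (best is None or pred > best):
            best = pred
        rows.append(
            {
                "window_index": i,
                "descriptor_value": float(value),
                "prediction": pred if pred is not None else np.nan,
                "valid": ok,
                "best_so_far": best if best is not None else np.nan,
            }
        )
    log = pd.DataFrame(
        rows,
        columns=["window_index", "descriptor_value", "prediction", "valid", "best_so_far"],
    )
    log.attrs["residual_samples"] = residual
    return log
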