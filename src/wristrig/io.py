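"""CSV interchange: sessions, window labels, feature and descriptor tables.

Two session dialects are auto-detected from the header row:

* raw counts   — ``t,gx,gy,gz[,ax,ay,az]`` (signed 16-bit gyroscope counts,
  converted on read);
* pre-converted — ``t,wx,wy,wz`` (angular velocity in °/s, taken verbatim).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signal import AngularVelocitySignal, convert_raw_to_angular_velocity

__all__ = [
    "read_session_csv",
    "write_session_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_feature_table",
    "write_descriptor_table",
]

_RAW_COLS = ["t", "gx", "gy", "gz"]
_CONVERTED_COLS = ["t", "wx", "wy", "wz"]


def read_session_csv(path: str | Path, sampling_rate_hz: float) -> AngularVelocitySignal:
    """Read a session CSV in either dialect into an angular-velocity signal."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if all(c in cols for c in _RAW_COLS):
        if df["t"].diff().dropna().lt(0).any():
            raise ValueError("sample timestamps must be non-decreasing")
        x = convert_raw_to_angular_velocity(df["gx"].to_numpy())
        y = convert_raw_to_angular_velocity(df["gy"].to_numpy())
        z = convert_raw_to_angular_velocity(df["gz"].to_numpy())
    elif all(c in cols for c in _CONVERTED_COLS):
        x = df["wx"].to_numpy(float)
        y = df["wy"].to_numpy(float)
        z = df["wz"].to_numpy(float)
    else:
        raise ValueError(
            f"unrecognised session header {cols}; expected {_RAW_COLS} or {_CONVERTED_COLS}"
        )
    return AngularVelocitySignal(
        sampling_rate_hz=sampling_rate_hz, omega_x=x, omega_y=y, omega_z=z
    )


def write_session_csv(
    path: str | Path, signal: AngularVelocitySignal, decimals: int = 6
) -> None:
    """Write a session in the pre-converted dialect (°/s, fixed precision)."""
    n = len(signal)
    t = np.arange(n) / signal.sampling_rate_hz
    df = pd.DataFrame(
        {
            "t": np.round(t, decimals),
            "wx": np.round(signal.omega_x, decimals),
            "wy": np.round(signal.omega_y, decimals),
            "wz": np.round(signal.omega_z, decimals),
        }
    )
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")


def write_labels_csv(
    path: str | Path, labels, valid=None
) -> None:
    labels = np.asarray(labels)
    valid = np.ones(labels.size, dtype=bool) if valid is None else np.asarray(valid, bool)
    pd.DataFrame(
        {"window_index": np.arange(labels.size), "label": labels, "valid": valid}
    ).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"window_index", "label", "valid"}
    if not required.issubset(df.columns):
        raise ValueError(f"labels CSV must have columns {sorted(required)}")
    return df


def write_feature_table(path: str | Path, feature_dicts: list[dict]) -> None:
    """Feature table: one row per (window, axis) with the μω/μp/δ triple."""
    rows = [
        {
            "window_index": i,
            "axis": axis,
            "mu_omega": f.mu_omega,
            "mu_peak": f.mu_peak,
            "delta": f.delta,
        }
        for i, d in enumerate(feature_dicts)
        for axis, f in d.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_descriptor_table(path: str | Path, values, descriptor: str) -> None:
    values = np.asarray(values, dtype=float)
    pd.DataFrame(
        {
            "window_index": np.arange(values.size),
            "descriptor": descriptor,
            "value": values,
        }
    ).to_csv(path, index=False)
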