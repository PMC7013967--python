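"""Device acquisition profiles and run-time configuration.

Two generations of the palm-worn IMU are supported: the original unit
sampling at 42 Hz with 300-sample feature windows, and the revised unit
sampling at 50 Hz with 200-sample windows (a 200-sample window then spans
exactly 4 s of passive wrist flexion).
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, model_validator

#: Gyroscope full-scale range in degrees per second.
GYRO_FULL_SCALE_DPS = 2000.0

#: Raw register full-scale count (2**15).
RAW_FULL_SCALE = 32768


class DeviceProfile(BaseModel):
    """Acquisition parameters of one hardware generation."""

    name: str
    sampling_rate_hz: float = Field(gt=0)
    window_size: int = Field(gt=0)

    @property
    def window_seconds(self) -> float:
        return self.window_size / self.sampling_rate_hz

    model_config = {"frozen": True}


#: First-generation unit: 42 Hz, 300-sample windows.
PROFILE_V1 = DeviceProfile(name="v1", sampling_rate_hz=42.0, window_size=300)

#: Second-generation unit: 50 Hz, 200-sample (4 s) windows.
PROFILE_V2 = DeviceProfile(name="v2", sampling_rate_hz=50.0, window_size=200)

PROFILES: dict[str, DeviceProfile] = {"v1": PROFILE_V1, "v2": PROFILE_V2}


class PipelineConfig(BaseModel):
    """Signal-conditioning configuration, serialisable to JSON or TOML.

    ``peak_margin`` is the minimum rise-and-fall a local maximum must show
    over its flanking valleys to count as a flexion peak (°/s);
    ``dip_threshold`` plays the same role for cogwheel-artefact dips.
    """

    device_profile: Literal["v1", "v2"] = "v2"
    sampling_rate_hz: float | None = None
    window_size: int | None = None
    filter_width: int = Field(default=4, ge=1)
    peak_margin: float = Field(default=0.2, gt=0)
    dip_threshold: float = Field(default=0.2, gt=0)

    @model_validator(mode="after")
    def _fill_from_profile(self) -> "PipelineConfig":
        profile = PROFILES[self.device_profile]
        if self.sampling_rate_hz is None:
            object.__setattr__(self, "sampling_rate_hz", profile.sampling_rate_hz)
        if self.window_size is None:
            object.__setattr__(self, "window_size", profile.window_size)
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls.model_validate(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
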