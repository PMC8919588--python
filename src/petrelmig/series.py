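"""Validated containers for raw geolocator (GLS) series and deployment metadata.

Tags sample light every minute and store the maximum per 10-minute interval;
immersion is tested every few seconds and stored as the count of wet tests
per 10-minute interval. Two tag families are supported:

* ``low-range`` (MK15-style): clipped light scale, immersion counts 0–200,
  light threshold 4 for twilight detection, interference below 64.
* ``full-range`` (Intigeo-style): full light scale, immersion counts 0–20,
  light threshold 1, interference below 100.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_MINUTES = 10
INTERVALS_PER_DAY = 144


class TagModel(str, enum.Enum):
    LOW_RANGE = "low-range"
    FULL_RANGE = "full-range"

    @property
    def light_threshold(self) -> float:
        return 4.0 if self is TagModel.LOW_RANGE else 1.0

    @property
    def interference_threshold(self) -> float:
        return 64.0 if self is TagModel.LOW_RANGE else 100.0

    @property
    def max_wet_per_interval(self) -> int:
        return 200 if self is TagModel.LOW_RANGE else 20


class ValidationError(ValueError):
    """Raised when a series violates its type invariants."""


def _check_timestamps(ts: pd.DatetimeIndex, what: str) -> list[str]:
    gaps: list[str] = []
    if ts.tz is None:
        raise ValidationError(f"{what}: timestamps must be timezone-aware UTC")
    diffs = ts.to_series().diff().dropna()
    dup = diffs[diffs <= pd.Timedelta(0)]
    if len(dup):
        raise ValidationError(
            f"{what}: timestamps not strictly increasing at {dup.index[0].isoformat()}"
        )
    step = pd.Timedelta(minutes=INTERVAL_MINUTES)
    for t, d in diffs[diffs != step].items():
        gaps.append(f"gap of {d} before {t.isoformat()}")
    return gaps


@dataclass
class LightSeries:
    """Max light per 10-minute interval."""

    timestamps: pd.DatetimeIndex
    light: np.ndarray
    tag_model: TagModel = TagModel.FULL_RANGE
    gaps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.light = np.asarray(self.light, dtype=float)
        if len(self.timestamps) != len(self.light):
            raise ValidationError("light: timestamps and values differ in length")
        self.gaps = _check_timestamps(self.timestamps, "light") + list(self.gaps)
        if np.any(self.light < 0):
            k = int(np.argmax(self.light < 0))
            raise ValidationError(f"light: negative value at {self.timestamps[k].isoformat()}")

    def __len__(self) -> int:
        return len(self.light)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "light": self.light})


@dataclass
class ImmersionSeries:
    """Count of wet tests per 10-minute interval (0 = dry, max = entirely wet)."""

    timestamps: pd.DatetimeIndex
    wet_count: np.ndarray
    tag_model: TagModel = TagModel.FULL_RANGE
    gaps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.wet_count = np.asarray(self.wet_count, dtype=int)
        if len(self.timestamps) != len(self.wet_count):
            raise ValidationError("immersion: timestamps and values differ in length")
        self.gaps = _check_timestamps(self.timestamps, "immersion") + list(self.gaps)
        cap = self.tag_model.max_wet_per_interval
        bad = (self.wet_count < 0) | (self.wet_count > cap)
        if np.any(bad):
            k = int(np.argmax(bad))
            raise ValidationError(
                f"immersion: wet_count {self.wet_count[k]} outside [0, {cap}] "
                f"at {self.timestamps[k].isoformat()} for {self.tag_model.value} tag"
            )

    def __len__(self) -> int:
        return len(self.wet_count)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "wet_count": self.wet_count})


@dataclass
class SSTLog:
    """Sea-surface temperatures recorded by the tag while wet (°C)."""

    timestamps: pd.DatetimeIndex
    temp_C: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        if len(self.timestamps) != len(self.temp_C):
            raise ValidationError("sst: timestamps and values differ in length")
        if len(self.timestamps) and self.timestamps.tz is None:
            raise ValidationError("sst: timestamps must be timezone-aware UTC")
        ok = (self.temp_C >= -2.0) & (self.temp_C <= 40.0)
        if not np.all(ok):
            k = int(np.argmax(~ok))
            raise ValidationError(
                f"sst: temperature {self.temp_C[k]:.2f} °C outside [-2, 40] "
                f"at {self.timestamps[k].isoformat()}"
            )

    def __len__(self) -> int:
        return len(self.temp_C)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "temp_C": self.temp_C})


@dataclass
class Deployment:
    """Metadata for one tag deployment on one individual."""

    individual_id: str
    tag_id: str
    colony_lon: float
    colony_lat: float
    calibration_start: pd.Timestamp
    calibration_end: pd.Timestamp
    deploy_date: pd.Timestamp | None = None
    retrieve_date: pd.Timestamp | None = None
    tag_model: TagModel = TagModel.FULL_RANGE

    def __post_init__(self) -> None:
        if not (-180.0 <= self.colony_lon < 180.0):
            raise ValidationError(f"colony longitude out of range: {self.colony_lon}")
        if not (-90.0 <= self.colony_lat <= 90.0):
            raise ValidationError(f"colony latitude out of range: {self.colony_lat}")
        self.calibration_start = pd.Timestamp(self.calibration_start)
        self.calibration_end = pd.Timestamp(self.calibration_end)
        ndays = (self.calibration_end - self.calibration_start).days
        if not 3 <= ndays <= 5:
            raise ValidationError(
                f"calibration window must span 3-5 days, got {ndays} "
                f"({self.calibration_start.date()} to {self.calibration_end.date()})"
            )
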