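"""Reading and writing the text formats used throughout the pipeline.

Logger files are plain delimited text with one row per 10-minute interval
(ISO-8601 UTC timestamp, value). Deployment metadata is a YAML mapping.
Tracks, phenology tables and comparison tables are CSV.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from petrelmig.series import (
    Deployment,
    ImmersionSeries,
    LightSeries,
    SSTLog,
    TagModel,
    ValidationError,
)


class ParseError(ValueError):
    """Raised when a logger file cannot be parsed."""


def _read_two_column(path, value_name: str) -> pd.DataFrame:
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "timestamp" not in df.columns or value_name not in df.columns:
        raise ParseError(f"{path}: expected columns 'timestamp' and '{value_name}'")
    try:
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        bad = None
        for i, raw in enumerate(df["timestamp"]):
            try:
                pd.to_datetime(raw, utc=True)
            except (ValueError, TypeError):
                bad = i
                break
        raise ParseError(f"{path}: malformed timestamp at row {bad}: {df['timestamp'].iloc[bad]!r}") from exc
    df["timestamp"] = ts
    return df


def read_light(path, tag_model: TagModel | str = TagModel.FULL_RANGE) -> LightSeries:
    tag_model = TagModel(tag_model)
    df = _read_two_column(path, "light")
    return LightSeries(pd.DatetimeIndex(df["timestamp"]), df["light"].to_numpy(), tag_model)


def read_immersion(path, tag_model: TagModel | str = TagModel.FULL_RANGE) -> ImmersionSeries:
    tag_model = TagModel(tag_model)
    df = _read_two_column(path, "wet_count")
    return ImmersionSeries(pd.DatetimeIndex(df["timestamp"]), df["wet_count"].to_numpy(), tag_model)


def read_sst(path) -> SSTLog:
    df = _read_two_column(path, "temp_C")
    return SSTLog(pd.DatetimeIndex(df["timestamp"]), df["temp_C"].to_numpy())


def read_logger_files(
    light_path, immersion_path, sst_path, tag_model: TagModel | str
) -> tuple[LightSeries, ImmersionSeries, SSTLog]:
    """Read the three raw logger files of one deployment, validating invariants."""
    tag_model = TagModel(tag_model)
    return (
        read_light(light_path, tag_model),
        read_immersion(immersion_path, tag_model),
        read_sst(sst_path),
    )


def write_series(series, path) -> None:
    """Write any raw series (Light/Immersion/SST) in its logger-file schema."""
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].map(lambda t: t.strftime("%Y-%m-%dT%H:%M:%SZ"))
    df.to_csv(path, index=False)


def read_deployment(path) -> Deployment:
    """Read deployment metadata from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return Deployment(
            individual_id=str(raw["individual_id"]),
            tag_id=str(raw["tag_id"]),
            colony_lon=float(raw["colony_lon"]),
            colony_lat=float(raw["colony_lat"]),
            calibration_start=pd.Timestamp(raw["calibration_start"]),
            calibration_end=pd.Timestamp(raw["calibration_end"]),
            deploy_date=pd.Timestamp(raw["deploy_date"]) if raw.get("deploy_date") else None,
            retrieve_date=pd.Timestamp(raw["retrieve_date"]) if raw.get("retrieve_date") else None,
            tag_model=TagModel(raw.get("tag_model", "full-range")),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing deployment field {exc}") from exc


def write_deployment(dep: Deployment, path) -> None:
    data = {
        "individual_id": dep.individual_id,
        "tag_id": dep.tag_id,
        "colony_lon": dep.colony_lon,
        "colony_lat": dep.colony_lat,
        "calibration_start": str(dep.calibration_start),
        "calibration_end": str(dep.calibration_end),
        "deploy_date": str(dep.deploy_date) if dep.deploy_date is not None else None,
        "retrieve_date": str(dep.retrieve_date) if dep.retrieve_date is not None else None,
        "tag_model": dep.tag_model.value,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


TRACK_COLUMNS = [
    "individual_id",
    "year",
    "epoch",
    "lon_med",
    "lat_med",
    "lon_lo",
    "lon_hi",
    "lat_lo",
    "lat_hi",
]


def write_track(track: pd.DataFrame, path) -> None:
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise ValidationError(f"track table missing columns: {missing}")
    out = track.copy()
    out["epoch"] = pd.to_datetime(out["epoch"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out[TRACK_COLUMNS].to_csv(path, index=False)


def read_track(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["epoch"] = pd.to_datetime(df["epoch"], utc=True)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df).to_csv(path, index=False)


def read_table(path, parse_dates: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in parse_dates or []:
        df[c] = pd.to_datetime(df[c])
    return df
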