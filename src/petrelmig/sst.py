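"""Gridded sea-surface-temperature field: weekly means on a 1.0° × 1.0° grid.

The field plays the role of a remotely sensed SST climatology against which
tag-recorded temperatures are matched during track refinement. A synthetic
generator produces a smooth field with the dominant real-ocean structure —
a meridional (poleward-cooling) gradient, a seasonal cycle of opposite phase
in the two hemispheres, and a weak zonal harmonic — on the same grid layout
(week × lat × lon).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class SSTField:
    """Weekly 1°×1° SST grids with bilinear spatial / nearest-week interpolation."""

    def __init__(self, lons: np.ndarray, lats: np.ndarray, values: np.ndarray):
        self.lons = np.asarray(lons, dtype=float)
        self.lats = np.asarray(lats, dtype=float)
        self.values = np.asarray(values, dtype=float)  # (52, nlat, nlon)
        if self.values.shape != (52, len(self.lats), len(self.lons)):
            raise ValueError(
                f"values shape {self.values.shape} != (52, {len(self.lats)}, {len(self.lons)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SST field contains non-finite values")

    @staticmethod
    def week_of(times) -> np.ndarray:
        """Week index 0..51 (day-of-year // 7, capped)."""
        doy = pd.to_datetime(times).dayofyear if hasattr(times, "__iter__") else pd.Timestamp(times).dayofyear
        return np.minimum(np.asarray(doy, dtype=int) - 1, 363) // 7

    def value_at(self, lon, lat, times) -> np.ndarray:
        """SST (°C) bilinearly interpolated in space, nearest in week."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        week = np.atleast_1d(self.week_of(times))
        lon, lat, week = np.broadcast_arrays(lon, lat, week)
        fx = np.clip((lon - self.lons[0]) / (self.lons[1] - self.lons[0]), 0, len(self.lons) - 1.001)
        fy = np.clip((lat - self.lats[0]) / (self.lats[1] - self.lats[0]), 0, len(self.lats) - 1.001)
        ix = fx.astype(int)
        iy = fy.astype(int)
        tx = fx - ix
        ty = fy - iy
        v = self.values
        w = week
        out = (
            v[w, iy, ix] * (1 - tx) * (1 - ty)
            + v[w, iy, ix + 1] * tx * (1 - ty)
            + v[w, iy + 1, ix] * (1 - tx) * ty
            + v[w, iy + 1, ix + 1] * tx * ty
        )
        return out if out.shape != (1,) else out

    def to_frame(self) -> pd.DataFrame:
        """Long-format (lon, lat, week, temp_C) table."""
        ww, yy, xx = np.meshgrid(np.arange(52), self.lats, self.lons, indexing="ij")
        return pd.DataFrame(
            {"week": ww.ravel(), "lat": yy.ravel(), "lon": xx.ravel(), "temp_C": self.values.ravel()}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SSTField":
        lons = np.sort(df["lon"].unique())
        lats = np.sort(df["lat"].unique())
        piv = df.sort_values(["week", "lat", "lon"])
        values = piv["temp_C"].to_numpy().reshape(52, len(lats), len(lons))
        return cls(lons, lats, values)


def synthetic_sst_field(
    lon_min: float = 20.0,
    lon_max: float = 120.0,
    lat_min: float = -45.0,
    lat_max: float = 30.0,
    t_warm: float = 29.0,
    lat_peak: float = 10.0,
    meridional_scale: float = 55.0,
    seasonal_amp: float = 2.0,
    zonal_amp: float = 0.6,
    asym_per_deg: float = 0.12,
) -> SSTField:
    """Smooth synthetic SST field for the Indian Ocean window.

    T(lon, lat, week) = t_warm − 16·((lat − lat_peak)/meridional_scale)²
    + asym_per_deg·lat + seasonal cycle of opposite phase across the equator
    + weak zonal wave. The meridional profile is nearly flat through the
    tropics and steepens toward the southern subtropics, as in the real
    basin (where SST carries little latitude information near the equator
    and a lot in the south); the weak linear term keeps the enclosed
    northern basins warmer than the open southern subtropics at equal |lat|.
    """
    lons = np.arange(lon_min, lon_max + 0.5, 1.0)
    lats = np.arange(lat_min, lat_max + 0.5, 1.0)
    weeks = np.arange(52)
    W, Y, X = np.meshgrid(weeks, lats, lons, indexing="ij")
    base = t_warm - 16.0 * ((Y - lat_peak) / meridional_scale) ** 2 + asym_per_deg * Y
    phase = np.cos(2 * np.pi * (W / 52.0 - 0.08))  # warmest late Jan (southern summer)
    hemis = np.tanh((lat_peak - Y) / 10.0)  # +1 south of the thermal equator
    seasonal = seasonal_amp * phase * hemis
    zonal = zonal_amp * np.sin(np.deg2rad(3.0 * X))
    values = np.clip(base + seasonal + zonal, -1.9, 35.0)
    return SSTField(lons, lats, values)
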