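"""Solar ephemeris for threshold geolocation.

Implements the standard low-precision solar position algorithm (geometric
mean longitude / anomaly, equation of centre, apparent longitude, corrected
obliquity) as used by the NOAA solar calculator: declination and equation of
time accurate to well under 0.01° / a few seconds over 1950–2050, which is
far below geolocator light-curve noise.

A *twilight* here is the time the sun crosses a configurable zenith angle
(90.833° = standard sunrise/sunset with refraction; calibrated tags use
94–99°). All times are UTC; longitudes positive east in [-180, 180).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_J2000 = np.datetime64("2000-01-01T12:00:00")
_MIN_PER_DAY = 1440.0


def _julian_centuries(times: np.ndarray) -> np.ndarray:
    dt_days = (times - _J2000) / np.timedelta64(1, "D")
    return dt_days / 36525.0


def solar_coefficients(times) -> tuple[np.ndarray, np.ndarray]:
    """Solar declination (degrees) and equation of time (minutes) at UTC `times`.

    Vectorised over any array-like of datetimes.
    """
    times = np.asarray(pd.to_datetime(times, utc=True).tz_localize(None).to_numpy()
                       if not isinstance(times, np.ndarray) else times,
                       dtype="datetime64[s]")
    T = _julian_centuries(times)
    L0 = np.mod(280.46646 + T * (36000.76983 + T * 0.0003032), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = np.deg2rad(M)
    C = (
        np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + np.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.deg2rad(omega))
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.8150 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(np.deg2rad(omega))
    epsr = np.deg2rad(eps)
    decl = np.rad2deg(np.arcsin(np.sin(epsr) * np.sin(np.deg2rad(app_long))))
    y = np.tan(epsr / 2.0) ** 2
    L0r = np.deg2rad(L0)
    eqtime = 4.0 * np.rad2deg(
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(Mr)
        + 4.0 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * Mr)
    )
    return decl, eqtime


def zenith_angle(lon, lat, times) -> np.ndarray:
    """Solar zenith angle (degrees) at positions and UTC times (broadcast)."""
    times = pd.to_datetime(times, utc=True)
    tarr = np.asarray(times.tz_localize(None).to_numpy() if hasattr(times, "tz_localize")
                      else times, dtype="datetime64[s]")
    decl, eqtime = solar_coefficients(tarr)
    minutes = (
        (tarr - tarr.astype("datetime64[D]")).astype("timedelta64[s]").astype(float) / 60.0
    )
    tst = np.mod(minutes + eqtime + 4.0 * np.asarray(lon, dtype=float), _MIN_PER_DAY)
    ha = tst / 4.0 - 180.0
    latr = np.deg2rad(np.asarray(lat, dtype=float))
    declr = np.deg2rad(decl)
    cosz = np.sin(latr) * np.sin(declr) + np.cos(latr) * np.cos(declr) * np.cos(np.deg2rad(ha))
    return np.rad2deg(np.arccos(np.clip(cosz, -1.0, 1.0)))


def hour_angle_deg(lat, decl, zenith) -> np.ndarray:
    """Hour angle (degrees) at which the sun reaches `zenith`; NaN if never crossed."""
    latr = np.deg2rad(np.asarray(lat, dtype=float))
    declr = np.deg2rad(np.asarray(decl, dtype=float))
    zr = np.deg2rad(np.asarray(zenith, dtype=float))
    cos_ha = (np.cos(zr) - np.sin(latr) * np.sin(declr)) / (np.cos(latr) * np.cos(declr))
    with np.errstate(invalid="ignore"):
        ha = np.rad2deg(np.arccos(cos_ha))
    return np.where(np.abs(cos_ha) <= 1.0, ha, np.nan)


def twilight_time(lon, lat, date, zenith, kind, n_iter: int = 3):
    """UTC time the sun crosses `zenith` on `date` at (lon, lat).

    kind is 'sunrise' (morning, descending zenith) or 'sunset'. Vectorised;
    elements where the sun never reaches the zenith (polar day/night for
    that zenith) are NaT.
    """
    if kind not in ("sunrise", "sunset"):
        raise ValueError(f"kind must be 'sunrise' or 'sunset', got {kind!r}")
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    dates = pd.to_datetime(np.atleast_1d(np.asarray(date)))
    day0 = np.asarray(dates, dtype="datetime64[D]").astype("datetime64[s]")
    lon, lat, day0 = np.broadcast_arrays(lon, lat, day0)
    # initial guess: local solar noon, then fixed-point refinement
    minutes = np.full(lon.shape, 720.0) - 4.0 * lon
    for _ in range(n_iter):
        t_guess = day0 + (minutes * 60.0).astype("timedelta64[s]")
        decl, eqtime = solar_coefficients(t_guess)
        ha = hour_angle_deg(lat, decl, zenith)
        sign = -1.0 if kind == "sunrise" else 1.0
        minutes = 720.0 - 4.0 * lon - eqtime + sign * 4.0 * ha
    out = day0 + np.where(
        np.isnan(minutes), np.timedelta64("NaT", "s"), (np.nan_to_num(minutes) * 60.0).round().astype("int64").astype("timedelta64[s]")
    )
    out = np.where(np.isnan(minutes), np.datetime64("NaT", "s"), out)
    if out.shape == (1,):
        t = out[0]
        return None if np.isnat(t) else pd.Timestamp(t, tz="UTC")
    return out


def twilight_minutes_utc(lon, lat, day0, decl, eqtime, zenith, kind_sign) -> np.ndarray:
    """Fast path used by the MCMC likelihood: minutes after UTC midnight of the
    zenith crossing, given precomputed per-day declination and equation of time.

    `kind_sign` is -1 for sunrise, +1 for sunset. Returns NaN where no crossing.
    """
    ha = hour_angle_deg(lat, decl, zenith)
    return 720.0 - 4.0 * lon - eqtime + kind_sign * 4.0 * ha


def day_length_hours(lat, decl, zenith) -> np.ndarray:
    """Time (hours) the sun spends above `zenith`."""
    return 2.0 * hour_angle_deg(lat, decl, zenith) / 15.0
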