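"""Daily behavioural features for ashore/at-sea classification.

Three features per calendar day, chosen because a petrel frequenting the
colony (1) shades the tag while sitting, (2) stays dry, and (3) stays close
to the colony:

* **light interference** — count of daylight light samples below the tag's
  interference threshold, out of the day's daylight samples (the daylight
  window is that day's detected twilights shrunk by a 30-min margin);
* **wet sum** — total immersion count over the day's 144 10-min intervals;
* **colony distance** — WGS84 geodesic distance (km) from the day's mean
  median position to the colony.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from petrelmig.series import ImmersionSeries, LightSeries
from petrelmig.twilight import TwilightSeries

DAYLIGHT_MARGIN_MIN = 30.0

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_B = _A * (1.0 - _F)


def geodesic_km(lon1, lat1, lon2, lat2, tol: float = 1e-12, max_iter: int = 200):
    """WGS84 geodesic distance (Vincenty inverse formula), km.

    Falls back to a spherical great-circle value for the rare non-converging
    near-antipodal pairs.
    """
    lon1, lat1, lon2, lat2 = (np.atleast_1d(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    lon1, lat1, lon2, lat2 = np.broadcast_arrays(lon1, lat1, lon2, lat2)
    U1 = np.arctan((1 - _F) * np.tan(np.deg2rad(lat1)))
    U2 = np.arctan((1 - _F) * np.tan(np.deg2rad(lat2)))
    L = np.deg2rad(lon2 - lon1)
    lam = L.copy()
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)
    converged = np.zeros(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            sin_alpha = np.where(sin_sigma > 0, cosU1 * cosU2 * sin_lam / np.maximum(sin_sigma, 1e-300), 0.0)
        cos_sq_alpha = 1.0 - sin_alpha**2
        with np.errstate(invalid="ignore", divide="ignore"):
            cos2sm = np.where(
                cos_sq_alpha > 0, cos_sigma - 2.0 * sinU1 * sinU2 / np.maximum(cos_sq_alpha, 1e-300), 0.0
            )
        Cc = _F / 16.0 * cos_sq_alpha * (4.0 + _F * (4.0 - 3.0 * cos_sq_alpha))
        lam_new = L + (1.0 - Cc) * _F * sin_alpha * (
            sigma + Cc * sin_sigma * (cos2sm + Cc * cos_sigma * (-1.0 + 2.0 * cos2sm**2))
        )
        delta = np.abs(lam_new - lam)
        lam = lam_new
        converged = delta < tol
        if converged.all():
            break
    u_sq = cos_sq_alpha * (_A**2 - _B**2) / _B**2
    Aa = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    Bb = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = Bb * sin_sigma * (
        cos2sm
        + Bb / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos2sm**2)
            - Bb / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos2sm**2)
        )
    )
    dist = _B * Aa * (sigma - delta_sigma) / 1000.0
    coincident = (np.abs(lat1 - lat2) < 1e-12) & (np.abs(lon1 - lon2) < 1e-12)
    dist = np.where(coincident, 0.0, dist)
    if not converged.all():
        from petrelmig.emd import haversine_km

        bad = ~converged & ~coincident
        dist = np.where(bad, haversine_km(lon1, lat1, lon2, lat2), dist)
    return float(dist[0]) if dist.size == 1 else dist


def daily_features(
    light: LightSeries,
    immersion: ImmersionSeries,
    track: pd.DataFrame,
    colony_lon: float,
    colony_lat: float,
    twilights: TwilightSeries,
    interference_threshold: float | None = None,
) -> pd.DataFrame:
    """One row per calendar day: interference, wet sum, colony distance.

    Days without a detected twilight pair get missing interference (row
    retained); days without positions get missing distance.
    """
    if interference_threshold is None:
        interference_threshold = light.tag_model.interference_threshold

    dates = pd.date_range(
        light.timestamps[0].normalize(), light.timestamps[-1].normalize(), freq="D"
    )
    # daylight window per day from the twilight series
    sr: dict[pd.Timestamp, pd.Timestamp] = {}
    ss: dict[pd.Timestamp, pd.Timestamp] = {}
    for t, k in zip(twilights.times, twilights.kinds):
        d = t.normalize()
        if k == "sunrise":
            sr.setdefault(d, t)
        else:
            ss[d] = t

    lt = light.timestamps
    lv = light.light
    margin = pd.Timedelta(minutes=DAYLIGHT_MARGIN_MIN)

    imm = immersion.to_frame()
    imm["date"] = imm["timestamp"].dt.normalize()
    wet = imm.groupby("date")["wet_count"].sum()

    trk = track.copy()
    trk["epoch"] = pd.to_datetime(trk["epoch"], utc=True)
    trk["date"] = trk["epoch"].dt.normalize()
    pos = trk.groupby("date")[["lon_med", "lat_med"]].mean()

    rows = []
    for d in dates:
        t0 = sr.get(d)
        t1 = ss.get(d)
        if t0 is not None and t1 is not None and t1 > t0:
            w0, w1 = t0 + margin, t1 - margin
            sel = (lt >= w0) & (lt < w1)
            n_day = int(sel.sum())
            n_int = int((lv[sel] < interference_threshold).sum()) if n_day else None
        else:
            n_day, n_int = None, None
        if d in pos.index:
            dist = geodesic_km(pos.loc[d, "lon_med"], pos.loc[d, "lat_med"], colony_lon, colony_lat)
        else:
            dist = np.nan
        rows.append(
            {
                "date": d,
                "interference_count": n_int,
                "daylight_sample_count": n_day,
                "wet_sum": int(wet.get(d)) if d in wet.index else None,
                "colony_distance_km": float(dist) if np.isfinite(dist) else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df["interference_count"] = df["interference_count"].astype("Int64")
    df["daylight_sample_count"] = df["daylight_sample_count"].astype("Int64")
    df["wet_sum"] = df["wet_sum"].astype("Int64")
    return df
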