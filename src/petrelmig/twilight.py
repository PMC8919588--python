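"""Threshold light-level geolocation: twilights, calibration, initial positions.

The threshold method reads positions off the light curve: the times at which
light crosses a fixed threshold define sunrise and sunset; longitude follows
from the midpoint of a twilight pair (local solar noon/midnight corrected by
the equation of time) and latitude from the day length given the solar
declination and a calibrated zenith angle. Near equinoxes day length is
~12 h at every latitude, so latitude is unidentifiable and flagged.

The zenith angle is tag-specific and absorbs sensor and mounting effects; it
is calibrated from a 3–5 day window at a known location. Under shading, the
observed sunrise is systematically late and sunset early (delays are
one-sided); when a log-normal shading model is supplied the calibration
corrects for it by maximum likelihood, otherwise it zeroes the median
discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import lognorm

from petrelmig import solar
from petrelmig.series import INTERVAL_MINUTES, LightSeries

MIN_EVENT_GAP_H = 2.0
MAX_EVENT_GAP_H = 22.0


@dataclass
class TwilightSeries:
    """Ordered, alternating sunrise/sunset threshold crossings."""

    times: pd.DatetimeIndex
    kinds: np.ndarray  # 'sunrise' | 'sunset'
    threshold_used: float
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kinds = np.asarray(self.kinds, dtype=object)
        if len(self.times) != len(self.kinds):
            raise ValueError("times and kinds length mismatch")
        for k in range(1, len(self.kinds)):
            if self.kinds[k] == self.kinds[k - 1]:
                raise ValueError(f"twilight kinds do not alternate at index {k}")

    def __len__(self) -> int:
        return len(self.times)

    def pairs(self, kind_first: str = "sunrise") -> list[tuple[int, int]]:
        """Indices of consecutive (kind_first, other) event pairs."""
        out = []
        for k in range(len(self) - 1):
            if self.kinds[k] == kind_first:
                out.append((k, k + 1))
        return out


def detect_twilights(light: LightSeries, threshold: float | None = None) -> TwilightSeries:
    """Threshold crossings of the light curve, interpolated within the 10-min bin.

    Upward crossings are sunrises, downward sunsets. Events bracketing an
    implausibly short day or night (< 2 h — e.g. a one-sample shading dip at
    noon) are removed in pairs; residual alternation violations (days with a
    single crossing) are dropped and logged.
    """
    if threshold is None:
        threshold = light.tag_model.light_threshold
    y = light.light
    t = light.timestamps
    if len(y) < 2:
        return TwilightSeries(pd.DatetimeIndex([], tz="UTC"), np.array([], dtype=object), threshold,
                              skipped=["series too short"])
    above = y >= threshold
    if above.all() or (~above).all():
        return TwilightSeries(
            pd.DatetimeIndex([], tz="UTC"), np.array([], dtype=object), threshold,
            skipped=["no threshold crossings (constant light or darkness)"],
        )
    change = np.nonzero(above[1:] != above[:-1])[0]
    times = []
    kinds = []
    # each sample is the max over its 10-min bin, so a value represents the
    # bin's midpoint: interpolate between bin midpoints, not bin starts
    half_bin = pd.Timedelta(minutes=INTERVAL_MINUTES / 2)
    for i in change:
        y0, y1 = y[i], y[i + 1]
        frac = (threshold - y0) / (y1 - y0) if y1 != y0 else 0.5
        times.append(t[i] + half_bin + frac * (t[i + 1] - t[i]))
        kinds.append("sunrise" if y1 > y0 else "sunset")
    times = pd.DatetimeIndex(times)
    kinds = np.asarray(kinds, dtype=object)

    skipped: list[str] = []
    # remove short-interval event pairs (spurious dips/spikes) until stable
    keep = np.ones(len(times), dtype=bool)
    changed = True
    while changed:
        changed = False
        idx = np.nonzero(keep)[0]
        for a, b in zip(idx[:-1], idx[1:]):
            gap_h = (times[b] - times[a]).total_seconds() / 3600.0
            if gap_h < MIN_EVENT_GAP_H:
                keep[a] = keep[b] = False
                skipped.append(
                    f"dropped {kinds[a]}/{kinds[b]} pair {gap_h * 60:.0f} min apart at "
                    f"{times[a].isoformat()}"
                )
                changed = True
                break
    idx = np.nonzero(keep)[0]
    # enforce alternation: drop the later of two same-kind neighbours
    final: list[int] = []
    for k in idx:
        if final and kinds[final[-1]] == kinds[k]:
            skipped.append(f"dropped non-alternating {kinds[k]} at {times[k].isoformat()}")
            continue
        final.append(k)
    return TwilightSeries(times[final], kinds[final], threshold, skipped=skipped)


@dataclass
class CalibrationResult:
    """Calibrated zenith angle and the twilight-error distribution."""

    zenith: float
    meanlog: float
    sdlog: float
    discrepancies_min: np.ndarray

    def __post_init__(self) -> None:
        if not 90.0 < self.zenith < 108.0:
            raise ValueError(f"calibrated zenith {self.zenith:.2f}° outside (90°, 108°)")


class CalibrationError(RuntimeError):
    pass


def _delays_minutes(tw: TwilightSeries, lon: float, lat: float, zenith: float) -> np.ndarray:
    """Signed shading delays (obs−pred for sunrise, pred−obs for sunset), minutes."""
    dates = tw.times.normalize().tz_localize(None) if tw.times.tz is not None else tw.times.normalize()
    decl, eqtime = solar.solar_coefficients(tw.times)
    sign = np.where(tw.kinds == "sunrise", -1.0, 1.0)
    pred = solar.twilight_minutes_utc(lon, lat, None, decl, eqtime, zenith, sign)
    obs = (
        (tw.times - tw.times.normalize()).total_seconds().to_numpy() / 60.0
    )
    delta = obs - np.mod(pred, 1440.0)
    delta = np.where(delta > 720.0, delta - 1440.0, delta)
    delta = np.where(delta < -720.0, delta + 1440.0, delta)
    return np.where(tw.kinds == "sunrise", delta, -delta)


def calibrate_zenith(
    tw: TwilightSeries,
    lon: float,
    lat: float,
    window: tuple | None = None,
    error_model: tuple[float, float] | None = None,
) -> CalibrationResult:
    """Calibrate the zenith angle from twilights recorded at a known location.

    With no `error_model`, the zenith is the value that zeroes the median
    observed-minus-predicted twilight discrepancy over the window. With a
    log-normal shading model ``(meanlog, sdlog)`` in log-minutes, the zenith
    maximises the likelihood of the (necessarily positive) shading delays
    under that distribution, which corrects the bias that one-sided shading
    otherwise folds into the zenith.
    """
    sel = np.ones(len(tw), dtype=bool)
    if window is not None:
        t0, t1 = (
            pd.Timestamp(x).tz_localize("UTC") if pd.Timestamp(x).tz is None else pd.Timestamp(x)
            for x in window
        )
        sel = (tw.times >= t0) & (tw.times < t1)
    times = tw.times[sel]
    kinds = tw.kinds[sel]
    if len(times) == 0 or (times.max() - times.min()) < pd.Timedelta(days=2):
        raise CalibrationError(
            "calibration needs at least 3 days of twilights at the known location"
        )
    sub = TwilightSeries(times, kinds, tw.threshold_used)

    def med(z: float) -> float:
        return float(np.median(_delays_minutes(sub, lon, lat, z)))

    if error_model is None:
        lo, hi = 90.1, 107.9
        if med(lo) * med(hi) > 0:
            z = lo if abs(med(lo)) < abs(med(hi)) else hi
        else:
            z = brentq(med, lo, hi, xtol=1e-4)
    else:
        meanlog, sdlog = error_model

        def nll(z: float) -> float:
            d = _delays_minutes(sub, lon, lat, z)
            if np.any(d <= 1e-9):
                return 1e12 + float(np.sum(np.maximum(1e-9 - d, 0.0)))
            return float(-np.sum(lognorm.logpdf(d, s=sdlog, scale=np.exp(meanlog))))

        res = minimize_scalar(nll, bounds=(90.1, 107.9), method="bounded",
                              options={"xatol": 1e-4})
        z = float(res.x)
    d = _delays_minutes(sub, lon, lat, z)
    pos = d[d > 0.05]
    if len(pos) >= 3:
        meanlog_hat = float(np.mean(np.log(pos)))
        sdlog_hat = float(np.std(np.log(pos), ddof=1))
    else:
        meanlog_hat, sdlog_hat = 0.0, 0.0
    return CalibrationResult(zenith=float(z), meanlog=meanlog_hat, sdlog=sdlog_hat,
                             discrepancies_min=d)


def threshold_positions(tw: TwilightSeries, zenith: float) -> pd.DataFrame:
    """Initial track from the threshold method: one position per twilight pair.

    Longitude from the equation-of-time-corrected midpoint of the pair;
    latitude from the pair's day (or night) length. Latitude is flagged
    indeterminate where day length barely depends on latitude (near
    equinoxes) and imputed by linear interpolation from neighbouring
    solvable pairs.
    """
    if len(tw) < 2:
        raise ValueError("need at least one twilight pair")
    rows = []
    decl_all, eq_all = solar.solar_coefficients(tw.times)
    for a in range(len(tw) - 1):
        b = a + 1
        gap_h = (tw.times[b] - tw.times[a]).total_seconds() / 3600.0
        if not (MIN_EVENT_GAP_H <= gap_h <= MAX_EVENT_GAP_H):
            continue
        is_day = tw.kinds[a] == "sunrise"
        mid = tw.times[a] + (tw.times[b] - tw.times[a]) / 2
        decl, eqtime = solar.solar_coefficients(pd.DatetimeIndex([mid]))
        decl, eqtime = float(decl[0]), float(eqtime[0])
        mid_min = (mid - mid.normalize()).total_seconds() / 60.0
        # solar noon (day pair) or midnight (night pair) at `mid`
        target = 720.0 if is_day else 0.0
        lon = (720.0 - eqtime - mid_min + target - 720.0) / 4.0 if is_day else (
            (720.0 - eqtime - mid_min - 720.0) / 4.0
        )
        lon = ((lon + 180.0) % 360.0) - 180.0
        # latitude from interval length
        interval_h = gap_h if is_day else 24.0 - gap_h
        lat, flagged = _solve_latitude(interval_h, decl, zenith)
        rows.append(
            {
                "epoch": mid,
                "lon": lon,
                "lat": lat,
                "lat_flagged": flagged,
                "kind": "day" if is_day else "night",
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no valid twilight pairs")
    # impute flagged latitudes from neighbours
    lat = df["lat"].to_numpy()
    if df["lat_flagged"].any() and (~df["lat_flagged"]).any():
        good = ~df["lat_flagged"].to_numpy()
        x = np.arange(len(df))
        lat[~good] = np.interp(x[~good], x[good], lat[good])
        df["lat"] = lat
    elif df["lat_flagged"].all():
        df["lat"] = 0.0
    return df


def _solve_latitude(interval_h: float, decl: float, zenith: float) -> tuple[float, bool]:
    """Latitude whose day length above `zenith` equals `interval_h` hours."""

    def f(phi: float) -> float:
        dl = solar.day_length_hours(phi, decl, zenith)
        if np.isnan(dl):
            # sun never crosses: sign by polar day vs night
            latr, dr = np.deg2rad(phi), np.deg2rad(decl)
            cosz = np.sin(latr) * np.sin(dr) + np.cos(latr) * np.cos(dr)
            return (24.0 if np.rad2deg(np.arccos(np.clip(cosz, -1, 1))) < zenith else 0.0) - interval_h
        return dl - interval_h

    lo, hi = -88.0, 88.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        return (0.0, True)
    lat = brentq(f, lo, hi, xtol=1e-4)
    # sensitivity check: near-equinox day length is flat in latitude
    span = abs(f(np.clip(lat + 5, lo, hi)) - f(np.clip(lat - 5, lo, hi)))
    return (float(lat), bool(span < 0.05))
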