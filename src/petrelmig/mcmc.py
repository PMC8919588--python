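"""Bayesian refinement of threshold-geolocation tracks (Estelle-style MCMC).

One position is estimated per twilight event. The posterior combines:

* a **twilight model** — the observed twilight is the true one shifted by a
  one-sided shading delay (sunrise can only be late, sunset only early) with
  log-normal density in minutes (default meanlog 2.2, sdlog 1.0);
* a **behavioural model** — great-circle speed between consecutive positions
  follows a gamma prior (default shape 2.0, rate 0.1, km/h);
* a **spatial mask** — probability zero on land;
* an **SST likelihood** — daily median tag temperature vs the gridded field
  at the candidate position (Gaussian, default SD 1.0 °C).

Sampling is Metropolis-within-Gibbs with checkerboard (odd/even site)
updates, which are conditionally independent given the other parity because
only adjacent positions interact through the speed prior. The schedule
follows the standard design: a relaxed-model burn-in (halved speed-prior
rate, softened mask) with proposal-scale tuning to 20–40 % acceptance, three
short runs to check split-chain R-hat < 1.1, then the production chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from petrelmig import solar
from petrelmig.emd import haversine_km
from petrelmig.landmask import LandMask
from petrelmig.series import SSTLog
from petrelmig.sst import SSTField
from petrelmig.twilight import TwilightSeries


@dataclass
class MovementPrior:
    """Gamma prior on great-circle speed between consecutive positions (km/h)."""

    shape: float = 2.0
    rate: float = 0.1

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma shape and rate must be > 0")


@dataclass
class ChainsConfig:
    """MCMC schedule; defaults follow the full production schedule."""

    burn_in: int = 2000
    conv_runs: int = 3
    conv_samples: int = 300
    conv_thin: int = 4
    n_chains: int = 4
    n_samples: int = 3000
    rhat_threshold: float = 1.1
    max_restarts: int = 3
    initial_scale_deg: float = 1.0
    target_accept: tuple[float, float] = (0.2, 0.4)

    @classmethod
    def fast(cls) -> "ChainsConfig":
        """Reduced schedule for population-scale runs."""
        return cls(burn_in=500, conv_runs=3, conv_samples=150, conv_thin=3,
                   n_chains=2, n_samples=750, max_restarts=3)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PosteriorTrack:
    """Posterior position samples per twilight event."""

    epochs: pd.DatetimeIndex
    lon: np.ndarray  # (chains, samples, sites)
    lat: np.ndarray
    acceptance: float
    rhat: float
    individual_id: str = ""
    year: int = 0

    @property
    def n_sites(self) -> int:
        return self.lon.shape[2]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        c, s, k = self.lon.shape
        return self.lon.reshape(c * s, k), self.lat.reshape(c * s, k)


class _Model:
    """Per-track precomputation and vectorised local log-densities."""

    def __init__(self, tw: TwilightSeries, zenith: float, twilight_model: tuple[float, float],
                 movement: MovementPrior, mask: LandMask, sst_field: SSTField | None,
                 sst_log: SSTLog | None, sst_sd: float):
        self.K = len(tw)
        self.times = tw.times
        self.zenith = zenith
        self.meanlog, self.sdlog = twilight_model
        self.movement = movement
        self.mask = mask
        self.sst_sd = sst_sd
        decl, eqtime = solar.solar_coefficients(tw.times)
        self.decl = decl
        self.eqtime = eqtime
        self.sign = np.where(np.asarray(tw.kinds) == "sunrise", -1.0, 1.0)
        self.obs_min = (tw.times - tw.times.normalize()).total_seconds().to_numpy() / 60.0
        self.dt_h = np.diff(tw.times.asi8).astype(float) / 3.6e12  # hours
        # daily-median SST matched to events by calendar date
        self.sst_obs = np.full(self.K, np.nan)
        if sst_field is not None and sst_log is not None and len(sst_log):
            med = (
                sst_log.to_frame()
                .assign(date=lambda d: d["timestamp"].dt.normalize())
                .groupby("date")["temp_C"]
                .median()
            )
            ev_dates = tw.times.normalize()
            m = med.reindex(ev_dates)
            self.sst_obs = m.to_numpy()
        self.sst_field = sst_field
        # packed arrays for the numba engine
        self._land, self._mlon0, self._mlat0, self._mres = mask.raster()
        self._week = np.zeros(self.K, dtype=np.int64)
        if sst_field is None:
            self._fv = np.zeros((52, 2, 2))
            self._lon0, self._dlon = 0.0, 1.0
            self._lat0, self._dlat = 0.0, 1.0
            self._nlon, self._nlat = 2, 2
        if sst_field is not None:
            # precomputed fast-path arrays: pandas-free bilinear interpolation
            self._week = np.asarray(SSTField.week_of(tw.times), dtype=np.int64)
            self._fv = sst_field.values
            self._lon0 = float(sst_field.lons[0])
            self._dlon = float(sst_field.lons[1] - sst_field.lons[0])
            self._lat0 = float(sst_field.lats[0])
            self._dlat = float(sst_field.lats[1] - sst_field.lats[0])
            self._nlon = len(sst_field.lons)
            self._nlat = len(sst_field.lats)

    def twilight_logp(self, lon: np.ndarray, lat: np.ndarray, idx: np.ndarray,
                      relaxed: bool = False) -> np.ndarray:
        pred = (
            720.0
            - 4.0 * lon
            - self.eqtime[idx]
            + self.sign[idx] * 4.0 * solar.hour_angle_deg(lat, self.decl[idx], self.zenith)
        )
        delta = self.obs_min[idx] - np.mod(pred, 1440.0)
        delta = np.where(delta > 720.0, delta - 1440.0, delta)
        delta = np.where(delta < -720.0, delta + 1440.0, delta)
        delay = np.where(self.sign[idx] < 0, delta, -delta)  # minutes, must be > 0
        out = np.full(len(idx), -np.inf)
        ok = np.isfinite(delay) & (delay > 0)
        d = delay[ok]
        ld = np.log(d)
        out[ok] = -ld - 0.5 * ((ld - self.meanlog) / self.sdlog) ** 2
        if relaxed:
            # burn-in: soft quadratic penalty instead of a hard one-sided support
            bad = np.isfinite(delay) & (delay <= 0)
            out[bad] = -8.0 - 0.5 * (delay[bad] / 5.0) ** 2
        return out

    def speed_logp(self, lon1, lat1, lon2, lat2, dt_h, rate: float) -> np.ndarray:
        v = haversine_km(lon1, lat1, lon2, lat2) / dt_h
        v = np.maximum(v, 1e-3)
        return (self.movement.shape - 1.0) * np.log(v) - rate * v

    def sst_logp(self, lon: np.ndarray, lat: np.ndarray, idx: np.ndarray) -> np.ndarray:
        if self.sst_field is None:
            return np.zeros(len(idx))
        obs = self.sst_obs[idx]
        out = np.zeros(len(idx))
        ok = np.isfinite(obs)
        if ok.any():
            fx = np.clip((lon[ok] - self._lon0) / self._dlon, 0, self._nlon - 1.001)
            fy = np.clip((lat[ok] - self._lat0) / self._dlat, 0, self._nlat - 1.001)
            ix = fx.astype(int)
            iy = fy.astype(int)
            tx = fx - ix
            ty = fy - iy
            v = self._fv
            w = self._week[idx[ok]]
            pred = (
                v[w, iy, ix] * (1 - tx) * (1 - ty)
                + v[w, iy, ix + 1] * tx * (1 - ty)
                + v[w, iy + 1, ix] * (1 - tx) * ty
                + v[w, iy + 1, ix + 1] * tx * ty
            )
            out[ok] = -0.5 * ((obs[ok] - pred) / self.sst_sd) ** 2
        return out

    def mask_logp(self, lon: np.ndarray, lat: np.ndarray, soft: bool) -> np.ndarray:
        land = self.mask.on_land(lon, lat)
        return np.where(land, -50.0 if soft else -np.inf, 0.0)

    def local_logp(self, idx: np.ndarray, lon_i: np.ndarray, lat_i: np.ndarray,
                   lon_all: np.ndarray, lat_all: np.ndarray, rate: float,
                   soft_mask: bool) -> np.ndarray:
        lp = self.twilight_logp(lon_i, lat_i, idx, relaxed=soft_mask)
        lp += self.mask_logp(lon_i, lat_i, soft_mask)
        lp += self.sst_logp(lon_i, lat_i, idx)
        return self._speed_terms(lp, idx, lon_i, lat_i, lon_all, lat_all, rate)

    def _speed_terms(self, lp, idx, lon_i, lat_i, lon_all, lat_all, rate):
        left = idx > 0
        if left.any():
            il = idx[left]
            lp[left] += self.speed_logp(lon_all[il - 1], lat_all[il - 1],
                                        lon_i[left], lat_i[left], self.dt_h[il - 1], rate)
        right = idx < self.K - 1
        if right.any():
            ir = idx[right]
            lp[right] += self.speed_logp(lon_i[right], lat_i[right],
                                         lon_all[ir + 1], lat_all[ir + 1], self.dt_h[ir], rate)
        return lp

    def nb_args(self, rate: float, soft: bool) -> tuple:
        """Packed argument tuple for the numba sweep kernel."""
        return (
            self.obs_min, self.sign, self.decl, self.eqtime, self.dt_h,
            self.sst_obs, self._week, self._fv,
            self._lon0, self._dlon, self._lat0, self._dlat,
            float(self._nlon), float(self._nlat),
            self._land, self._mlon0, self._mlat0, self._mres,
            self.zenith, self.meanlog, self.sdlog,
            self.movement.shape, rate, self.sst_sd, soft,
        )


from numba import njit


@njit(cache=True)
def _site_logp_nb(x, y, k, lon, lat, obs_min, sign, decl, eqtime, dt_h, sst_obs, week,
                  fv, lon0f, dlonf, lat0f, dlatf, nlonf, nlatf,
                  land, mlon0, mlat0, mres, zenith, meanlog, sdlog,
                  shape, rate, sst_sd, soft, with_speed):  # pragma: no cover
    """Scalar local log-density of site k at (x, y); numba engine.

    Mirrors _Model.local_logp / twilight, SST, mask and speed terms; the
    numpy implementation is the reference it is tested against.
    """
    K = lon.shape[0]
    # twilight
    zr = zenith * 0.017453292519943295
    yr = y * 0.017453292519943295
    dr = decl[k] * 0.017453292519943295
    cosH = (np.cos(zr) - np.sin(yr) * np.sin(dr)) / (np.cos(yr) * np.cos(dr))
    lp = 0.0
    if cosH < -1.0 or cosH > 1.0:
        return -np.inf
    ha = np.arccos(cosH) * 57.29577951308232
    pred = 720.0 - 4.0 * x - eqtime[k] + sign[k] * 4.0 * ha
    delta = obs_min[k] - (pred % 1440.0)
    if delta > 720.0:
        delta -= 1440.0
    elif delta < -720.0:
        delta += 1440.0
    delay = delta if sign[k] < 0 else -delta
    if delay > 0.0:
        ld = np.log(delay)
        lp += -ld - 0.5 * ((ld - meanlog) / sdlog) ** 2
    elif soft:
        lp += -8.0 - 0.5 * (delay / 5.0) ** 2
    else:
        return -np.inf
    # land mask raster; outside the rasterised study window counts as land
    ix = int((x - mlon0) / mres)
    iy = int((y - mlat0) / mres)
    outside = iy < 0 or iy >= land.shape[0] or ix < 0 or ix >= land.shape[1]
    if outside or land[iy, ix]:
        if soft:
            lp += -50.0
        else:
            return -np.inf
    # SST
    if sst_obs[k] == sst_obs[k]:  # not NaN
        fx = (x - lon0f) / dlonf
        fy = (y - lat0f) / dlatf
        if fx < 0.0:
            fx = 0.0
        if fx > nlonf - 1.001:
            fx = nlonf - 1.001
        if fy < 0.0:
            fy = 0.0
        if fy > nlatf - 1.001:
            fy = nlatf - 1.001
        i0 = int(fx)
        j0 = int(fy)
        tx = fx - i0
        ty = fy - j0
        w = week[k]
        pred_sst = (
            fv[w, j0, i0] * (1 - tx) * (1 - ty)
            + fv[w, j0, i0 + 1] * tx * (1 - ty)
            + fv[w, j0 + 1, i0] * (1 - tx) * ty
            + fv[w, j0 + 1, i0 + 1] * tx * ty
        )
        lp += -0.5 * ((sst_obs[k] - pred_sst) / sst_sd) ** 2
    # speed to neighbours
    if with_speed:
        for nb in (-1, 1):
            kk = k + nb
            if kk < 0 or kk >= K:
                continue
            p1 = yr
            p2 = lat[kk] * 0.017453292519943295
            dphi = p2 - p1
            dlmb = (lon[kk] - x) * 0.017453292519943295
            a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
            sq = np.sqrt(a)
            if sq > 1.0:
                sq = 1.0
            dist = 2.0 * 6371.0 * np.arcsin(sq)
            dt = dt_h[k] if nb == 1 else dt_h[k - 1]
            v = dist / dt
            if v < 1e-3:
                v = 1e-3
            lp += (shape - 1.0) * np.log(v) - rate * v
    return lp


@njit(cache=True)
def _sweep_nb(lon, lat, free, obs_min, sign, decl, eqtime, dt_h, sst_obs, week,
              fv, lon0f, dlonf, lat0f, dlatf, nlonf, nlatf,
              land, mlon0, mlat0, mres, zenith, meanlog, sdlog,
              shape, rate, sst_sd, soft,
              prop_lon, prop_lat, mult, u_lon, u_lat,
              blk_i, blk_len, blk_dlon, blk_dlat, blk_u,
              scale_lon, scale_lat, acc_lon, acc_lat):  # pragma: no cover
    """Checkerboard sweep + block moves, in place.

    Longitude and latitude are updated in separate Metropolis sub-steps with
    independently adapted per-site scales: twilight timing pins longitude
    tightly everywhere, while latitude can be near-flat (equinox, dry tag),
    so the two coordinates need very different step sizes.
    Per-site accept flags are written to acc_lon / acc_lat.
    """
    K = lon.shape[0]
    acc = 0
    for parity in range(2):
        for k in range(parity, K, 2):
            acc_lon[k] = 0
            acc_lat[k] = 0
            if not free[k]:
                continue
            cur = _site_logp_nb(lon[k], lat[k], k, lon, lat, obs_min, sign, decl, eqtime,
                                dt_h, sst_obs, week, fv, lon0f, dlonf, lat0f, dlatf,
                                nlonf, nlatf, land, mlon0, mlat0, mres, zenith, meanlog,
                                sdlog, shape, rate, sst_sd, soft, True)
            # longitude sub-step
            x = lon[k] + prop_lon[k] * scale_lon[k] * mult[k]
            x = ((x + 180.0) % 360.0) - 180.0
            prop = _site_logp_nb(x, lat[k], k, lon, lat, obs_min, sign, decl, eqtime,
                                 dt_h, sst_obs, week, fv, lon0f, dlonf, lat0f, dlatf,
                                 nlonf, nlatf, land, mlon0, mlat0, mres, zenith, meanlog,
                                 sdlog, shape, rate, sst_sd, soft, True)
            if prop > -np.inf and (cur == -np.inf or np.log(u_lon[k]) < prop - cur):
                lon[k] = x
                cur = prop
                acc += 1
                acc_lon[k] = 1
            # latitude sub-step
            y = lat[k] + prop_lat[k] * scale_lat[k] * mult[k]
            if y > 88.0:
                y = 88.0
            elif y < -88.0:
                y = -88.0
            prop = _site_logp_nb(lon[k], y, k, lon, lat, obs_min, sign, decl, eqtime,
                                 dt_h, sst_obs, week, fv, lon0f, dlonf, lat0f, dlatf,
                                 nlonf, nlatf, land, mlon0, mlat0, mres, zenith, meanlog,
                                 sdlog, shape, rate, sst_sd, soft, True)
            if prop > -np.inf and (cur == -np.inf or np.log(u_lat[k]) < prop - cur):
                lat[k] = y
                acc += 1
                acc_lat[k] = 1
    # block translation moves
    nb_moves = blk_i.shape[0]
    for b in range(nb_moves):
        i = blk_i[b]
        j = i + blk_len[b] - 1
        if j >= K:
            j = K - 1
        ok = True
        for k in range(i, j + 1):
            if not free[k]:
                ok = False
                break
        if not ok:
            continue
        cur = 0.0
        prop = 0.0
        bad = False
        for k in range(i, j + 1):
            cur += _site_logp_nb(lon[k], lat[k], k, lon, lat, obs_min, sign, decl, eqtime,
                                 dt_h, sst_obs, week, fv, lon0f, dlonf, lat0f, dlatf,
                                 nlonf, nlatf, land, mlon0, mlat0, mres, zenith, meanlog,
                                 sdlog, shape, rate, sst_sd, soft, False)
        # speed terms on pairs (i-1..j, k..k+1) counted once
        lo = i - 1 if i > 0 else 0
        hi = j + 1 if j + 1 <= K - 1 else K - 1
        for k in range(lo, hi):
            p1 = lat[k] * 0.017453292519943295
            p2 = lat[k + 1] * 0.017453292519943295
            dlmb = (lon[k + 1] - lon[k]) * 0.017453292519943295
            a = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
            sq = min(np.sqrt(a), 1.0)
            v = max(2.0 * 6371.0 * np.arcsin(sq) / dt_h[k], 1e-3)
            cur += (shape - 1.0) * np.log(v) - rate * v
        nlon = lon.copy()
        nlat = lat.copy()
        for k in range(i, j + 1):
            nlon[k] = ((lon[k] + blk_dlon[b] + 180.0) % 360.0) - 180.0
            yv = lat[k] + blk_dlat[b]
            if yv > 88.0:
                yv = 88.0
            elif yv < -88.0:
                yv = -88.0
            nlat[k] = yv
        for k in range(i, j + 1):
            lp = _site_logp_nb(nlon[k], nlat[k], k, nlon, nlat, obs_min, sign, decl, eqtime,
                               dt_h, sst_obs, week, fv, lon0f, dlonf, lat0f, dlatf,
                               nlonf, nlatf, land, mlon0, mlat0, mres, zenith, meanlog,
                               sdlog, shape, rate, sst_sd, soft, False)
            if lp == -np.inf:
                bad = True
                break
            prop += lp
        if bad:
            continue
        for k in range(lo, hi):
            p1 = nlat[k] * 0.017453292519943295
            p2 = nlat[k + 1] * 0.017453292519943295
            dlmb = (nlon[k + 1] - nlon[k]) * 0.017453292519943295
            a = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
            sq = min(np.sqrt(a), 1.0)
            v = max(2.0 * 6371.0 * np.arcsin(sq) / dt_h[k], 1e-3)
            prop += (shape - 1.0) * np.log(v) - rate * v
        if cur == -np.inf or np.log(blk_u[b]) < prop - cur:
            for k in range(i, j + 1):
                lon[k] = nlon[k]
                lat[k] = nlat[k]
    return acc


def _range_logp(model: _Model, lon, lat, i: int, j: int, rate: float, soft: bool) -> float:
    """Joint log-density terms touched by sites i..j (inclusive): their
    twilight/mask/SST terms plus each speed term involving a site in range."""
    idx = np.arange(i, j + 1)
    lp = float(
        np.sum(model.twilight_logp(lon[idx], lat[idx], idx, relaxed=soft))
        + np.sum(model.mask_logp(lon[idx], lat[idx], soft))
        + np.sum(model.sst_logp(lon[idx], lat[idx], idx))
    )
    lo = max(i - 1, 0)
    hi = min(j + 1, model.K - 1)
    pair = np.arange(lo, hi)  # speed terms (k, k+1)
    lp += float(
        np.sum(
            model.speed_logp(lon[pair], lat[pair], lon[pair + 1], lat[pair + 1],
                             model.dt_h[pair], rate)
        )
    )
    return lp


def _block_move(model: _Model, lon, lat, scale, rng, rate, soft_mask,
                free: np.ndarray | None = None) -> bool:
    """Translate a random contiguous window of positions by a common offset."""
    K = model.K
    i = int(rng.integers(0, K))
    length = int(min(rng.geometric(3.0 / K), K))
    j = min(i + length - 1, K - 1)
    if free is not None and not free[i : j + 1].all():
        return False
    dlon = rng.normal(0.0, scale)
    dlat = rng.normal(0.0, 2.0 * scale)
    cur = _range_logp(model, lon, lat, i, j, rate, soft_mask)
    lon_p = lon.copy()
    lat_p = lat.copy()
    lon_p[i : j + 1] = ((lon_p[i : j + 1] + dlon + 180.0) % 360.0) - 180.0
    lat_p[i : j + 1] = np.clip(lat_p[i : j + 1] + dlat, -88.0, 88.0)
    prop = _range_logp(model, lon_p, lat_p, i, j, rate, soft_mask)
    if prop == -np.inf:
        return False
    if cur == -np.inf or np.log(rng.uniform()) < prop - cur:
        lon[i : j + 1] = lon_p[i : j + 1]
        lat[i : j + 1] = lat_p[i : j + 1]
        return True
    return False


def _sweep(model: _Model, lon, lat, cur_lp, scale, rng, rate, soft_mask,
           free: np.ndarray | None = None) -> float:
    """One checkerboard sweep plus block-translation moves, in place.

    `free` marks updatable sites; pinned (known-location) sites keep their
    positions but still constrain neighbours through the speed prior.
    Latitude proposals use twice the longitude scale — day length constrains
    latitude far more weakly than twilight timing constrains longitude — and
    a heavy-tailed mixture (occasional 4x jumps) crosses the wide,
    weakly identified latitude basins (near-equinox, dry-tag days).
    `scale` is a pair of per-site arrays (lon, lat), adapted during burn-in:
    weakly identified sites need order-of-magnitude larger steps than
    well-constrained ones, and latitude often far larger than longitude.
    Randomness is pre-drawn from `rng`; the arithmetic runs in numba.
    Returns per-site (lon, lat) acceptance flags.
    """
    K = model.K
    if free is None:
        free = np.ones(K, dtype=bool)
    if isinstance(scale, tuple):
        scale_lon, scale_lat = scale
    else:
        scale_lon = np.broadcast_to(np.asarray(scale, dtype=float), (K,)).copy()
        scale_lat = 2.0 * scale_lon
    mult = np.where(rng.uniform(size=K) < 0.15, 4.0, 1.0)
    prop_lon = rng.normal(0.0, 1.0, K)
    prop_lat = rng.normal(0.0, 1.0, K)
    u_lon = rng.uniform(size=K)
    u_lat = rng.uniform(size=K)
    B = max(3, min(8, K // 12))
    blk_i = rng.integers(0, K, B)
    blk_len = np.minimum(rng.geometric(3.0 / K, B), K).astype(np.int64)
    blk_dlon = rng.normal(0.0, float(np.median(scale_lon)), B)
    blk_dlat = rng.normal(0.0, float(np.median(scale_lat)), B)
    blk_u = rng.uniform(size=B)
    acc_lon = np.zeros(K, dtype=np.int8)
    acc_lat = np.zeros(K, dtype=np.int8)
    _sweep_nb(
        lon, lat, free, *model.nb_args(rate, soft_mask),
        prop_lon, prop_lat, mult, u_lon, u_lat,
        blk_i, blk_len, blk_dlon, blk_dlat, blk_u,
        scale_lon, scale_lat, acc_lon, acc_lat,
    )
    return acc_lon, acc_lat


def _split_rhat(x: np.ndarray) -> np.ndarray:
    """Split-chain R-hat per site; x has shape (chains, samples, sites)."""
    c, s, k = x.shape
    half = s // 2
    chains = np.concatenate([x[:, :half, :], x[:, half : 2 * half, :]], axis=0)
    m, n = chains.shape[0], chains.shape[1]
    means = chains.mean(axis=1)  # (m, k)
    var_within = chains.var(axis=1, ddof=1).mean(axis=0)  # (k,)
    var_between = n * means.var(axis=0, ddof=1)  # (k,)
    var_hat = (n - 1) / n * var_within + var_between / n
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_hat / var_within)
    return np.where(var_within > 1e-12, rhat, 1.0)


def refine_track_mcmc(
    initial: pd.DataFrame,
    tw: TwilightSeries,
    zenith: float,
    movement: MovementPrior | None = None,
    mask: LandMask | None = None,
    sst_field: SSTField | None = None,
    sst_log: SSTLog | None = None,
    chains: ChainsConfig | None = None,
    twilight_model: tuple[float, float] = (2.2, 1.0),
    sst_sd: float = 1.0,
    seed: int = 0,
    individual_id: str = "",
    year: int = 0,
    fixed_window: tuple | None = None,
    fixed_position: tuple[float, float] | None = None,
) -> PosteriorTrack:
    """Refine an initial threshold track by MCMC; deterministic given `seed`.

    `initial` is the threshold-position table (columns epoch, lon, lat); the
    state has one position per twilight event in `tw`, initialised from the
    nearest initial position (moved off land if needed). Events inside
    `fixed_window` (e.g. the calibration period at the colony) are pinned at
    `fixed_position` and never updated — the standard way of anchoring
    known-location periods.
    """
    movement = movement or MovementPrior()
    mask = mask or LandMask()
    chains = chains or ChainsConfig()
    rng = np.random.default_rng(seed)
    model = _Model(tw, zenith, twilight_model, movement, mask, sst_field, sst_log, sst_sd)
    K = model.K
    if K < 2:
        raise ValueError("need at least 2 twilight events")

    # initial state: nearest threshold position per event
    init_t = pd.DatetimeIndex(pd.to_datetime(initial["epoch"], utc=True)).asi8
    ev_t = tw.times.asi8
    nearest = np.abs(ev_t[:, None] - init_t[None, :]).argmin(axis=1)
    lon = initial["lon"].to_numpy()[nearest].astype(float).copy()
    lat = initial["lat"].to_numpy()[nearest].astype(float).copy()
    # threshold positions imply zero shading delay — the boundary of the
    # one-sided twilight density. Shift each site east (sunrise) / west
    # (sunset) by the prior median delay so the initial state is in support.
    offset_deg = np.exp(model.meanlog) / 4.0
    lon = lon - model.sign * offset_deg  # sign: -1 sunrise, +1 sunset

    free = np.ones(K, dtype=bool)
    if fixed_window is not None:
        if fixed_position is None:
            raise ValueError("fixed_window requires fixed_position")
        t0, t1 = (pd.Timestamp(x).tz_localize("UTC") if pd.Timestamp(x).tz is None
                  else pd.Timestamp(x) for x in fixed_window)
        pinned = (tw.times >= t0) & (tw.times < t1)
        free[np.asarray(pinned)] = False
        lon[~free] = fixed_position[0]
        lat[~free] = fixed_position[1]
    # nudge on-land initials off land by local random search
    land = mask.on_land(lon, lat)
    for k in np.nonzero(land)[0]:
        for r in (1.0, 2.0, 4.0, 8.0):
            cand = rng.normal(0.0, r, size=(40, 2))
            cl = ((lon[k] + cand[:, 0] + 180.0) % 360.0) - 180.0
            ca = np.clip(lat[k] + cand[:, 1], -88.0, 88.0)
            sea = ~mask.on_land(cl, ca)
            if sea.any():
                j = int(np.argmax(sea))
                lon[k], lat[k] = cl[j], ca[j]
                break

    relaxed_rate = movement.rate / 2.0
    scale = (
        np.full(K, chains.initial_scale_deg),
        np.full(K, 2.0 * chains.initial_scale_deg),
    )
    target = 0.5 * (chains.target_accept[0] + chains.target_accept[1])

    # --- burn-in under the relaxed model with per-site scale adaptation ------
    # lon and lat scales adapt independently (Robbins-Monro on the log scale)
    for it in range(chains.burn_in):
        fl_lon, fl_lat = _sweep(model, lon, lat, None, scale, rng, relaxed_rate, True, free)
        gain = 0.25 / (1.0 + it / 50.0) ** 0.6
        for arr, flags in ((scale[0], fl_lon), (scale[1], fl_lat)):
            arr[free] = np.clip(arr[free] * np.exp(gain * (flags[free] - target)), 0.02, 40.0)
    # settle into the strict model: every site must reach finite density
    # (off land, positive shading delay) before chains are compared
    all_idx = np.arange(K)
    for _ in range(500):
        lp = model.local_logp(all_idx, lon, lat, lon, lat, movement.rate, False)
        if np.all(np.isfinite(lp)):
            break
        _sweep(model, lon, lat, None, scale, rng, movement.rate, False, free)

    # --- convergence check: short independent runs ---------------------------
    # the retained draws are thinned in proportion to track length (longer
    # tracks mix more slowly); a failed check triples the span and redraws
    base_thin = chains.conv_thin * max(1, round(K / 100))
    for restart in range(chains.max_restarts + 1):
        thin = base_thin * 2**restart
        conv = np.empty((chains.conv_runs, chains.conv_samples, K, 2))
        states = []
        for c in range(chains.conv_runs):
            lon_c, lat_c = lon.copy(), lat.copy()
            crng = np.random.default_rng(rng.integers(2**31))
            for s in range(chains.conv_samples):
                for _ in range(thin):
                    _sweep(model, lon_c, lat_c, None, scale, crng, movement.rate, False, free)
                conv[c, s, :, 0] = lon_c
                conv[c, s, :, 1] = lat_c
            states.append((lon_c, lat_c))
        rhat = max(
            float(np.nanmax(_split_rhat(conv[..., 0]))),
            float(np.nanmax(_split_rhat(conv[..., 1]))),
        )
        if rhat < chains.rhat_threshold:
            break
        # not converged: continue from the last state with a longer span
        lon, lat = states[-1]
    else:
        raise ConvergenceError(
            f"split-chain R-hat {rhat:.3f} >= {chains.rhat_threshold} after "
            f"{chains.max_restarts} restarts (K={K} sites)"
        )

    # --- production chains ---------------------------------------------------
    out_lon = np.empty((chains.n_chains, chains.n_samples, K), dtype=np.float32)
    out_lat = np.empty_like(out_lon)
    acc_total = 0.0
    n_free = max(int(free.sum()), 1)
    for c in range(chains.n_chains):
        lon_c, lat_c = lon.copy(), lat.copy()
        crng = np.random.default_rng(rng.integers(2**31))
        for s in range(chains.n_samples):
            fl_lon, fl_lat = _sweep(model, lon_c, lat_c, None, scale, crng,
                                    movement.rate, False, free)
            acc_total += 0.5 * float(fl_lon.sum() + fl_lat.sum()) / n_free
            out_lon[c, s] = lon_c
            out_lat[c, s] = lat_c
    acc = acc_total / (chains.n_chains * chains.n_samples)
    return PosteriorTrack(
        epochs=tw.times,
        lon=out_lon,
        lat=out_lat,
        acceptance=float(acc),
        rhat=rhat,
        individual_id=individual_id,
        year=year,
    )


def summarize_posterior(post: PosteriorTrack) -> pd.DataFrame:
    """Median track and central 95 % credible intervals per twilight epoch."""
    lon, lat = post.pooled()
    q = np.percentile(lon, [2.5, 50.0, 97.5], axis=0)
    p = np.percentile(lat, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "individual_id": post.individual_id,
            "year": post.year,
            "epoch": post.epochs,
            "lon_med": q[1],
            "lat_med": p[1],
            "lon_lo": q[0],
            "lon_hi": q[2],
            "lat_lo": p[0],
            "lat_hi": p[2],
        }
    )
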