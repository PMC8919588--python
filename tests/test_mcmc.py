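"""MCMC refinement: model components, summaries, and posterior behaviour."""

import numpy as np
import pandas as pd
import pytest

from conftest import COLONY, solar_twilight_series
from petrelmig.landmask import LandMask
from petrelmig.mcmc import (
    ChainsConfig,
    MovementPrior,
    PosteriorTrack,
    _Model,
    _site_logp_nb,
    _split_rhat,
    refine_track_mcmc,
    summarize_posterior,
)
from petrelmig.sst import synthetic_sst_field

TINY = ChainsConfig(burn_in=150, conv_runs=2, conv_samples=60, conv_thin=2,
                    n_chains=2, n_samples=150, max_restarts=4, rhat_threshold=1.3)


def tiny_inputs(seed=0, days=10, lon=70.0, lat=-25.0, shaded=True):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2014-12-01", periods=days)
    tw = solar_twilight_series(lon, lat, dates, 96.0,
                               rng=rng if shaded else None, meanlog=2.2, sdlog=0.6)
    initial = pd.DataFrame(
        {"epoch": tw.times, "lon": np.full(len(tw), lon), "lat": np.full(len(tw), lat)}
    )
    return tw, initial


def test_one_sided_twilight_density_zero_for_negative_delay(land_mask, sst_field):
    tw, _ = tiny_inputs(shaded=False)
    model = _Model(tw, 96.0, (2.2, 1.0), MovementPrior(), land_mask, None, None, 1.0)
    idx = np.array([0])
    # at the generating position the delay is ~0; nudging longitude west makes
    # the predicted sunrise later than observed -> negative delay -> -inf
    west = model.twilight_logp(np.array([70.0 - 2.0]), np.array([-25.0]), idx)
    east = model.twilight_logp(np.array([70.0 + 2.0]), np.array([-25.0]), idx)
    assert np.isneginf(west[0])
    assert np.isfinite(east[0])


def test_numba_engine_matches_numpy_reference(land_mask, sst_field, rendered_track):
    track, cfg, light, _, sstlog = rendered_track
    from petrelmig.twilight import detect_twilights

    tw = detect_twilights(light)
    model = _Model(tw, 96.5, (2.2, 1.0), MovementPrior(), land_mask, sst_field, sstlog, 1.0)
    rng = np.random.default_rng(0)
    K = model.K
    lon = rng.uniform(55, 95, K)
    lat = rng.uniform(-30, -5, K)  # open-ocean box away from coastlines
    ref = model.local_logp(np.arange(K), lon, lat, lon, lat, 0.1, False)
    got = np.array(
        [_site_logp_nb(lon[k], lat[k], k, lon, lat, *model.nb_args(0.1, False), True)
         for k in range(K)]
    )
    finite = np.isfinite(ref)
    assert (finite == np.isfinite(got)).all()
    np.testing.assert_allclose(got[finite], ref[finite], rtol=1e-10, atol=1e-10)


def test_split_rhat_detects_disagreement():
    rng = np.random.default_rng(0)
    good = rng.normal(size=(3, 200, 4))
    bad = good.copy()
    bad[1, :, 2] += 5.0
    assert _split_rhat(good).max() < 1.1
    assert _split_rhat(bad)[2] > 1.5


def test_refinement_recovers_position_and_stays_off_land(land_mask, sst_field):
    tw, initial = tiny_inputs(seed=3)
    post = refine_track_mcmc(initial, tw, 96.0, mask=land_mask, sst_field=None,
                             sst_log=None, chains=TINY, seed=4)
    track = summarize_posterior(post)
    assert np.abs(track["lon_med"] - 70.0).median() < 2.0
    assert np.abs(track["lat_med"] + 25.0).median() < 4.0
    lon, lat = post.pooled()
    assert not land_mask.on_land(lon.ravel(), lat.ravel()).any()
    assert (track["lon_lo"] <= track["lon_med"]).all()
    assert (track["lon_med"] <= track["lon_hi"]).all()


def test_chain_permutation_invariance(land_mask):
    tw, initial = tiny_inputs(seed=5)
    post = refine_track_mcmc(initial, tw, 96.0, mask=land_mask, chains=TINY, seed=6)
    flipped = PosteriorTrack(post.epochs, post.lon[::-1].copy(), post.lat[::-1].copy(),
                             post.acceptance, post.rhat)
    pd.testing.assert_frame_equal(summarize_posterior(post), summarize_posterior(flipped))


def test_determinism_given_seed(land_mask):
    tw, initial = tiny_inputs(seed=8)
    p1 = refine_track_mcmc(initial, tw, 96.0, mask=land_mask, chains=TINY, seed=9)
    p2 = refine_track_mcmc(initial, tw, 96.0, mask=land_mask, chains=TINY, seed=9)
    np.testing.assert_array_equal(p1.lon, p2.lon)


def test_fixed_window_pins_calibration_sites(land_mask):
    tw, initial = tiny_inputs(seed=10, lon=COLONY[0], lat=COLONY[1])
    t0 = tw.times[0].normalize()
    post = refine_track_mcmc(
        initial, tw, 96.0, mask=land_mask, chains=TINY, seed=11,
        fixed_window=(t0, t0 + pd.Timedelta(days=3)), fixed_position=COLONY,
    )
    pinned = np.asarray((tw.times >= t0) & (tw.times < t0 + pd.Timedelta(days=3)))
    lon, lat = post.pooled()
    np.testing.assert_allclose(lon[:, pinned], COLONY[0])
    np.testing.assert_allclose(lat[:, pinned], COLONY[1])


def test_wider_sst_likelihood_widens_latitude_ci(land_mask, sst_field):
    widths = {}
    for sd in (0.5, 3.0):
        tw, initial = tiny_inputs(seed=12)
        # logger SST at the true position
        sst_times = pd.date_range("2014-12-01 06:00", periods=10, freq="D", tz="UTC")
        vals = sst_field.value_at(np.full(10, 70.0), np.full(10, -25.0), sst_times)
        from petrelmig.series import SSTLog

        log = SSTLog(sst_times, vals)
        post = refine_track_mcmc(initial, tw, 96.0, mask=land_mask, sst_field=sst_field,
                                 sst_log=log, chains=TINY, seed=13, sst_sd=sd)
        track = summarize_posterior(post)
        widths[sd] = float((track["lat_hi"] - track["lat_lo"]).mean())
    assert widths[3.0] > widths[0.5]


def test_posterior_percentiles_match_nearest_rank():
    vals = np.arange(1.0, 12001.0)
    post = PosteriorTrack(
        epochs=pd.DatetimeIndex([pd.Timestamp("2014-01-01", tz="UTC")]),
        lon=vals.reshape(4, 3000, 1),
        lat=vals.reshape(4, 3000, 1),
        acceptance=0.3,
        rhat=1.0,
    )
    track = summarize_posterior(post)
    assert track.loc[0, "lon_lo"] == pytest.approx(300, abs=1)   # nearest-rank 300
    assert track.loc[0, "lon_hi"] == pytest.approx(11700, abs=1)
    assert track.loc[0, "lon_med"] == pytest.approx(6000.5, abs=1)


def test_degenerate_posterior_zero_width():
    post = PosteriorTrack(
        epochs=pd.DatetimeIndex([pd.Timestamp("2014-01-01", tz="UTC")]),
        lon=np.full((2, 10, 1), 55.0),
        lat=np.full((2, 10, 1), -20.0),
        acceptance=0.0,
        rhat=1.0,
    )
    track = summarize_posterior(post)
    assert track.loc[0, "lon_hi"] - track.loc[0, "lon_lo"] == 0.0


def test_speed_prior_shrinks_implausible_jumps(land_mask):
    # initial positions alternate over ~2000 km; the speed prior should pull
    # the posterior mean consecutive speed below the initial track's
    rng = np.random.default_rng(14)
    tw, initial = tiny_inputs(seed=15)
    initial = initial.copy()
    initial.loc[::2, "lon"] = 60.0
    initial.loc[1::2, "lon"] = 80.0
    from petrelmig.emd import haversine_km

    def mean_speed(lon, lat):
        d = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        dt = np.diff(tw.times.asi8) / 3.6e12
        return float(np.mean(d / dt))

    post = refine_track_mcmc(initial, tw, 96.0, mask=land_mask, chains=TINY, seed=16)
    track = summarize_posterior(post)
    v_init = mean_speed(initial["lon"].to_numpy(), initial["lat"].to_numpy())
    v_post = mean_speed(track["lon_med"].to_numpy(), track["lat_med"].to_numpy())
    assert v_post < v_init
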