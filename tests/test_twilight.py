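"""Twilight detection, zenith calibration and threshold positions."""

import numpy as np
import pandas as pd
import pytest

from conftest import COLONY, solar_twilight_series
from petrelmig.series import LightSeries
from petrelmig.simulate import render_light, true_twilights
from petrelmig.twilight import (
    CalibrationError,
    calibrate_zenith,
    detect_twilights,
    threshold_positions,
)

ZEN = 96.0


def test_detect_recovers_rendered_twilights(rendered_track):
    track, cfg, light, _, _ = rendered_track
    cfg0 = cfg.replace(twilight_sdlog=0.0, twilight_meanlog=0.0,
                       shading_prob_ashore=0.0, shading_prob_atsea=0.0)
    clean = render_light(track, cfg0, np.random.default_rng(0), zenith=ZEN)
    tw = detect_twilights(clean)
    truth = true_twilights(track, ZEN).dropna(subset=["sunrise"])
    sr_det = pd.DatetimeIndex(sorted(t for t, k in zip(tw.times, tw.kinds) if k == "sunrise"))
    merged = pd.merge_asof(
        pd.DataFrame({"det": sr_det.astype("datetime64[ns, UTC]")}),
        truth.assign(sunrise=truth["sunrise"].astype("datetime64[ns, UTC]")).sort_values("sunrise"),
        left_on="det", right_on="sunrise", direction="nearest",
    )
    err_min = (merged["det"] - merged["sunrise"]).dt.total_seconds().abs() / 60.0
    assert (err_min <= 10.0 + 1e-9).mean() > 0.97


def test_constant_darkness_yields_empty_series():
    ts = pd.date_range("2014-01-01", periods=288, freq="10min", tz="UTC")
    tw = detect_twilights(LightSeries(ts, np.zeros(288)))
    assert len(tw) == 0 and tw.skipped


def test_noon_dip_filtered_by_minimum_night_length():
    ts = pd.date_range("2014-01-01", periods=288, freq="10min", tz="UTC")
    light = np.where((ts.hour >= 6) & (ts.hour < 18), 180.0, 0.0)
    clean = detect_twilights(LightSeries(ts, light.copy()), threshold=1.0)
    light[ts.get_loc(pd.Timestamp("2014-01-01 12:00", tz="UTC"))] = 0.0  # one-sample dip
    dipped = detect_twilights(LightSeries(ts, light), threshold=1.0)
    assert len(dipped) == len(clean)
    assert all(a == b for a, b in zip(dipped.kinds, clean.kinds))


def test_calibration_noiseless_recovers_zenith():
    tw = solar_twilight_series(*COLONY, pd.date_range("2014-02-01", periods=5), ZEN)
    cal = calibrate_zenith(tw, *COLONY)
    assert abs(cal.zenith - ZEN) < 0.05


def test_calibration_under_lognormal_shading():
    errs = []
    for seed in range(8):
        rng = np.random.default_rng(seed)
        tw = solar_twilight_series(*COLONY, pd.date_range("2014-02-01", periods=5), ZEN,
                                   rng=rng, meanlog=2.2, sdlog=1.0)
        cal = calibrate_zenith(tw, *COLONY, error_model=(2.2, 1.0))
        errs.append(cal.zenith - ZEN)
    assert np.mean(np.abs(errs)) < 0.35
    assert np.max(np.abs(errs)) < 0.8


def test_calibration_too_short_window_errors():
    tw = solar_twilight_series(*COLONY, pd.date_range("2014-02-01", periods=1), ZEN)
    with pytest.raises(CalibrationError):
        calibrate_zenith(tw, *COLONY)


def test_threshold_positions_solstice_accuracy():
    tw = solar_twilight_series(*COLONY, pd.date_range("2014-12-10", periods=10), ZEN)
    pos = threshold_positions(tw, ZEN)
    good = pos[~pos["lat_flagged"]]
    assert len(good) > 10
    assert np.abs(good["lon"] - COLONY[0]).max() < 0.5
    assert np.abs(good["lat"] - COLONY[1]).max() < 1.0


def test_threshold_positions_equinox_flagged():
    tw = solar_twilight_series(*COLONY, pd.date_range("2014-03-18", periods=6), ZEN)
    pos = threshold_positions(tw, ZEN)
    assert pos["lat_flagged"].mean() > 0.5


def test_longitude_translation_equivariance():
    d = pd.date_range("2014-12-10", periods=6)
    p0 = threshold_positions(solar_twilight_series(COLONY[0], COLONY[1], d, ZEN), ZEN)
    p1 = threshold_positions(solar_twilight_series(COLONY[0] + 10, COLONY[1], d, ZEN), ZEN)
    np.testing.assert_allclose(p1["lon"] - p0["lon"], 10.0, atol=0.05)
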