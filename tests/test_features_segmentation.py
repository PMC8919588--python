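"""Daily features (geodesics, interference, wet sums) and bout extraction."""

import numpy as np
import pandas as pd
import pytest

from petrelmig.features import daily_features, geodesic_km
from petrelmig.segmentation import MigrationBout, extract_migrations, phenology_table
from petrelmig.simulate import render_immersion, render_light
from petrelmig.twilight import detect_twilights

# frozen WGS84 geodesic references (R geosphere::distGeo, km)
DISTGEO = [
    ((57.78, -19.85, 57.44, -20.25), 56.798079),
    ((57.78, -19.85, 63.0, 12.0), 3568.999360),
    ((63.0, 12.0, 100.0, -26.0), 5807.847764),
    ((0.0, 0.0, 90.0, 0.0), 10018.754171),
    ((20.0, -35.0, 120.0, 30.0), 12692.485791),
]


@pytest.mark.parametrize("args, expected", DISTGEO)
def test_geodesic_matches_distgeo_reference(args, expected):
    assert geodesic_km(*args) == pytest.approx(expected, abs=1e-3)


def test_daily_features_from_rendered_series(rendered_track):
    track, cfg, light, imm, _ = rendered_track
    tw = detect_twilights(light)
    # a perfect 'track table' from the simulator truth
    df = pd.DataFrame({"epoch": track.epochs, "lon_med": track.lon, "lat_med": track.lat})
    feats = daily_features(light, imm, df, cfg.colony_lon, cfg.colony_lat, tw)
    assert len(feats) == len(track.dates)
    feats = feats.assign(state=track.state)
    ashore = feats[feats.state == "ashore"].iloc[cfg.calibration_days:]
    atsea = feats[feats.state == "at-sea"]
    prop_ashore = (ashore.interference_count / ashore.daylight_sample_count).mean()
    prop_atsea = (atsea.interference_count / atsea.daylight_sample_count).mean()
    assert prop_ashore == pytest.approx(cfg.shading_prob_ashore, abs=0.08)
    assert prop_atsea == pytest.approx(cfg.shading_prob_atsea, abs=0.08)
    cap = cfg.tag_model.max_wet_per_interval
    assert atsea.wet_sum.mean() == pytest.approx(144 * cap * cfg.wet_rate_atsea, rel=0.05)
    assert ashore.wet_sum.mean() < 0.05 * 144 * cap
    assert (ashore.colony_distance_km < 50).all()
    assert atsea.colony_distance_km.max() > 1000


def test_interference_thresholds_by_tag_model(rendered_track):
    track, cfg, light, imm, _ = rendered_track
    tw = detect_twilights(light)
    df = pd.DataFrame({"epoch": track.epochs, "lon_med": track.lon, "lat_med": track.lat})
    hi = daily_features(light, imm, df, cfg.colony_lon, cfg.colony_lat, tw,
                        interference_threshold=1.0)
    assert (hi["interference_count"].dropna() == 0).all()  # nothing below 1 in daylight


def _states(runs):
    out = []
    for label, n in runs:
        out += [label] * n
    dates = pd.date_range("2014-06-01", periods=len(out))
    return pd.DataFrame({"date": dates, "state": out})


def test_bout_extraction_basic():
    seq = _states([("ashore", 10), ("at-sea", 100), ("ashore", 10)])
    bouts = extract_migrations(seq, individual_id="x")
    assert len(bouts) == 1
    b = bouts[0]
    assert not b.partial
    assert b.duration_days == 100
    assert b.departure_date == pd.Timestamp("2014-06-11")
    assert b.arrival_date == pd.Timestamp("2014-09-19")


@pytest.mark.parametrize("run, accepted", [(89, False), (90, True)])
def test_min_duration_boundary(run, accepted):
    seq = _states([("ashore", 5), ("at-sea", run), ("ashore", 5)])
    assert bool(extract_migrations(seq)) is accepted


def test_edge_bouts_flagged_partial_and_excluded():
    seq = _states([("at-sea", 120), ("ashore", 10), ("at-sea", 95), ("ashore", 5)])
    bouts = extract_migrations(seq, individual_id="x")
    assert [b.partial for b in bouts] == [True, False]
    table = phenology_table([(b, 2014) for b in bouts])
    assert len(table) == 1


def test_duration_identity_across_year_boundary():
    b = MigrationBout("x", pd.Timestamp("2014-05-20"), pd.Timestamp("2014-09-01"))
    assert b.duration_days == (b.arrival_date - b.departure_date).days
    tab = phenology_table([(b, 2013)])
    assert tab.loc[0, "departure_season"] == "winter"
    assert tab.loc[0, "departure_day"] == 354
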