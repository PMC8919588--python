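"""Stage/period splitting and pairwise comparison tables."""

import numpy as np
import pandas as pd
import pytest

from petrelmig.similarity import (
    MigrationTrack,
    departure_difference_days,
    from_track_table,
    pairwise_comparisons,
    split_periods,
    split_stages,
    stage_lengths,
)


def make_track(ind, year, dep, duration, lon0, lat0, jitter=0.0, seed=0):
    dep = pd.Timestamp(dep, tz="UTC")
    arr = dep + pd.Timedelta(days=duration)
    epochs = pd.date_range(dep, arr - pd.Timedelta(hours=12), freq="12h", tz="UTC")
    rng = np.random.default_rng(seed)
    lon = np.full(len(epochs), lon0) + rng.normal(0, jitter, len(epochs))
    lat = np.full(len(epochs), lat0) + rng.normal(0, jitter, len(epochs))
    return MigrationTrack(ind, year, epochs, lon, lat, dep, arr)


def test_stage_lengths_balanced_partition():
    assert stage_lengths(176, 6) == [30, 30, 29, 29, 29, 29]
    assert sum(stage_lengths(176, 6)) == 176
    assert stage_lengths(180, 6) == [30] * 6


def test_176_day_bout_gives_5_periods_and_6_stages():
    t = make_track("a", 2014, "2014-08-01", 176, 60.0, -20.0)
    periods = split_periods(t, 30)
    stages = split_stages(t, 6)
    assert len(periods) == 5  # trailing 26 days dropped
    assert len(stages) == 6
    assert sum(len(p) for p in periods) == 5 * 30 * 2
    assert sum(len(s) for s in stages) == 176 * 2


def test_too_short_bout_errors():
    t = make_track("a", 2014, "2014-08-01", 20, 60.0, -20.0)
    with pytest.raises(ValueError, match="period"):
        split_periods(t, 30)


def test_departure_difference_circular():
    a = make_track("a", 2014, "2014-06-05", 120, 60.0, -20.0)  # day 5
    b = make_track("a", 2015, "2016-05-28", 120, 60.0, -20.0)  # day 363
    assert departure_difference_days(a, b) == 7


def test_whole_mode_pair_count_and_flags():
    tracks = [
        make_track("a", 2014, "2014-08-01", 120, 60.0, -20.0),
        make_track("a", 2015, "2015-08-05", 120, 60.2, -20.1),
        make_track("b", 2014, "2014-09-01", 120, 90.0, -10.0),
    ]
    tab = pairwise_comparisons(tracks, mode="whole")
    assert len(tab) == 3
    assert tab["same_individual"].sum() == 1
    assert set(tab["stage_label"]) == {"whole"}
    assert (tab["emd_km"] >= 0).all()
    assert tab["ba"].between(0, 1).all()


def test_identical_repeat_track_gives_zero_emd_ba_one():
    tracks = [
        make_track("a", 2014, "2014-08-01", 100, 60.0, -20.0),
        make_track("a", 2015, "2014-08-01", 100, 60.0, -20.0),
    ]
    tab = pairwise_comparisons(tracks, mode="whole")
    row = tab.iloc[0]
    assert row["emd_km"] < 1e-9
    assert row["ba"] == pytest.approx(1.0, abs=1e-9)
    assert row["same_individual"] == 1


def test_stage_mode_within_individual_only():
    tracks = [
        make_track("a", 2014, "2014-08-01", 120, 60.0, -20.0, jitter=0.3, seed=1),
        make_track("a", 2015, "2015-08-01", 132, 60.0, -20.0, jitter=0.3, seed=2),
        make_track("b", 2014, "2014-08-01", 120, 90.0, -10.0, jitter=0.3, seed=3),
    ]
    tab = pairwise_comparisons(tracks, mode="stages", n_stages=6)
    assert set(tab["id_a"]) == {"a/2014"}
    assert list(tab["stage_label"]) == ["whole"] + [f"s{k}" for k in range(1, 7)]
    per = pairwise_comparisons(tracks, mode="periods", period_days=30)
    # 120 d -> 4 periods; truncated to the shorter track's count
    assert list(per["stage_label"]) == ["whole", "p1", "p2", "p3", "p4"]


def test_destination_reuse_means_within_below_between():
    rng = np.random.default_rng(8)
    dests = [(55.0, 2.0), (85.0, -12.0), (100.0, -25.0)]
    tracks = []
    for i in range(6):
        lon0, lat0 = dests[i % 3]
        for y in (2014, 2015):
            tracks.append(
                make_track(f"ind{i}", y, f"{y}-08-01", 100,
                           lon0 + rng.normal(0, 0.5), lat0 + rng.normal(0, 0.5),
                           jitter=1.0, seed=i * 10 + y)
            )
    tab = pairwise_comparisons(tracks, mode="whole", with_ba=False)
    within = tab[tab.same_individual == 1]["emd_km"].mean()
    between = tab[tab.same_individual == 0]["emd_km"].mean()
    assert within < between


def test_from_track_table_restricts_to_bout():
    epochs = pd.date_range("2014-06-01", periods=200, freq="12h", tz="UTC")
    df = pd.DataFrame({"epoch": epochs, "lon_med": 60.0, "lat_med": -20.0})
    mt = from_track_table(df, "a", 2014, "2014-06-20", "2014-07-20")
    assert mt.duration_days == 30
    assert len(mt.lon) == 60
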