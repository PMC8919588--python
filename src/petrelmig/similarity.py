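"""Pairwise spatial and spatiotemporal similarity of migrations.

Whole-migration similarity compares the twice-daily median locations of two
migratory journeys with the earth mover's distance (EMD, km) and — as a
scale-free counterpart — the Bhattacharyya affinity of their kernel UDs.
Spatiotemporal similarity splits each migration either into consecutive
30-day *periods* counted from departure (a trailing remainder shorter than
the period is dropped) or into six *stages* of equal duration covering the
whole bout, and compares matched periods/stages of the same individual's
migrations in different years.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from petrelmig.calendars import day_index, petrel_year_length
from petrelmig.emd import PointSet, emd
from petrelmig.ud import ud_overlap


@dataclass
class MigrationTrack:
    """Twice-daily median positions of one individual-year migration bout."""

    individual_id: str
    year: int
    epochs: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    departure_date: pd.Timestamp
    arrival_date: pd.Timestamp

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.epochs) == len(self.lon) == len(self.lat)):
            raise ValueError("epochs/lon/lat length mismatch")
        if len(self.lon) == 0:
            raise ValueError("migration track has no positions")

    @property
    def duration_days(self) -> int:
        return int((self.arrival_date - self.departure_date).days)

    @property
    def label(self) -> str:
        return f"{self.individual_id}/{self.year}"

    def point_set(self) -> PointSet:
        return PointSet(self.lon, self.lat)


def from_track_table(
    track: pd.DataFrame,
    individual_id: str,
    year: int,
    departure_date,
    arrival_date,
) -> MigrationTrack:
    """Restrict a summarised track table to the migration bout."""
    dep = pd.Timestamp(departure_date).tz_localize("UTC") if pd.Timestamp(departure_date).tz is None else pd.Timestamp(departure_date)
    arr = pd.Timestamp(arrival_date).tz_localize("UTC") if pd.Timestamp(arrival_date).tz is None else pd.Timestamp(arrival_date)
    ep = pd.to_datetime(track["epoch"], utc=True)
    sel = (ep >= dep) & (ep < arr)
    sub = track.loc[sel]
    return MigrationTrack(
        individual_id=individual_id,
        year=year,
        epochs=pd.DatetimeIndex(ep[sel]),
        lon=sub["lon_med"].to_numpy(),
        lat=sub["lat_med"].to_numpy(),
        departure_date=dep,
        arrival_date=arr,
    )


def _slice_days(mt: MigrationTrack, day_lo: int, day_hi: int) -> PointSet:
    """Points with epoch in [departure + day_lo, departure + day_hi) days."""
    t0 = mt.departure_date + pd.Timedelta(days=day_lo)
    t1 = mt.departure_date + pd.Timedelta(days=day_hi)
    sel = (mt.epochs >= t0) & (mt.epochs < t1)
    if not sel.any():
        raise ValueError(f"no positions in days [{day_lo}, {day_hi}) of {mt.label}")
    return PointSet(mt.lon[sel], mt.lat[sel])


def split_periods(mt: MigrationTrack, period_days: int = 30) -> list[PointSet]:
    """Consecutive `period_days`-day blocks from departure; remainder dropped."""
    d = mt.duration_days
    if d < period_days:
        raise ValueError(
            f"bout of {d} d too short for {period_days}-day periods ({mt.label})"
        )
    n = d // period_days
    return [_slice_days(mt, k * period_days, (k + 1) * period_days) for k in range(n)]


def stage_lengths(duration_days: int, n_stages: int = 6) -> list[int]:
    """Balanced partition of the bout into `n_stages` blocks, long blocks first."""
    q, r = divmod(duration_days, n_stages)
    return [q + 1] * r + [q] * (n_stages - r)


def split_stages(mt: MigrationTrack, n_stages: int = 6) -> list[PointSet]:
    """Six contiguous stages of (near-)equal duration covering the whole bout."""
    d = mt.duration_days
    if d < n_stages:
        raise ValueError(f"bout of {d} d too short for {n_stages} stages ({mt.label})")
    lengths = stage_lengths(d, n_stages)
    edges = np.concatenate([[0], np.cumsum(lengths)])
    return [_slice_days(mt, int(edges[k]), int(edges[k + 1])) for k in range(n_stages)]


def departure_difference_days(a: MigrationTrack, b: MigrationTrack) -> int:
    """Absolute circular difference of annual departure timing, in days."""
    da = day_index(a.departure_date)
    db = day_index(b.departure_date)
    year_len = min(petrel_year_length(a.departure_date), petrel_year_length(b.departure_date))
    diff = abs(da - db)
    return int(min(diff, year_len - diff))


def pairwise_comparisons(
    tracks: list[MigrationTrack],
    mode: str = "whole",
    period_days: int = 30,
    n_stages: int = 6,
    h_km: float = 200.0,
    cell_km: float = 50.0,
    with_ba: bool = True,
) -> pd.DataFrame:
    """Comparison table of track pairs.

    mode 'whole': every unordered pair of tracks, EMD (and BA of the kernel
    UDs) with a same-individual flag and the departure-date difference.
    mode 'stages' / 'periods': same-individual pairs only, EMD between
    matched stage/period indices (periods truncated to the shorter track),
    plus a 'whole' row per pair so stage effects can be contrasted against
    the whole migration.
    """
    if mode not in ("whole", "stages", "periods"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks to compare")
    labels = [t.label for t in tracks]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate track labels (same individual and year)")
    # shared projection centre for all UDs
    center = (
        float(np.mean(np.concatenate([t.lon for t in tracks]))),
        float(np.mean(np.concatenate([t.lat for t in tracks]))),
    )
    rows = []
    for a, b in combinations(tracks, 2):
        same = int(a.individual_id == b.individual_id)
        if mode != "whole" and not same:
            continue
        dep_diff = departure_difference_days(a, b)
        base = {
            "id_a": a.label,
            "id_b": b.label,
            "same_individual": same,
            "departure_diff_days": dep_diff,
        }
        whole_emd = emd(a.point_set(), b.point_set())
        if mode == "whole":
            row = dict(base, stage_label="whole", emd_km=whole_emd)
            if with_ba:
                row["ba"] = ud_overlap(a.lon, a.lat, b.lon, b.lat, h_km, cell_km, center=center)
            rows.append(row)
            continue
        rows.append(dict(base, stage_label="whole", emd_km=whole_emd))
        if mode == "stages":
            pa = split_stages(a, n_stages)
            pb = split_stages(b, n_stages)
            names = [f"s{k+1}" for k in range(n_stages)]
        else:
            pa = split_periods(a, period_days)
            pb = split_periods(b, period_days)
            names = [f"p{k+1}" for k in range(min(len(pa), len(pb)))]
        for k, name in enumerate(names):
            rows.append(dict(base, stage_label=name, emd_km=emd(pa[k], pb[k])))
    return pd.DataFrame(rows)
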