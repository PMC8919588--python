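"""Migration bouts and phenology from decoded daily states.

A migration is a maximal run of consecutive at-sea days lasting at least
three months (90 days by default), bounded by ashore days on both sides;
runs truncated by the start or end of the record are flagged partial and
excluded from phenology. Departure is the first at-sea day of the run and
arrival the first ashore day after it, so duration = arrival − departure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from petrelmig.calendars import day_index, season_of

MIN_MIGRATION_DAYS = 90


@dataclass
class MigrationBout:
    individual_id: str
    departure_date: pd.Timestamp
    arrival_date: pd.Timestamp
    partial: bool = False

    @property
    def duration_days(self) -> int:
        return int((self.arrival_date - self.departure_date).days)

    @property
    def departure_day(self) -> int:
        return day_index(self.departure_date)

    @property
    def arrival_day(self) -> int:
        return day_index(self.arrival_date)


def extract_migrations(
    states: pd.DataFrame,
    min_days: int = MIN_MIGRATION_DAYS,
    individual_id: str = "",
) -> list[MigrationBout]:
    """Migration bouts from a decoded state sequence (columns date, state)."""
    dates = pd.to_datetime(states["date"].to_numpy())
    atsea = (states["state"].to_numpy() == "at-sea").astype(int)
    if len(atsea) == 0:
        return []
    edges = np.diff(np.concatenate([[0], atsea, [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]  # exclusive
    bouts = []
    for s, e in zip(starts, ends):
        run_days = int(e - s)
        if run_days < min_days:
            continue
        partial = s == 0 or e == len(atsea)
        dep = pd.Timestamp(dates[s])
        arr = pd.Timestamp(dates[e - 1]) + pd.Timedelta(days=1)  # first ashore day after
        bouts.append(MigrationBout(individual_id, dep, arr, partial=partial))
    return bouts


def phenology_table(bouts: list[tuple[MigrationBout, int]]) -> pd.DataFrame:
    """Phenology table from (bout, petrel_year) pairs; partial bouts excluded.

    Columns: individual, year, departure_day, arrival_day, duration,
    departure_season, arrival_season — the input contract of the statistical
    stage. Day indices are raw (1-based from 1 June); signed-day conversion
    is applied downstream per individual.
    """
    rows = []
    for bout, year in bouts:
        if bout.partial:
            continue
        rows.append(
            {
                "individual_id": bout.individual_id,
                "year": year,
                "departure_date": bout.departure_date,
                "arrival_date": bout.arrival_date,
                "departure_day": bout.departure_day,
                "arrival_day": bout.arrival_day,
                "duration": bout.duration_days,
                "departure_season": season_of(bout.departure_date),
                "arrival_season": season_of(bout.arrival_date),
            }
        )
    return pd.DataFrame(rows)
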