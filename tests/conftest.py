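import numpy as np
import pandas as pd
import pytest

from petrelmig import solar
from petrelmig.landmask import LandMask
from petrelmig.simulate import SimConfig, render_track, simulate_population
from petrelmig.sst import synthetic_sst_field
from petrelmig.twilight import TwilightSeries

COLONY = (57.78, -19.85)


@pytest.fixture(scope="session")
def land_mask():
    return LandMask()


@pytest.fixture(scope="session")
def sst_field():
    return synthetic_sst_field()


@pytest.fixture(scope="session")
def small_population():
    """4 individuals x 2 years with destination reuse; deterministic."""
    cfg = SimConfig(
        n_individuals=4, years_per_individual=(2,), years_probs=(1.0,), seed=42,
        pre_days=20, post_days=20,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def rendered_track(small_population, sst_field):
    """One simulated track with its rendered raw logger series."""
    cfg = small_population.config
    track = small_population.tracks[0]
    rng = np.random.default_rng(7)
    light, imm, sstlog = render_track(track, cfg, sst_field, rng)
    return track, cfg, light, imm, sstlog


def solar_twilight_series(lon, lat, dates, zenith, rng=None, meanlog=None, sdlog=None):
    """Noise-free (or log-normally shaded) twilights straight from the ephemeris."""
    times = []
    kinds = []
    for d in pd.to_datetime(dates):
        sr = solar.twilight_time(lon, lat, d, zenith, "sunrise")
        ss = solar.twilight_time(lon, lat, d, zenith, "sunset")
        if sr is None or ss is None:
            continue
        if rng is not None:
            sr = sr + pd.Timedelta(minutes=float(rng.lognormal(meanlog, sdlog)))
            ss = ss - pd.Timedelta(minutes=float(rng.lognormal(meanlog, sdlog)))
        times += [sr, ss]
        kinds += ["sunrise", "sunset"]
    return TwilightSeries(pd.DatetimeIndex(times), np.array(kinds, dtype=object), 1.0)
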