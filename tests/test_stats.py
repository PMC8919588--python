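"""Study-level statistics: seasonal variability, range correlation, models."""

import numpy as np
import pandas as pd
import pytest

from petrelmig.calendars import day_index_to_date
from petrelmig.stats import (
    pearson_range_correlation,
    phenology_signed,
    seasonal_variability,
    similarity_models,
    timing_repeatabilities,
)


def synth_phenology(rng, n_ind=40, sd_within=10.0, mean_day=100.0, sd_between=30.0,
                    duration=175.0):
    rows = []
    for i in range(n_ind):
        mu = rng.normal(mean_day, sd_between)
        for k, year in enumerate((2013, 2014)):
            dep = int(np.clip(round(rng.normal(mu, sd_within)), 1, 360))
            dur = int(rng.normal(duration, 15))
            dep_date = pd.Timestamp(day_index_to_date(dep, year))
            arr_date = dep_date + pd.Timedelta(days=dur)
            rows.append(
                {
                    "individual_id": f"i{i:03d}",
                    "year": year,
                    "departure_date": dep_date,
                    "arrival_date": arr_date,
                    "departure_day": dep,
                    "arrival_day": 0,
                    "duration": dur,
                    "departure_season": "winter" if dep_date.month in (5, 6, 7, 8, 9) else "summer",
                    "arrival_season": "winter" if arr_date.month in (5, 6, 7, 8, 9) else "summer",
                }
            )
    return pd.DataFrame(rows)


def test_signed_conversion_applied_per_individual():
    rows = [
        {"individual_id": "a", "year": 2013, "departure_date": pd.Timestamp("2014-05-30"),
         "arrival_date": pd.Timestamp("2014-11-01")},
        {"individual_id": "a", "year": 2014, "departure_date": pd.Timestamp("2015-06-02"),
         "arrival_date": pd.Timestamp("2015-11-05")},
    ]
    ph = phenology_signed(pd.DataFrame(rows))
    assert list(ph["departure_day_signed"]) == [-1, 2]


def test_timing_repeatabilities_recover_construction():
    rng = np.random.default_rng(0)
    ph = synth_phenology(rng, n_ind=60, sd_within=10.0, sd_between=30.0)
    reps = timing_repeatabilities(ph, n_boot=100, seed=0)
    r_true = 30.0**2 / (30.0**2 + 10.0**2)  # 0.9
    assert reps["departure"].R == pytest.approx(r_true, abs=0.08)
    assert reps["departure"].ci_low < reps["departure"].R < reps["departure"].ci_high


def test_seasonal_variability_detects_winter_excess():
    rng = np.random.default_rng(1)
    rows = []
    for i in range(56):
        season = "winter" if i < 17 else "summer"
        base = rng.uniform(40, 140)
        sd = 25.0 if season == "winter" else 8.0
        month_anchor = 7 if season == "winter" else 12
        for year in (2013, 2014):
            day = rng.normal(base, sd)
            dep = pd.Timestamp(year=year, month=month_anchor, day=15) + pd.Timedelta(
                days=int(day) % 20
            )
            dep = pd.Timestamp(year=year, month=month_anchor, day=1 + int(abs(day)) % 27)
            rows.append(
                {
                    "individual_id": f"i{i}",
                    "year": year,
                    "departure_date": dep,
                    "arrival_date": dep + pd.Timedelta(days=150),
                }
            )
    # build ranges directly via signed days: spread differs by season
    ph = pd.DataFrame(rows)
    ph["departure_season"] = np.where(ph["departure_date"].dt.month.isin([5, 6, 7, 8, 9]),
                                      "winter", "summer")
    ph["arrival_season"] = "winter"
    out = seasonal_variability(ph)
    assert out.departure_fit is not None
    k = out.departure_fit.columns.index("season[winter]")
    assert out.departure_fit.params[k] > 0
    assert out.departure_fit.pvalues[k] < 0.05


def test_seasonal_null_type_one_error_controlled():
    rng = np.random.default_rng(2)
    hits = 0
    n_sim = 200
    for s in range(n_sim):
        ranges = pd.DataFrame(
            {
                "range_days": rng.gamma(2.0, 10.0, 40),
                "season": ["winter"] * 15 + ["summer"] * 25,
            }
        )
        from petrelmig.glm import fit_glm

        fit = fit_glm(ranges, "range_days", ["season"], family="gamma", link="log")
        k = fit.columns.index("season[winter]")
        if fit.pvalues[k] < 0.05:
            hits += 1
    assert 0.02 <= hits / n_sim <= 0.10


def test_pearson_identity_and_printed_consistency():
    ph = synth_phenology(np.random.default_rng(3), n_ind=30)
    ph2 = ph.copy()
    res_self = pearson_range_correlation(
        ph.assign(arrival_date=lambda d: d["departure_date"] + pd.Timedelta(days=10))
    )
    assert res_self["r"] == pytest.approx(1.0, abs=1e-9)
    # t = r sqrt(df/(1-r^2)) reproduces a printed (r, t, df) triple to the
    # width implied by rounding r to two decimals
    r, df = 0.64, 60
    t = r * np.sqrt(df / (1 - r**2))
    assert t == pytest.approx(6.38, abs=0.1)


def test_similarity_models_on_constructed_tables():
    rng = np.random.default_rng(4)
    n = 300
    same = rng.integers(0, 2, n)
    diff = rng.uniform(0, 150, n)
    mu = np.maximum(1800 - 1200 * same + 2.0 * diff, 100)
    tab = pd.DataFrame(
        {
            "emd_km": rng.gamma(6.0, mu / 6.0),
            "ba": np.clip(0.35 + 0.35 * same + rng.normal(0, 0.08, n), 0.01, 0.99),
            "same_individual": same,
            "departure_diff_days": diff,
        }
    )
    models = similarity_models(tab)
    k = models.emd_whole.columns.index("same_individual")
    assert models.emd_whole.params[k] < 0
    kb = models.ba_whole.columns.index("same_individual")
    assert models.ba_whole.params[kb] > 0  # more overlap within individuals
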