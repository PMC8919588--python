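"""End-to-end orchestration: simulate → geolocate → segment → similarity → stats.

Each stage is a pure function over in-memory objects plus a file-based
wrapper used by the CLI, so running the stages one by one on the same
config and seed is bit-identical to the combined run: every source of
randomness derives its seed from the global seed, the stage name and the
track identity (never from execution order).
"""

from __future__ import annotations

import json
import pathlib
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from petrelmig import io as gio
from petrelmig.calendars import petrel_year_start
from petrelmig.features import daily_features
from petrelmig.hmm import decode_states, fit_hmm
from petrelmig.landmask import LandMask
from petrelmig.mcmc import (
    ChainsConfig,
    ConvergenceError,
    MovementPrior,
    refine_track_mcmc,
    summarize_posterior,
)
from petrelmig.segmentation import MigrationBout, extract_migrations, phenology_table
from petrelmig.similarity import MigrationTrack, from_track_table, pairwise_comparisons
from petrelmig.simulate import PopulationTruth, SimConfig, render_track, simulate_population
from petrelmig.sst import SSTField, synthetic_sst_field
from petrelmig.stats import (
    SimilarityModels,
    pearson_range_correlation,
    repeatability_table,
    similarity_models,
    timing_repeatabilities,
)
from petrelmig.twilight import calibrate_zenith, detect_twilights, threshold_positions

TRUE_ZENITH = 96.0


def stage_seed(seed: int, stage: str, key: str = "") -> int:
    """Stable sub-seed below 2^31 for (global seed, stage, item)."""
    return (zlib.crc32(f"{seed}|{stage}|{key}".encode()) ^ (seed * 2654435761)) % (2**31)


@dataclass
class PipelineResult:
    truth: PopulationTruth
    tracks: dict[str, pd.DataFrame]  # label -> summarised track table
    phenology: pd.DataFrame
    comparisons_whole: pd.DataFrame
    comparisons_stages: pd.DataFrame
    comparisons_periods: pd.DataFrame
    repeatabilities: pd.DataFrame
    models: SimilarityModels | None
    pearson_ranges: dict | None
    diagnostics: dict = field(default_factory=dict)


def geolocate_one(
    light,
    sstlog,
    cfg: SimConfig,
    field: SSTField,
    mask: LandMask,
    chains: ChainsConfig,
    seed: int,
    individual_id: str = "",
    year: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Twilights → calibration → threshold track → MCMC → summarised track."""
    tw = detect_twilights(light)
    t0 = light.timestamps[0]
    # the calibration window is rendered with the tag exposed (no shading), so
    # the median rule applies; shading during deployment is the MCMC's job
    cal = calibrate_zenith(
        tw,
        cfg.colony_lon,
        cfg.colony_lat,
        window=(t0, t0 + pd.Timedelta(days=cfg.calibration_days)),
    )
    initial = threshold_positions(tw, cal.zenith)
    post = refine_track_mcmc(
        initial,
        tw,
        cal.zenith,
        movement=MovementPrior(),
        mask=mask,
        sst_field=field,
        sst_log=sstlog,
        chains=chains,
        twilight_model=(cfg.twilight_meanlog, max(cfg.twilight_sdlog, 0.3)),
        seed=seed,
        individual_id=individual_id,
        year=year,
        fixed_window=(t0, t0 + pd.Timedelta(days=cfg.calibration_days)),
        fixed_position=(cfg.colony_lon, cfg.colony_lat),
    )
    return summarize_posterior(post), cal.zenith


def segment_one(light, immersion, track_df, cfg: SimConfig, seed: int,
                individual_id: str = "") -> list[MigrationBout]:
    tw = detect_twilights(light)
    feats = daily_features(light, immersion, track_df, cfg.colony_lon, cfg.colony_lat, tw)
    model = fit_hmm(feats, n_restarts=4, seed=seed)
    states = decode_states(model, feats)
    return extract_migrations(states, individual_id=individual_id)


def run_all(
    cfg: SimConfig,
    seed: int = 0,
    chains: ChainsConfig | None = None,
    n_boot: int = 1000,
    with_similarity_splits: bool = True,
    progress: bool = False,
) -> PipelineResult:
    """Run the full analysis on a synthetic population."""
    chains = chains or ChainsConfig.fast()
    cfg = cfg.replace(seed=stage_seed(seed, "simulate"))
    truth = simulate_population(cfg)
    mask = LandMask()
    field = synthetic_sst_field()

    tracks: dict[str, pd.DataFrame] = {}
    bouts: list[tuple[MigrationBout, int]] = []
    zeniths = {}
    dropped: list[str] = []
    for t in truth.tracks:
        label = f"{t.individual_id}/{t.year}"
        rng = np.random.default_rng(stage_seed(seed, "render", label))
        light, imm, sstlog = render_track(t, cfg, field, rng, zenith=TRUE_ZENITH)
        try:
            track_df, zen = geolocate_one(
                light, sstlog, cfg, field, mask, chains,
                stage_seed(seed, "mcmc", label), t.individual_id, t.year,
            )
        except ConvergenceError as err:
            # treat like a failed deployment: excluded from analysis, logged
            dropped.append(f"{label}: {err}")
            continue
        zeniths[label] = zen
        tracks[label] = track_df
        for bout in segment_one(light, imm, track_df, cfg,
                                stage_seed(seed, "hmm", label), t.individual_id):
            bouts.append((bout, t.year))
        if progress:
            print(f"  processed {label} (zenith {zen:.2f})")

    phen = phenology_table(bouts)
    # one bout per individual-year track expected; keep the longest if extra
    phen = (
        phen.sort_values("duration", ascending=False)
        .groupby(["individual_id", "year"], as_index=False)
        .first()
        .sort_values(["individual_id", "year"])
        .reset_index(drop=True)
    )

    mig_tracks: list[MigrationTrack] = []
    for _, row in phen.iterrows():
        label = f"{row['individual_id']}/{row['year']}"
        if label not in tracks:
            continue
        mig_tracks.append(
            from_track_table(
                tracks[label], row["individual_id"], int(row["year"]),
                row["departure_date"], row["arrival_date"],
            )
        )

    comp_whole = pairwise_comparisons(mig_tracks, mode="whole")
    comp_stages = (
        pairwise_comparisons(mig_tracks, mode="stages") if with_similarity_splits else pd.DataFrame()
    )
    comp_periods = (
        pairwise_comparisons(mig_tracks, mode="periods") if with_similarity_splits else pd.DataFrame()
    )

    reps = timing_repeatabilities(phen, n_boot=n_boot, seed=stage_seed(seed, "boot"))
    models = similarity_models(
        comp_whole,
        comp_stages if len(comp_stages) else None,
        comp_periods if len(comp_periods) else None,
    ) if len(comp_whole) >= 4 else None
    try:
        pearson = pearson_range_correlation(phen)
    except ValueError:
        pearson = None

    return PipelineResult(
        truth=truth,
        tracks=tracks,
        phenology=phen,
        comparisons_whole=comp_whole,
        comparisons_stages=comp_stages,
        comparisons_periods=comp_periods,
        repeatabilities=repeatability_table(reps),
        models=models,
        pearson_ranges=pearson,
        diagnostics={
            "zeniths": zeniths,
            "true_repeatability": truth.true_repeatability,
            "dropped_tracks": dropped,
        },
    )


def write_results(result: PipelineResult, out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.truth.truth_table().to_csv(out / "truth.csv", index=False)
    result.phenology.to_csv(out / "phenology.csv", index=False)
    result.comparisons_whole.to_csv(out / "comparisons_whole.csv", index=False)
    if len(result.comparisons_stages):
        result.comparisons_stages.to_csv(out / "comparisons_stages.csv", index=False)
    if len(result.comparisons_periods):
        result.comparisons_periods.to_csv(out / "comparisons_periods.csv", index=False)
    result.repeatabilities.to_csv(out / "repeatability.csv", index=False)
    tdir = out / "tracks"
    tdir.mkdir(exist_ok=True)
    for label, df in result.tracks.items():
        gio.write_track(df, tdir / (label.replace("/", "_") + ".csv"))
    summary = {
        "true_repeatability_departure": result.truth.true_repeatability,
        "pearson_ranges": result.pearson_ranges,
    }
    if result.models is not None:
        summary["emd_model_terms"] = result.models.emd_whole.terms
        summary["emd_model_coefficients"] = dict(
            zip(result.models.emd_whole.columns, result.models.emd_whole.params.tolist())
        )
    if result.models is not None and result.models.ba_whole is not None:
        summary["ba_model_coefficients"] = dict(
            zip(result.models.ba_whole.columns, result.models.ba_whole.params.tolist())
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
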