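"""Study-level statistical analyses of phenology and similarity tables.

Combines the repeatability estimator and the GLM suite:

* repeatability of departure date, arrival date and migration duration
  (signed-day conversion applied per individual before fitting);
* seasonal differences in within-individual variability (gamma/log GLMs of
  per-individual date ranges on season);
* Pearson correlation between individuals' departure and arrival ranges;
* the EMD and BA GLMs on pairwise comparison tables, with backwards
  stepwise deletion and Tukey-adjusted stage/period contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from petrelmig.calendars import signed_days
from petrelmig.glm import GLMError, GLMFit, emmeans_tukey, fit_glm, stepwise_backward
from petrelmig.repeatability import RepeatabilityError, RepeatabilityEstimate, repeatability


def phenology_signed(phenology: pd.DataFrame) -> pd.DataFrame:
    """Add signed departure/arrival day columns (per-individual conversion)."""
    out = phenology.copy()
    out["departure_day_signed"] = signed_days(
        pd.to_datetime(out["departure_date"]), out["individual_id"]
    )
    out["arrival_day_signed"] = signed_days(
        pd.to_datetime(out["arrival_date"]), out["individual_id"]
    )
    return out


def timing_repeatabilities(
    phenology: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> dict[str, RepeatabilityEstimate]:
    """Repeatability of departure, arrival and duration (multi-record birds only)."""
    ph = phenology_signed(phenology)
    counts = ph.groupby("individual_id").size()
    repeated = counts[counts >= 2].index
    ph = ph[ph["individual_id"].isin(repeated)]
    out = {}
    for key, col in (
        ("departure", "departure_day_signed"),
        ("arrival", "arrival_day_signed"),
        ("duration", "duration"),
    ):
        try:
            out[key] = repeatability(
                ph[col].to_numpy(float), ph["individual_id"].to_numpy(), n_boot=n_boot, seed=seed
            )
        except RepeatabilityError:
            continue  # too few repeated individuals for this trait
    return out


@dataclass
class SeasonalVariability:
    ranges: pd.DataFrame  # individual, event, season, range_days
    departure_fit: GLMFit | None
    arrival_fit: GLMFit | None
    zero_ranges_replaced: int = 0


def seasonal_variability(phenology: pd.DataFrame, min_events: int = 2) -> SeasonalVariability:
    """Within-individual date ranges vs season (gamma GLM, log link).

    The range (days between an individual's earliest and latest date) is
    computed separately for departures and arrivals, restricted to
    individuals whose events all fall in one season; zero ranges are set to
    0.5 d to stay inside the gamma support.
    """
    ph = phenology_signed(phenology)
    rows = []
    n_zero = 0
    for event, day_col, season_col in (
        ("departure", "departure_day_signed", "departure_season"),
        ("arrival", "arrival_day_signed", "arrival_season"),
    ):
        for ind, g in ph.groupby("individual_id"):
            if len(g) < min_events:
                continue
            seasons = set(g[season_col])
            if len(seasons) != 1:
                continue
            rng = float(g[day_col].max() - g[day_col].min())
            if rng == 0.0:
                rng = 0.5
                n_zero += 1
            rows.append(
                {
                    "individual_id": ind,
                    "event": event,
                    "season": next(iter(seasons)),
                    "range_days": rng,
                }
            )
    ranges = pd.DataFrame(rows)
    fits: dict[str, GLMFit | None] = {"departure": None, "arrival": None}
    for event in ("departure", "arrival"):
        sub = ranges[ranges["event"] == event]
        if len(sub) >= 4 and sub["season"].nunique() == 2:
            fits[event] = fit_glm(sub, "range_days", ["season"], family="gamma", link="log")
    return SeasonalVariability(
        ranges=ranges,
        departure_fit=fits["departure"],
        arrival_fit=fits["arrival"],
        zero_ranges_replaced=n_zero,
    )


def pearson_range_correlation(phenology: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation of per-individual departure vs arrival date ranges."""
    ph = phenology_signed(phenology)
    rows = []
    for ind, g in ph.groupby("individual_id"):
        if len(g) < 2:
            continue
        rows.append(
            {
                "dep_range": float(g["departure_day_signed"].max() - g["departure_day_signed"].min()),
                "arr_range": float(g["arrival_day_signed"].max() - g["arrival_day_signed"].min()),
            }
        )
    d = pd.DataFrame(rows)
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 individuals with repeated tracks")
    r, p = sps.pearsonr(d["dep_range"], d["arr_range"])
    df = n - 2
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    return {"r": float(r), "t": float(t), "df": int(df), "p": float(p)}


@dataclass
class SimilarityModels:
    emd_whole: GLMFit
    emd_whole_log: list[dict]
    ba_whole: GLMFit | None
    ba_whole_log: list[dict]
    emd_stages: GLMFit | None = None
    emd_stages_log: list[dict] = field(default_factory=list)
    stage_contrasts: pd.DataFrame | None = None
    emd_periods: GLMFit | None = None
    emd_periods_log: list[dict] = field(default_factory=list)
    period_contrasts: pd.DataFrame | None = None


def _fit_largest(table, response, terms, family, link):
    """Fit dropping trailing terms while the design is rank deficient
    (tiny or degenerate tables; interactions go first)."""
    for k in range(len(terms), -1, -1):
        try:
            return fit_glm(table, response, terms[:k], family=family, link=link)
        except GLMError as err:
            if "rank deficient" not in str(err) or k == 0:
                raise
    raise GLMError("no non-degenerate model")


def whole_migration_models(comparisons: pd.DataFrame, alpha: float = 0.05):
    """Gamma/identity EMD GLM and binomial/log BA GLM on whole-migration pairs.

    Both start with same-individual, departure-difference and their
    interaction, reduced by backwards stepwise deletion.
    """
    terms = ["same_individual", "departure_diff_days", "same_individual:departure_diff_days"]
    full = _fit_largest(comparisons, "emd_km", terms, "gamma", "identity")
    emd_fit, emd_log = stepwise_backward(full, alpha=alpha)
    ba_fit, ba_log = None, []
    if "ba" in comparisons.columns and comparisons["ba"].notna().all():
        tbl = comparisons.copy()
        eps = 1e-6
        tbl["ba"] = tbl["ba"].clip(eps, 1 - eps)
        # the log link is first choice; its MLE can sit on the mu -> 1
        # boundary (near-identical within-individual overlaps), in which
        # case the logit link is the standard fallback
        for link in ("log", "logit"):
            try:
                ba_full = _fit_largest(tbl, "ba", terms, "binomial", link)
                ba_fit, ba_log = stepwise_backward(ba_full, alpha=alpha)
                break
            except GLMError:
                continue
    return emd_fit, emd_log, ba_fit, ba_log


def stage_models(
    stage_comparisons: pd.DataFrame,
    alpha: float = 0.05,
    departure_diff_at: float | None = None,
):
    """Gamma/identity GLM of within-individual stage/period EMD values.

    `stage_label` is categorical with 'whole' as the reference level; the
    Tukey-adjusted pairwise contrasts are evaluated at `departure_diff_at`
    (default: the median departure difference, as in the whole-migration
    predictions).
    """
    tbl = stage_comparisons.copy()
    tbl["stage_label"] = tbl["stage_label"].astype(str)
    # make 'whole' the reference level by ordering (build_design sorts levels)
    tbl["stage_label"] = tbl["stage_label"].map(lambda s: "0whole" if s == "whole" else s)
    terms = ["stage_label", "departure_diff_days", "stage_label:departure_diff_days"]
    full = _fit_largest(tbl, "emd_km", terms, "gamma", "identity")
    fit, log = stepwise_backward(full, alpha=alpha)
    contrasts = None
    if "stage_label" in fit.terms:
        at = {"departure_diff_days": float(
            tbl["departure_diff_days"].median() if departure_diff_at is None else departure_diff_at
        )}
        contrasts = emmeans_tukey(fit, "stage_label", covariate_values=at)
    return fit, log, contrasts


def similarity_models(
    whole: pd.DataFrame,
    stages: pd.DataFrame | None = None,
    periods: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> SimilarityModels:
    emd_fit, emd_log, ba_fit, ba_log = whole_migration_models(whole, alpha=alpha)
    out = SimilarityModels(
        emd_whole=emd_fit, emd_whole_log=emd_log, ba_whole=ba_fit, ba_whole_log=ba_log
    )
    if stages is not None and len(stages):
        out.emd_stages, out.emd_stages_log, out.stage_contrasts = stage_models(stages, alpha)
    if periods is not None and len(periods):
        out.emd_periods, out.emd_periods_log, out.period_contrasts = stage_models(periods, alpha)
    return out


def repeatability_table(estimates: dict[str, RepeatabilityEstimate]) -> pd.DataFrame:
    """Serialise repeatability estimates in the familiar table layout."""
    rows = []
    for name, e in estimates.items():
        rows.append(
            {
                "trait": name,
                "n_ind": e.n_individuals,
                "n_obs": e.n_observations,
                "R": round(e.R, 3),
                "ci_low": round(e.ci_low, 3),
                "ci_high": round(e.ci_high, 3),
                "p": e.p_value,
                "var_among": e.var_among,
                "var_residual": e.var_residual,
            }
        )
    return pd.DataFrame(rows)


def glm_table(fit: GLMFit) -> pd.DataFrame:
    """Estimate ± SE / t / p layout for a fitted GLM."""
    sf = fit.summary_frame().reset_index(names="term")
    sf["estimate"] = sf["estimate"].round(2)
    sf["se"] = sf["se"].round(2)
    sf["stat"] = sf["stat"].round(2)
    return sf
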