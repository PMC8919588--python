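"""Two-state hidden Markov model for daily ashore/at-sea classification.

States emit three conditionally independent features per day: Gaussian
colony distance, Gaussian wet sum, and binomial light interference (count
out of that day's daylight samples). Missing features are marginalised out
of the emission density rather than imputed. Fitting is Baum–Welch EM with
multiple seeded restarts; the state with the smaller mean colony distance is
canonicalised as "ashore", which makes the fit invariant to restart order
and label switching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STATES = ("ashore", "at-sea")


@dataclass
class HMMModel:
    initial: np.ndarray  # (2,)
    transition: np.ndarray  # (2, 2), rows sum to 1
    dist_mean: np.ndarray  # (2,)
    dist_sd: np.ndarray
    wet_mean: np.ndarray
    wet_sd: np.ndarray
    interference_p: np.ndarray  # (2,)
    log_likelihood: float = np.nan

    def __post_init__(self) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.dist_sd <= 0) or np.any(self.wet_sd <= 0):
            raise ValueError("emission SDs must be > 0")
        if np.any((self.interference_p <= 0) | (self.interference_p >= 1)):
            raise ValueError("interference probabilities must be in (0, 1)")


class HMMFitError(RuntimeError):
    pass


def _extract(features: pd.DataFrame):
    dist = features["colony_distance_km"].to_numpy(dtype=float)
    wet = features["wet_sum"].astype("float").to_numpy()
    k = features["interference_count"].astype("float").to_numpy()
    n = features["daylight_sample_count"].astype("float").to_numpy()
    return dist, wet, k, n


def _log_emissions(model: HMMModel, dist, wet, k, n) -> np.ndarray:
    """(T, 2) log emission densities with missing features marginalised."""
    T = len(dist)
    logb = np.zeros((T, 2))
    for s in range(2):
        ok = np.isfinite(dist)
        logb[ok, s] += -0.5 * ((dist[ok] - model.dist_mean[s]) / model.dist_sd[s]) ** 2 - np.log(
            model.dist_sd[s]
        )
        ok = np.isfinite(wet)
        logb[ok, s] += -0.5 * ((wet[ok] - model.wet_mean[s]) / model.wet_sd[s]) ** 2 - np.log(
            model.wet_sd[s]
        )
        ok = np.isfinite(k) & np.isfinite(n) & (n > 0)
        p = model.interference_p[s]
        # binomial log-pmf without the k-choose-n constant (state-independent)
        logb[ok, s] += k[ok] * np.log(p) + (n[ok] - k[ok]) * np.log1p(-p)
    return logb


def forward_backward(model: HMMModel, logb: np.ndarray):
    """Scaled forward-backward. Returns (gamma, xi_sum, log_likelihood)."""
    T = logb.shape[0]
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    pi = model.initial
    A = model.transition
    alpha = np.empty((T, 2))
    cscale = np.empty(T)
    alpha[0] = pi * b[0]
    cscale[0] = alpha[0].sum()
    alpha[0] /= cscale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * b[t]
        cscale[t] = alpha[t].sum()
        alpha[t] /= cscale[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    xi_sum = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        beta[t] = (A * (b[t + 1] * beta[t + 1])[None, :]).sum(axis=1) / cscale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    for t in range(T - 1):
        x = alpha[t][:, None] * A * (b[t + 1] * beta[t + 1])[None, :] / cscale[t + 1]
        xi_sum += x
    loglik = float(np.log(cscale).sum() + logb.max(axis=1).sum())
    return gamma, xi_sum, loglik


def viterbi(model: HMMModel, logb: np.ndarray) -> np.ndarray:
    T = logb.shape[0]
    logA = np.log(model.transition)
    delta = np.log(model.initial) + logb[0]
    back = np.zeros((T, 2), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logb[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _init_model(dist, wet, k, n, rng: np.random.Generator) -> HMMModel:
    """Random-restart initialisation: split days around feature quantiles."""

    def _mom(x, frac):
        x = x[np.isfinite(x)]
        if len(x) == 0:
            return 0.0, 1.0
        q = np.quantile(x, frac)
        return float(q), float(max(np.std(x) * rng.uniform(0.5, 1.5), 1e-3))

    d_lo, d_sd = _mom(dist, rng.uniform(0.05, 0.35))
    d_hi, _ = _mom(dist, rng.uniform(0.65, 0.95))
    w_lo, w_sd = _mom(wet, rng.uniform(0.05, 0.35))
    w_hi, _ = _mom(wet, rng.uniform(0.65, 0.95))
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = k / np.maximum(n, 1.0)
    p_hi = float(np.clip(np.nanquantile(prop, 0.8), 0.05, 0.95))
    p_lo = float(np.clip(np.nanquantile(prop, 0.2), 0.02, p_hi - 0.01))
    return HMMModel(
        initial=np.array([0.5, 0.5]),
        transition=np.array([[0.95, 0.05], [0.05, 0.95]]),
        dist_mean=np.array([d_lo, d_hi]),
        dist_sd=np.array([d_sd, d_sd]),
        wet_mean=np.array([w_lo, w_hi]),
        wet_sd=np.array([w_sd, w_sd]),
        interference_p=np.array([p_hi, p_lo]),
        log_likelihood=np.nan,
    )


def _canonicalize(model: HMMModel) -> HMMModel:
    """State 0 = ashore = smaller mean colony distance."""
    if model.dist_mean[0] <= model.dist_mean[1]:
        return model
    o = [1, 0]
    return HMMModel(
        initial=model.initial[o],
        transition=model.transition[np.ix_(o, o)],
        dist_mean=model.dist_mean[o],
        dist_sd=model.dist_sd[o],
        wet_mean=model.wet_mean[o],
        wet_sd=model.wet_sd[o],
        interference_p=model.interference_p[o],
        log_likelihood=model.log_likelihood,
    )


def fit_hmm(
    features: pd.DataFrame,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_days: int = 60,
) -> HMMModel:
    """Baum–Welch fit of the two-state model; best of `n_restarts` by log-likelihood."""
    if len(features) < min_days:
        raise HMMFitError(f"need >= {min_days} days of features, got {len(features)}")
    dist_raw, wet_raw, k, n = _extract(features)
    # standardise the Gaussian features for EM numerics
    d_loc, d_scl = np.nanmean(dist_raw), max(float(np.nanstd(dist_raw)), 1e-9)
    w_loc, w_scl = np.nanmean(wet_raw), max(float(np.nanstd(wet_raw)), 1e-9)
    dist = (dist_raw - d_loc) / d_scl
    wet = (wet_raw - w_loc) / w_scl

    rng = np.random.default_rng(seed)
    best: HMMModel | None = None
    for _ in range(n_restarts):
        model = _init_model(dist, wet, k, n, rng)
        try:
            model = _em(model, dist, wet, k, n, max_iter, tol)
        except HMMFitError:
            continue
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    if best is None:
        raise HMMFitError("all EM restarts degenerated")
    # back-transform to original feature scale
    out = HMMModel(
        initial=best.initial,
        transition=best.transition,
        dist_mean=best.dist_mean * d_scl + d_loc,
        dist_sd=best.dist_sd * d_scl,
        wet_mean=best.wet_mean * w_scl + w_loc,
        wet_sd=best.wet_sd * w_scl,
        interference_p=best.interference_p,
        log_likelihood=best.log_likelihood,
    )
    return _canonicalize(out)


def _em(model: HMMModel, dist, wet, k, n, max_iter: int, tol: float) -> HMMModel:
    prev = -np.inf
    for _ in range(max_iter):
        logb = _log_emissions(model, dist, wet, k, n)
        gamma, xi_sum, loglik = forward_backward(model, logb)
        w = gamma  # (T, 2)
        new = {}
        for name, x in (("dist", dist), ("wet", wet)):
            ok = np.isfinite(x)
            ws = w[ok]
            denom = ws.sum(axis=0)
            mu = (ws * x[ok, None]).sum(axis=0) / np.maximum(denom, 1e-12)
            var = (ws * (x[ok, None] - mu[None, :]) ** 2).sum(axis=0) / np.maximum(denom, 1e-12)
            sd = np.sqrt(var)
            if np.any(sd < 1e-8):
                raise HMMFitError("degenerate emission (sd -> 0)")
            new[name] = (mu, sd)
        okb = np.isfinite(k) & np.isfinite(n) & (n > 0)
        wb = w[okb]
        p = (wb * k[okb, None]).sum(axis=0) / np.maximum((wb * n[okb, None]).sum(axis=0), 1e-12)
        p = np.clip(p, 1e-6, 1 - 1e-6)
        A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
        A = np.clip(A, 1e-8, None)
        A /= A.sum(axis=1, keepdims=True)
        model = HMMModel(
            initial=np.clip(gamma[0], 1e-8, None) / np.clip(gamma[0], 1e-8, None).sum(),
            transition=A,
            dist_mean=new["dist"][0],
            dist_sd=new["dist"][1],
            wet_mean=new["wet"][0],
            wet_sd=new["wet"][1],
            interference_p=p,
            log_likelihood=loglik,
        )
        if np.isfinite(prev) and abs(loglik - prev) <= tol * max(abs(prev), 1.0):
            break
        prev = loglik
    return model


def decode_states(model: HMMModel, features: pd.DataFrame) -> pd.DataFrame:
    """Viterbi path and per-day posterior state probabilities."""
    dist, wet, k, n = _extract(features)
    logb = _log_emissions(model, dist, wet, k, n)
    gamma, _, _ = forward_backward(model, logb)
    path = viterbi(model, logb)
    return pd.DataFrame(
        {
            "date": pd.to_datetime(features["date"].to_numpy()),
            "state": np.asarray(STATES, dtype=object)[path],
            "p_ashore": gamma[:, 0],
            "p_atsea": gamma[:, 1],
        }
    )
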