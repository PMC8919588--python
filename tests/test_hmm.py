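"""Two-state HMM: exact oracles by path enumeration, EM properties, recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from petrelmig.hmm import (
    HMMModel,
    _log_emissions,
    decode_states,
    fit_hmm,
    forward_backward,
    viterbi,
)


def toy_model():
    return HMMModel(
        initial=np.array([0.7, 0.3]),
        transition=np.array([[0.9, 0.1], [0.2, 0.8]]),
        dist_mean=np.array([10.0, 2000.0]),
        dist_sd=np.array([50.0, 400.0]),
        wet_mean=np.array([5.0, 1300.0]),
        wet_sd=np.array([10.0, 300.0]),
        interference_p=np.array([0.8, 0.1]),
    )


def toy_features(T, seed=0, states=None):
    rng = np.random.default_rng(seed)
    m = toy_model()
    if states is None:
        states = rng.integers(0, 2, T)
    n = np.full(T, 60)
    return (
        pd.DataFrame(
            {
                "date": pd.date_range("2014-01-01", periods=T),
                "colony_distance_km": rng.normal(m.dist_mean[states], m.dist_sd[states]).clip(0),
                "wet_sum": rng.normal(m.wet_mean[states], m.wet_sd[states]).clip(0).astype(int),
                "interference_count": rng.binomial(n, m.interference_p[states]),
                "daylight_sample_count": n,
            }
        ),
        np.asarray(states),
    )


def brute_force_posteriors(model, logb):
    """Exact state posteriors and Viterbi path by 2^T enumeration."""
    T = logb.shape[0]
    logA = np.log(model.transition)
    logpi = np.log(model.initial)
    best_lp, best_path = -np.inf, None
    total = -np.inf
    logpost = np.full((T, 2), -np.inf)
    for path in itertools.product((0, 1), repeat=T):
        lp = logpi[path[0]] + logb[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logb[t, path[t]]
        total = np.logaddexp(total, lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
        for t in range(T):
            logpost[t, path[t]] = np.logaddexp(logpost[t, path[t]], lp)
    return np.exp(logpost - total), np.array(best_path), total


def test_forward_backward_matches_enumeration():
    feats, _ = toy_features(8, seed=1)
    m = toy_model()
    logb = _log_emissions(
        m,
        feats["colony_distance_km"].to_numpy(float),
        feats["wet_sum"].to_numpy(float),
        feats["interference_count"].to_numpy(float),
        feats["daylight_sample_count"].to_numpy(float),
    )
    gamma, _, loglik = forward_backward(m, logb)
    post_ref, _, total_ref = brute_force_posteriors(m, logb)
    np.testing.assert_allclose(gamma, post_ref, atol=1e-10)
    assert loglik == pytest.approx(total_ref, abs=1e-10)


def test_viterbi_matches_enumeration():
    for seed in (2, 3, 4):
        feats, _ = toy_features(5, seed=seed)
        m = toy_model()
        logb = _log_emissions(
            m,
            feats["colony_distance_km"].to_numpy(float),
            feats["wet_sum"].to_numpy(float),
            feats["interference_count"].to_numpy(float),
            feats["daylight_sample_count"].to_numpy(float),
        )
        _, ref_path, _ = brute_force_posteriors(m, logb)
        np.testing.assert_array_equal(viterbi(m, logb), ref_path)


def test_em_loglikelihood_monotone():
    states = np.r_[np.zeros(40, int), np.ones(60, int), np.zeros(30, int)]
    feats, _ = toy_features(130, seed=5, states=states)
    from petrelmig.hmm import _em, _extract, _init_model

    dist, wet, k, n = _extract(feats)
    rng = np.random.default_rng(0)
    model = _init_model(dist, wet, k, n, rng)
    lls = []
    for _ in range(30):
        logb = _log_emissions(model, dist, wet, k, n)
        _, _, ll = forward_backward(model, logb)
        lls.append(ll)
        model = _em(model, dist, wet, k, n, max_iter=1, tol=0.0)
    assert all(b >= a - 1e-7 for a, b in zip(lls, lls[1:]))


def test_decoding_accuracy_on_separated_features():
    states = np.r_[np.zeros(50, int), np.ones(170, int), np.zeros(40, int)]
    feats, truth = toy_features(260, seed=6, states=states)
    model = fit_hmm(feats, n_restarts=4, seed=0)
    decoded = decode_states(model, feats)
    acc = (np.where(decoded["state"] == "at-sea", 1, 0) == truth).mean()
    assert acc >= 0.98


def test_posteriors_sum_to_one_and_missing_marginalised():
    feats, _ = toy_features(60, seed=7)
    feats.loc[5:10, "colony_distance_km"] = np.nan
    feats.loc[20:22, "interference_count"] = pd.NA
    model = fit_hmm(feats, n_restarts=3, seed=1)
    dec = decode_states(model, feats)
    np.testing.assert_allclose(dec["p_ashore"] + dec["p_atsea"], 1.0, atol=1e-12)


def test_canonical_labels_smaller_distance_is_ashore():
    states = np.r_[np.zeros(60, int), np.ones(120, int)]
    for seed in range(3):
        feats, _ = toy_features(180, seed=seed, states=states)
        model = fit_hmm(feats, n_restarts=3, seed=seed)
        assert model.dist_mean[0] < model.dist_mean[1]


def test_affine_rescaling_leaves_path_unchanged():
    states = np.r_[np.zeros(50, int), np.ones(100, int), np.zeros(30, int)]
    feats, _ = toy_features(180, seed=9, states=states)
    big = feats.copy()
    big["colony_distance_km"] = big["colony_distance_km"] * 1000.0
    p1 = decode_states(fit_hmm(feats, n_restarts=3, seed=2), feats)["state"]
    p2 = decode_states(fit_hmm(big, n_restarts=3, seed=2), big)["state"]
    assert (p1 == p2).all()


def test_all_ashore_single_state_path():
    feats, _ = toy_features(80, seed=10, states=np.zeros(80, int))
    model = toy_model()
    dec = decode_states(model, feats)
    assert set(dec["state"]) == {"ashore"}
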