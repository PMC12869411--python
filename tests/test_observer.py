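"""Unit tests for the two-stage search/decision observer."""

import dataclasses
from itertools import chain, combinations

import numpy as np
import pytest

from vsmo.features import ClassStats, estimate_class_stats, whitened_delta
from vsmo.lroc import SENTINEL_RATING
from vsmo.observer import (
    BranchStats,
    FittedObserver,
    ImageRating,
    ObserverConfig,
    ThresholdSet,
    _prune_candidates,
    extract_case_features,
    fit_branch_statistics,
    fit_observer,
    fit_thresholds,
    make_observer,
    rate_dataset,
    rate_image,
    score_cases,
    score_feature_vector,
    search_candidates,
)


def _stats(delta, K, base=None):
    delta = np.asarray(delta, dtype=float)
    lo = np.zeros_like(delta) if base is None else np.asarray(base, dtype=float)
    return ClassStats(
        d_present=lo + delta,
        d_absent=lo,
        k_matrix=np.asarray(K, dtype=float),
        n_present=10,
        n_absent=10,
    )


# ---------------------------------------------------------------------------
# ThresholdSet / branch combinatorics
# ---------------------------------------------------------------------------


def test_unthresholded_set_is_all_minus_inf():
    ts = ThresholdSet.unthresholded(3)
    assert len(ts) == 3
    assert np.all(np.isneginf(ts.thresholds))


def _nonempty_subsets(k):
    return [
        tuple(s) for s in chain.from_iterable(combinations(range(k), r) for r in range(1, k + 1))
    ]


def test_all_seven_branches_for_three_features():
    # two present and two absent training rows per survival pattern, so every
    # one of the 2^3 - 1 nonempty branches is occupied without fallback
    subsets = _nonempty_subsets(3)
    rows, labels = [], []
    for si, sub in enumerate(subsets):
        for val, lab in ((1.0, True), (2.0, True), (1.2, False), (1.8, False)):
            r = np.full(3, -1.0)
            r[list(sub)] = val + 0.01 * si
            rows.append(r)
            labels.append(lab)
    X = np.array(rows)
    labels = np.array(labels)
    branches = fit_branch_statistics(X, labels, ThresholdSet(np.zeros(3)))
    assert set(branches) == set(subsets)
    for key, br in branches.items():
        assert br.branch_key == key
        assert not br.from_fallback
        assert br.stats.delta_d.size == len(key)


def test_sparse_branch_falls_back_to_marginal():
    X = np.array(
        [
            [1.0, 1.0],
            [2.0, 2.0],
            [1.1, 1.2],
            [1.9, 1.8],
            [3.0, -1.0],  # lone case surviving only on feature 0
        ]
    )
    labels = np.array([True, True, False, False, True])
    branches = fit_branch_statistics(X, labels, ThresholdSet(np.zeros(2)))
    assert branches[(0, 1)].from_fallback is False
    assert branches[(0,)].from_fallback is True
    marginal = estimate_class_stats(X[labels], X[~labels]).subset([0])
    assert np.allclose(branches[(0,)].stats.delta_d, marginal.delta_d)


def test_unthresholded_fit_yields_single_full_branch():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 3))
    labels = np.array([True] * 6 + [False] * 6)
    branches = fit_branch_statistics(X, labels, ThresholdSet.unthresholded(3))
    assert set(branches) == {(0, 1, 2)}


# ---------------------------------------------------------------------------
# score_feature_vector
# ---------------------------------------------------------------------------


def test_score_is_sentinel_when_all_features_subthreshold():
    stats = _stats([1.0, 1.0], np.eye(2))
    branches = {(0, 1): BranchStats((0, 1), stats)}
    ts = ThresholdSet(np.array([5.0, 5.0]))
    val = score_feature_vector(np.array([1.0, 2.0]), ts, branches, "prewhitening", stats)
    assert val == SENTINEL_RATING


def test_disabled_thresholds_reduce_to_plain_discriminant():
    stats = _stats([2.0, -1.0], [[2.0, 0.3], [0.3, 1.0]], base=[0.5, 0.2])
    branches = {(0, 1): BranchStats((0, 1), stats)}
    ts = ThresholdSet.unthresholded(2)
    d = np.array([0.7, -0.4])
    for mode in ("prewhitening", "nonprewhitening"):
        w = whitened_delta(stats) if mode == "prewhitening" else stats.delta_d
        expected = w @ d - 0.5 * w @ (stats.d_present + stats.d_absent)
        got = score_feature_vector(d, ts, branches, mode, stats)
        assert got == pytest.approx(expected, rel=1e-10)


def test_pw_and_npw_agree_under_identity_covariance():
    stats = _stats([1.5, -0.5, 2.0], np.eye(3))
    branches = {(0, 1, 2): BranchStats((0, 1, 2), stats)}
    ts = ThresholdSet.unthresholded(3)
    rng = np.random.default_rng(1)
    for _ in range(10):
        d = rng.normal(size=3)
        pw = score_feature_vector(d, ts, branches, "prewhitening", stats)
        npw = score_feature_vector(d, ts, branches, "nonprewhitening", stats)
        assert pw == pytest.approx(npw, rel=1e-4)


def test_score_feature_vector_unseen_branch_uses_fallback():
    # branch dict lacks (1,): scoring must fall back to the marginal subset
    stats = _stats([1.0, 3.0], np.eye(2))
    branches = {}
    ts = ThresholdSet(np.array([10.0, 0.0]))
    d = np.array([5.0, 2.0])  # survives only on feature 1
    sub = stats.subset([1])
    w = whitened_delta(sub)
    expected = w @ d[[1]] - 0.5 * w @ (sub.d_present + sub.d_absent)
    got = score_feature_vector(d, ts, branches, "prewhitening", stats)
    assert got == pytest.approx(float(expected), rel=1e-10)
    with pytest.raises(ValueError):
        score_feature_vector(np.zeros(3), ts, branches, "prewhitening", stats)


# ---------------------------------------------------------------------------
# search_candidates
# ---------------------------------------------------------------------------


def _one_feature_maps(stat):
    return stat[None, :, :]


_UNIT_STATS = ClassStats(
    d_present=np.array([1.0]),
    d_absent=np.array([0.0]),
    k_matrix=np.eye(1),
    n_present=10,
    n_absent=10,
)


def _peaky_map(peaks, size=24, seed=0):
    rng = np.random.default_rng(seed)
    stat = rng.normal(scale=1e-6, size=(size, size))
    for (r, c), v in peaks.items():
        stat[r, c] = v
    return stat


def test_search_candidates_ranked_and_separated():
    cfg = ObserverConfig(
        mode="nonprewhitening", border_px=2, min_separation_px=3.0, max_candidates=10
    )
    stat = _peaky_map({(5, 5): 1.0, (5, 7): 0.9, (15, 15): 0.8})
    cands = search_candidates(_one_feature_maps(stat), _UNIT_STATS, cfg)
    locs = [c.location for c in cands[:2]]
    # (5,7) lies within 3 px of the stronger (5,5) peak and must be skipped
    assert locs == [(5, 5), (15, 15)]
    assert (5, 7) not in [c.location for c in cands]
    scores = [c.search_score for c in cands]
    assert scores == sorted(scores, reverse=True)
    assert cands[0].search_score == pytest.approx(1.0)


def test_search_candidates_respect_border_and_cap():
    cfg = ObserverConfig(
        mode="nonprewhitening", border_px=4, min_separation_px=0.0, max_candidates=2
    )
    stat = _peaky_map({(1, 1): 5.0, (10, 10): 1.0, (10, 18): 0.9, (18, 10): 0.8})
    cands = search_candidates(_one_feature_maps(stat), _UNIT_STATS, cfg)
    assert len(cands) == 2  # capped
    assert (1, 1) not in [c.location for c in cands]  # inside the border margin
    assert [c.location for c in cands] == [(10, 10), (10, 18)]


def test_search_candidates_rejects_bad_maps():
    cfg = ObserverConfig()
    with pytest.raises(ValueError):
        search_candidates(np.zeros((16, 16)), _UNIT_STATS, cfg)
    with pytest.raises(ValueError):
        search_candidates(np.zeros((0, 16, 16)), _UNIT_STATS, cfg)


# ---------------------------------------------------------------------------
# threshold fitting
# ---------------------------------------------------------------------------


def test_empty_percentile_grid_disables_all_thresholds():
    cfg = ObserverConfig(threshold_grid_percentiles=())
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 2))
    labels = np.array([True] * 10 + [False] * 10)
    ts = fit_thresholds(X, labels, labels.copy(), cfg)
    assert np.all(np.isneginf(ts.thresholds))


def test_fitted_threshold_excludes_a_pure_noise_feature():
    # feature 0 is informative (N(3,1) vs N(0,1)); feature 1 is N(0,1) noise in
    # both classes.  With a finite sample any single threshold draw is noisy,
    # so assert on the median excluded fraction across fixed seeds.
    cfg = ObserverConfig()
    n = 60
    excluded = []
    for seed in range(12):
        rng = np.random.default_rng(seed)
        half = n // 2
        X = np.column_stack(
            [
                np.concatenate([rng.normal(3.0, 1.0, half), rng.normal(0.0, 1.0, half)]),
                rng.normal(0.0, 1.0, n),
            ]
        )
        labels = np.array([True] * half + [False] * half)
        ts = fit_thresholds(X, labels, labels.copy(), cfg)
        excluded.append(np.mean(X[:, 1] <= ts.thresholds[1]))
    assert float(np.median(excluded)) >= 0.5


# ---------------------------------------------------------------------------
# candidate pruning by the stage-1 threshold
# ---------------------------------------------------------------------------


def test_prune_candidates_keeps_the_best_of_each_image():
    mats = [np.arange(6.0).reshape(3, 2), np.arange(4.0).reshape(2, 2)]
    scores = [np.array([3.0, 2.0, 1.0]), np.array([0.4, 0.6])]
    flags = [np.array([True, False, False]), np.array([False, True])]
    pm, pf, ps = _prune_candidates(mats, scores, flags, 1.5)
    assert np.array_equal(ps[0], [3.0, 2.0])  # 1.0 pruned
    assert np.array_equal(pm[0], mats[0][:2])
    # image 2: everything below threshold, but its best candidate survives
    assert np.array_equal(ps[1], [0.6])
    assert np.array_equal(pf[1], [True])
    # -inf is a no-op
    pm, pf, ps = _prune_candidates(mats, scores, flags, float("-inf"))
    assert all(np.array_equal(a, b) for a, b in zip(pm, mats))


# ---------------------------------------------------------------------------
# config and rating invariants
# ---------------------------------------------------------------------------


def test_observer_config_validation():
    with pytest.raises(ValueError):
        ObserverConfig(mode="hotelling")
    with pytest.raises(ValueError):
        ObserverConfig(threshold_stage="never")
    with pytest.raises(ValueError):
        ObserverConfig(stage1_top_k=0)
    with pytest.raises(ValueError):
        ObserverConfig(max_candidates=0)
    with pytest.raises(ValueError):
        ObserverConfig(min_separation_px=-1.0)


def test_image_rating_invariant():
    with pytest.raises(ValueError):
        ImageRating(rating=1.0, reported_location=None, candidates=())
    with pytest.raises(ValueError):
        ImageRating(rating=SENTINEL_RATING, reported_location=(1, 2), candidates=())


# ---------------------------------------------------------------------------
# end-to-end pipeline on the small simulated datasets
# ---------------------------------------------------------------------------


def test_thresholded_with_everything_disabled_equals_unthresholded(
    fitted_base, tiny_test_dataset
):
    # stage1_top_k=None, search threshold -inf, all decision thresholds -inf
    # and the unthresholded branch statistics: the thresholded code path must
    # reproduce the unthresholded ratings exactly
    unthr = make_observer(fitted_base, thresholded=False)
    cfg = dataclasses.replace(fitted_base.config, stage1_top_k=None)
    base = dataclasses.replace(fitted_base, config=cfg)
    manual = FittedObserver(
        base=base,
        thresholds=ThresholdSet.unthresholded(len(unthr.thresholds)),
        branches=unthr.branches,
        thresholded=True,
    )
    ra = rate_dataset(tiny_test_dataset, unthr)
    rb = rate_dataset(tiny_test_dataset, manual)
    for a, b in zip(ra, rb):
        assert a.rating == pytest.approx(b.rating, rel=1e-12)
        assert a.reported_location == b.reported_location


def test_rate_image_is_deterministic_and_consistent_with_rate_dataset(
    fitted_base, tiny_test_dataset
):
    obs = make_observer(fitted_base, thresholded=False)
    records = rate_dataset(tiny_test_dataset, obs)
    assert len(records) == len(tiny_test_dataset)
    for img, rec in zip(tiny_test_dataset.images, records):
        r1 = rate_image(img, obs)
        r2 = rate_image(img, obs)
        assert r1.rating == r2.rating and r1.reported_location == r2.reported_location
        assert r1.rating == pytest.approx(rec.rating, rel=1e-12)
        assert r1.reported_location == rec.reported_location
        assert (r1.reported_location is None) == (r1.rating == SENTINEL_RATING)


def test_score_cases_matches_rate_dataset_for_thresholded_variant(
    fitted_base, tiny_test_dataset
):
    obs = make_observer(fitted_base, thresholded=True)
    assert len(obs.thresholds) == fitted_base.config.n_decision_features
    via_cases = score_cases(extract_case_features(tiny_test_dataset, fitted_base), obs)
    direct = rate_dataset(tiny_test_dataset, obs)
    for a, b in zip(via_cases, direct):
        assert a.rating == pytest.approx(b.rating, rel=1e-12)
        assert a.reported_location == b.reported_location


def test_fit_observer_end_to_end_smoke(tiny_dataset, tiny_test_dataset, small_bank, small_config):
    for thresholded in (False, True):
        obs = fit_observer(tiny_dataset, small_bank, small_config, thresholded=thresholded)
        assert obs.thresholded is thresholded
        records = rate_dataset(tiny_test_dataset, obs)
        assert len(records) == len(tiny_test_dataset)
        for rec in records:
            assert rec.truth_label == (rec.true_center is not None)
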