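"""Unit tests for class statistics, detectability and feature selection."""

import numpy as np
import pytest

from vsmo.features import (
    ClassStats,
    FeaturePairRule,
    auc_from_snr,
    estimate_class_stats,
    greedy_forward_select,
    pair_performance_curve,
    refine_bank,
    snr_squared,
)


def _stats(delta, K):
    delta = np.asarray(delta, dtype=float)
    return ClassStats(
        d_present=delta,
        d_absent=np.zeros_like(delta),
        k_matrix=np.asarray(K, dtype=float),
        n_present=10,
        n_absent=10,
    )


def test_estimate_class_stats_small_example():
    s = estimate_class_stats(np.array([[2.0], [4.0]]), np.array([[0.0], [2.0]]))
    assert s.delta_d[0] == pytest.approx(2.0)
    assert s.k_matrix[0, 0] == pytest.approx(2.0)  # pooled var of {2,4} and {0,2}
    assert (s.n_present, s.n_absent) == (2, 2)


def test_estimate_class_stats_validation():
    with pytest.raises(ValueError):
        estimate_class_stats(np.array([[1.0]]), np.array([[0.0], [1.0]]))
    with pytest.raises(ValueError):
        estimate_class_stats(np.ones((3, 2)), np.ones((3, 3)))


def test_snr_identity_covariance():
    assert snr_squared(_stats([3.0, 4.0], np.eye(2)), ridge=0.0) == pytest.approx(25.0)


def test_snr_affine_invariance():
    rng = np.random.default_rng(4)
    P = rng.normal(loc=1.0, size=(200, 3))
    A = rng.normal(loc=0.0, size=(200, 3))
    base = snr_squared(estimate_class_stats(P, A), ridge=0.0)
    for _ in range(5):
        M = rng.normal(size=(3, 3))
        while abs(np.linalg.det(M)) < 1e-2:
            M = rng.normal(size=(3, 3))
        t = snr_squared(estimate_class_stats(P @ M.T, A @ M.T), ridge=0.0)
        assert t == pytest.approx(base, rel=1e-8)


def test_pair_curve_closed_forms():
    s = 1.7
    for rho in (-0.5, 0.0, 0.3, 0.9):
        snr = pair_performance_curve(s, s, [rho])[0]
        assert snr**2 == pytest.approx(2 * s**2 / (1 + rho), rel=1e-12)
    # uncorrelated features add in quadrature
    snr = pair_performance_curve(1.0, 2.0, [0.0])[0]
    assert snr**2 == pytest.approx(5.0)
    # a zero-SNR partner never hurts
    assert pair_performance_curve(2.0, 0.0, [0.5])[0] >= 2.0


def test_pair_curve_validation():
    with pytest.raises(ValueError):
        pair_performance_curve(1.0, 1.0, [1.0])
    with pytest.raises(ValueError):
        pair_performance_curve(-1.0, 1.0, [0.0])


def test_fig1_pairing_rule():
    # fixed larger SNR s, partner either s (equal) or s/2 (different): the
    # equal pair wins at low correlation, the different pair at high
    s = 2.0
    lo, hi = 0.2, 0.85
    equal = pair_performance_curve(s, s, [lo, hi])
    unequal = pair_performance_curve(s, s / 2, [lo, hi])
    assert equal[0] > unequal[0]
    assert unequal[1] > equal[1]


def test_auc_from_snr():
    assert auc_from_snr(0.0) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        auc_from_snr(-0.1)
    # monotone and saturating
    assert auc_from_snr(1.0) < auc_from_snr(2.0) < 1.0


def test_auc_matches_monte_carlo_shifted_normals():
    snr = 1.3
    rng = np.random.default_rng(5)
    n = 100_000
    x_a = rng.normal(0.0, 1.0, n)
    x_p = rng.normal(snr, 1.0, n)
    mc = np.mean(x_p > x_a) + 0.5 * np.mean(x_p == x_a)
    assert auc_from_snr(snr) == pytest.approx(mc, abs=0.005)


def _exhaustive_best_subset(snr, corr, k):
    from itertools import combinations

    from vsmo.features import _subset_snr2

    best, best_val = None, -np.inf
    for sub in combinations(range(len(snr)), k):
        v = _subset_snr2(np.asarray(snr, float), np.asarray(corr, float), list(sub))
        if v > best_val + 1e-12:
            best, best_val = set(sub), v
    return best, best_val


def test_refine_bank_matches_exhaustive_on_toy():
    snr = np.array([2.0, 1.5, 0.3, 1.4])
    corr = np.array(
        [
            [1.0, 0.9, 0.0, 0.1],
            [0.9, 1.0, 0.0, 0.1],
            [0.0, 0.0, 1.0, 0.0],
            [0.1, 0.1, 0.0, 1.0],
        ]
    )
    chosen = refine_bank(snr, corr, FeaturePairRule(target_bank_size=2))
    best, _ = _exhaustive_best_subset(snr, corr, 2)
    assert set(chosen) == best


def test_refine_bank_validation():
    snr = np.ones(3)
    with pytest.raises(ValueError):
        refine_bank(snr, np.eye(4))
    bad = np.eye(3)
    bad[0, 1] = 0.5  # asymmetric
    with pytest.raises(ValueError):
        refine_bank(snr, bad)
    nod = np.eye(3)
    nod[1, 1] = 0.9  # non-unit diagonal
    with pytest.raises(ValueError):
        refine_bank(snr, nod)
    with pytest.raises(ValueError):
        refine_bank(snr, np.eye(3), FeaturePairRule(target_bank_size=4))


def test_greedy_forward_select_matches_exhaustive_on_toy():
    snr = np.array([1.0, 2.0, 1.9, 0.2, 1.2])
    corr = np.eye(5)
    corr[1, 2] = corr[2, 1] = 0.95

    from vsmo.features import _subset_snr2

    def objective(subset):
        return _subset_snr2(snr, corr, list(subset))

    chosen = greedy_forward_select(5, 2, objective)
    best, _ = _exhaustive_best_subset(snr, corr, 2)
    assert set(chosen) == best


def test_greedy_forward_select_tie_goes_to_lowest_index():
    chosen = greedy_forward_select(4, 2, lambda s: 1.0)
    assert chosen == (0, 1)
    with pytest.raises(ValueError):
        greedy_forward_select(2, 3, lambda s: 0.0)


def test_class_stats_subset():
    s = _stats([1.0, 2.0, 3.0], np.diag([1.0, 4.0, 9.0]))
    sub = s.subset([2, 0])
    assert np.allclose(sub.delta_d, [3.0, 1.0])
    assert np.allclose(sub.k_matrix, np.diag([9.0, 1.0]))
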