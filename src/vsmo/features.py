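"""Class statistics, Hotelling SNR, AUC mapping, and feature-bank refinement.

For feature vectors d with class means d_present and d_absent and a common
covariance K, the linear-discriminant detectability is

    SNR^2 = (d_present - d_absent)^T K^{-1} (d_present - d_absent)

and, under equal-covariance Gaussian statistics,

    AUC = Phi(SNR / sqrt(2)) = (1 + erf(SNR / 2)) / 2

with Phi the standard normal CDF.  These two identities drive everything in
this module: estimating class statistics, scoring feature subsets, reducing a
large Gabor bank to a small working bank, and choosing stage-specific feature
sets for the two-stage search observer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "ClassStats",
    "FeaturePairRule",
    "StageAssignment",
    "estimate_class_stats",
    "snr_squared",
    "auc_from_snr",
    "pair_performance_curve",
    "refine_bank",
    "greedy_forward_select",
    "select_stage_features",
]


@dataclass(frozen=True)
class ClassStats:
    """Per-class feature means and the pooled covariance of a two-class task."""

    d_present: np.ndarray
    d_absent: np.ndarray
    k_matrix: np.ndarray
    n_present: int
    n_absent: int

    @property
    def delta_d(self) -> np.ndarray:
        return self.d_present - self.d_absent

    @property
    def dim(self) -> int:
        return self.d_present.size

    def subset(self, indices: Sequence[int]) -> "ClassStats":
        """Statistics restricted to a subset of features."""
        idx = np.asarray(indices, dtype=int)
        return ClassStats(
            d_present=self.d_present[idx],
            d_absent=self.d_absent[idx],
            k_matrix=self.k_matrix[np.ix_(idx, idx)],
            n_present=self.n_present,
            n_absent=self.n_absent,
        )


@dataclass(frozen=True)
class FeaturePairRule:
    """Rule-of-thumb for pairing features during bank refinement: prefer
    similar-SNR partners at low correlation (< low_corr_cutoff) and
    dissimilar-SNR partners at high correlation (> high_corr_cutoff)."""

    low_corr_cutoff: float = 0.3
    high_corr_cutoff: float = 0.8
    target_bank_size: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_corr_cutoff < self.high_corr_cutoff <= 1.0:
            raise ValueError("need 0 <= low_corr_cutoff < high_corr_cutoff <= 1")
        if self.target_bank_size < 1:
            raise ValueError("target_bank_size must be >= 1")


@dataclass(frozen=True)
class StageAssignment:
    """Feature indices (into the refined bank) used by each observer stage."""

    search_indices: tuple[int, ...]
    decision_indices: tuple[int, ...]


def estimate_class_stats(
    present_features: np.ndarray, absent_features: np.ndarray
) -> ClassStats:
    """Class means and the degrees-of-freedom-pooled sample covariance.

    Rows are cases, columns features; both classes need >= 2 cases and equal
    dimensionality.  The covariance is assumed common to both classes, so the
    two class-centered scatter matrices are pooled.
    """
    P = np.atleast_2d(np.asarray(present_features, dtype=float))
    A = np.atleast_2d(np.asarray(absent_features, dtype=float))
    if P.shape[1] != A.shape[1]:
        raise ValueError("present and absent features must share dimensionality")
    n1, n2 = P.shape[0], A.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per class to pool a covariance")
    mp, ma = P.mean(axis=0), A.mean(axis=0)
    Sp = np.cov(P, rowvar=False, ddof=1).reshape(P.shape[1], P.shape[1])
    Sa = np.cov(A, rowvar=False, ddof=1).reshape(A.shape[1], A.shape[1])
    K = ((n1 - 1) * Sp + (n2 - 1) * Sa) / (n1 + n2 - 2)
    return ClassStats(d_present=mp, d_absent=ma, k_matrix=K, n_present=n1, n_absent=n2)


def default_ridge(k_matrix: np.ndarray) -> float:
    """Stabilizing ridge for small-sample covariance inversion."""
    k_matrix = np.atleast_2d(k_matrix)
    return 1e-6 * np.trace(k_matrix) / k_matrix.shape[0]


def whitened_delta(stats: ClassStats, ridge: Optional[float] = None) -> np.ndarray:
    """The prewhitening weight vector w = (K + ridge*I)^{-1} delta_d."""
    K = np.atleast_2d(stats.k_matrix)
    lam = default_ridge(K) if ridge is None else ridge
    Kr = K + lam * np.eye(K.shape[0])
    try:
        return np.linalg.solve(Kr, stats.delta_d)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance singular even after ridge {lam:g}: {exc}"
        ) from exc


def snr_squared(stats: ClassStats, ridge: Optional[float] = None) -> float:
    """Hotelling detectability SNR^2 = delta_d^T (K + ridge*I)^{-1} delta_d."""
    val = float(stats.delta_d @ whitened_delta(stats, ridge))
    return max(val, 0.0)


def auc_from_snr(snr: float) -> float:
    """Map a detectability SNR to the AUC of the matched binormal ROC."""
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    return 0.5 * (1.0 + erf(snr / 2.0))


def pair_performance_curve(
    s1: float, s2: float, rho_grid: Sequence[float]
) -> np.ndarray:
    """Combined SNR of a two-feature discriminant versus feature correlation.

    Features have individual SNRs ``s1``, ``s2`` and correlation rho; in
    standardized coordinates delta_d = (s1, s2) and K = [[1, rho], [rho, 1]],
    so SNR^2 = (s1^2 + s2^2 - 2 rho s1 s2) / (1 - rho^2).

    Holding the larger SNR fixed and varying the partner, an equal-SNR pair
    outperforms an unequal pair at low correlation, while at high correlation
    the unequal pair wins — the crossover for partner ratio r sits at
    rho = (1 + r)/2.  (Holding the *total* single-feature SNR^2 fixed instead,
    the unequal pair dominates for every positive rho.)
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("individual SNRs must be nonnegative")
    rho = np.asarray(rho_grid, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    snr2 = (s1**2 + s2**2 - 2.0 * rho * s1 * s2) / (1.0 - rho**2)
    return np.sqrt(np.maximum(snr2, 0.0))


def _subset_snr2(snr: np.ndarray, corr: np.ndarray, subset: Sequence[int]) -> float:
    """Combined SNR^2 of a subset from per-feature SNRs and their correlation
    matrix (features standardized to unit variance)."""
    idx = np.asarray(subset, dtype=int)
    s = snr[idx]
    R = corr[np.ix_(idx, idx)] + default_ridge(corr[np.ix_(idx, idx)]) * np.eye(idx.size)
    return float(s @ np.linalg.solve(R, s))


def refine_bank(
    per_feature_snr: Sequence[float],
    correlation_matrix: np.ndarray,
    rule: FeaturePairRule = FeaturePairRule(),
) -> list[int]:
    """Reduce a feature bank by greedy forward selection on combined SNR^2.

    At each step the feature whose addition maximizes the retained set's
    combined SNR^2 is appended.  Near-ties are broken by the pairing
    rule-of-thumb — among tied candidates whose correlation with the retained
    set is below ``low_corr_cutoff`` prefer the one with SNR closest to the
    retained features' mean SNR, above ``high_corr_cutoff`` the one farthest
    from it — and finally by lowest index, so the output is deterministic.
    """
    snr = np.asarray(per_feature_snr, dtype=float)
    corr = np.atleast_2d(np.asarray(correlation_matrix, dtype=float))
    n = snr.size
    if corr.shape != (n, n):
        raise ValueError("correlation matrix shape must match the SNR vector")
    if not np.allclose(corr, corr.T, atol=1e-8) or not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric with unit diagonal")
    target = rule.target_bank_size
    if target > n:
        raise ValueError(f"target bank size {target} exceeds bank size {n}")
    retained: list[int] = []
    remaining = list(range(n))
    while len(retained) < target:
        gains = np.array([_subset_snr2(snr, corr, retained + [j]) for j in remaining])
        best = gains.max()
        tied = [j for j, g in zip(remaining, gains) if g >= best * (1.0 - 1e-9)]
        if len(tied) > 1 and retained:
            mean_snr = snr[retained].mean()
            def _rule_key(j: int) -> tuple:
                cmax = float(np.abs(corr[j, retained]).max())
                gap = abs(snr[j] - mean_snr)
                if cmax < rule.low_corr_cutoff:
                    return (gap, j)  # prefer similar-SNR partners
                if cmax > rule.high_corr_cutoff:
                    return (-gap, j)  # prefer dissimilar-SNR partners
                return (0.0, j)
            choice = min(tied, key=_rule_key)
        else:
            choice = min(tied)
        retained.append(choice)
        remaining.remove(choice)
    return retained


def greedy_forward_select(
    n_candidates: int,
    k: int,
    objective: Callable[[tuple[int, ...]], float],
) -> tuple[int, ...]:
    """Greedy forward selection of ``k`` of ``n_candidates`` features
    maximizing ``objective(subset)``; ties go to the lowest index."""
    if k > n_candidates:
        raise ValueError(f"cannot select {k} features from {n_candidates}")
    chosen: list[int] = []
    remaining = list(range(n_candidates))
    for _ in range(k):
        scores = [objective(tuple(chosen + [j])) for j in remaining]
        best = max(scores)
        pick = min(j for j, s in zip(remaining, scores) if s >= best - 1e-12)
        chosen.append(pick)
        remaining.remove(pick)
    return tuple(chosen)


def select_stage_features(
    n_features: int,
    k: int,
    objective: Callable[[tuple[int, ...]], float],
) -> tuple[int, ...]:
    """Choose ``k`` stage features by greedy forward selection on a stage
    objective evaluated on training data: candidate-hit rate for the search
    stage, training LROC area for the decision stage (the caller supplies the
    objective closure; see :mod:`vsmo.observer` for the two stage objectives).
    """
    return greedy_forward_select(n_features, k, objective)
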