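"""Two-stage visual-search model observer with per-feature thresholding.

The observer mimics how a human reader works through an image:

1. **Search stage.** A pixelwise linear statistic over a small set of search
   features flags salient locations.  Its local maxima, ranked by score and
   pruned for minimum separation and image borders, become the candidate list
   — the handful of spots a reader would fixate.
2. **Decision stage.** At each candidate a second, independently chosen small
   feature set is extracted.  Each decision feature carries a lower threshold
   fitted on training data; feature values below threshold are discarded.
   The surviving subset selects its own *branch* linear discriminant (for k
   features there are at most 2^k - 1 nonempty subsets, each with class
   statistics estimated from the training cases that landed in that branch).
   A candidate whose every feature falls below threshold scores the sentinel
   rating; an image with no surviving candidate is called lesion-absent with
   the sentinel rating and no reported location.

Both stages run prewhitened (w = K^-1 delta_d) or nonprewhitened
(w = delta_d).  Thresholding acts as an online feature selector: it removes
low-salience responses before they reach the discriminant, which both helps
performance in noise and stabilizes training with few images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import maximum_filter

from .features import (
    ClassStats,
    StageAssignment,
    estimate_class_stats,
    greedy_forward_select,
    whitened_delta,
)
from .gabor import BankCorrelator, FilterBank
from .lroc import SENTINEL_RATING, CaseRecord, lroc_auc_from_arrays
from .phantoms import Dataset, ProjectionImage

__all__ = [
    "ThresholdSet",
    "BranchStats",
    "Candidate",
    "ObserverConfig",
    "ImageRating",
    "FittedObserver",
    "search_candidates",
    "fit_thresholds",
    "fit_search_threshold",
    "fit_branch_statistics",
    "score_feature_vector",
    "rate_image",
    "fit_observer",
    "fit_observer_base",
    "make_observer",
    "extract_case_features",
    "score_cases",
    "rate_dataset",
]


@dataclass(frozen=True)
class ThresholdSet:
    """One lower bound per decision feature; -inf disables a threshold."""

    thresholds: np.ndarray

    def __len__(self) -> int:
        return self.thresholds.size

    @classmethod
    def unthresholded(cls, k: int) -> "ThresholdSet":
        return cls(np.full(k, -np.inf))


@dataclass(frozen=True)
class BranchStats:
    """Class statistics for one surviving-feature subset (branch).

    ``branch_key`` holds the positions (within the decision-feature vector) of
    the features that cleared their thresholds; ``stats`` is restricted to
    those features.  ``from_fallback`` marks branches whose training occupancy
    was too small (< 2 cases per class), filled from the marginal statistics
    of the surviving features over all training data.
    """

    branch_key: tuple[int, ...]
    stats: ClassStats
    from_fallback: bool = False

    def weight(self, mode: str, ridge: Optional[float] = None) -> np.ndarray:
        if mode == "prewhitening":
            return whitened_delta(self.stats, ridge)
        if mode == "nonprewhitening":
            return self.stats.delta_d
        raise ValueError(f"unknown observer mode {mode!r}")

    def score(self, values: np.ndarray, mode: str) -> np.ndarray:
        """Centered discriminant w^T v - w^T (mean_present + mean_absent)/2."""
        w = self.weight(mode)
        offset = 0.5 * float(w @ (self.stats.d_present + self.stats.d_absent))
        return np.atleast_2d(values) @ w - offset


@dataclass(frozen=True)
class Candidate:
    location: tuple[int, int]
    search_score: float


@dataclass(frozen=True)
class ObserverConfig:
    """Knobs of the two-stage observer.

    ``min_separation_px`` defaults to roughly one lesion FWHM so candidates do
    not pile onto a single blob; ``border_px`` matches the phantom generator's
    lesion margin so candidates never sit where lesions cannot.
    """

    mode: str = "prewhitening"
    max_candidates: int = 10
    min_separation_px: float = 9.0
    border_px: int = 16
    localization_radius_px: float = 9.4
    n_search_features: int = 3
    n_decision_features: int = 3
    sentinel_rating: float = SENTINEL_RATING
    threshold_grid_percentiles: tuple[float, ...] = tuple(range(0, 100, 5))
    shared_stage_features: bool = False
    #: how many top-ranked candidates per lesion-absent training image feed the
    #: noise-class decision statistics (None = all candidates)
    n_absent_training_candidates: Optional[int] = None
    #: a fitted threshold is the lowest grid value whose training objective is
    #: within this tolerance of the best — a parsimony rule that keeps the
    #: threshold safely below the point where lesion candidates get clipped.
    #: The image-level fit widens this floor to at least one Hanley–McNeil
    #: standard error of the training LROC (one-standard-error rule), so a
    #: finite threshold is accepted only when its training gain exceeds the
    #: objective's own sampling noise
    threshold_objective_tolerance: float = 0.005
    #: where fitted thresholds act: "decision" (default) thresholds the
    #: decision features per candidate, "search" fits a lower threshold on the
    #: search statistic that prunes candidates, "both" does both
    threshold_stage: str = "decision"
    #: thresholded variants refine the stage-1 region-of-interest list to this
    #: many most-salient candidates (None = keep all); noise-driven candidates
    #: vary between training realizations, so trimming the list stabilizes the
    #: observer against training noise
    stage1_top_k: Optional[int] = 3

    def __post_init__(self) -> None:
        if self.mode not in ("prewhitening", "nonprewhitening"):
            raise ValueError("mode must be 'prewhitening' or 'nonprewhitening'")
        if self.threshold_stage not in ("search", "decision", "both"):
            raise ValueError("threshold_stage must be 'search', 'decision' or 'both'")
        if self.stage1_top_k is not None and self.stage1_top_k < 1:
            raise ValueError("stage1_top_k must be >= 1 or None")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")
        if self.min_separation_px < 0:
            raise ValueError("min_separation_px must be nonnegative")


@dataclass(frozen=True)
class ImageRating:
    """Final per-image output: confidence rating plus reported location."""

    rating: float
    reported_location: Optional[tuple[int, int]]
    candidates: tuple[Candidate, ...]

    def __post_init__(self) -> None:
        if (self.reported_location is None) != (self.rating == SENTINEL_RATING):
            raise ValueError("reported_location must be absent iff rating is the sentinel")


# ---------------------------------------------------------------------------
# Stage 1: candidate search
# ---------------------------------------------------------------------------


def _statistic_map(maps: np.ndarray, stats: ClassStats, mode: str) -> np.ndarray:
    """Pixelwise linear search statistic w^T d(x) over the stage's maps."""
    if mode == "prewhitening":
        w = whitened_delta(stats)
    else:
        w = stats.delta_d
    return np.tensordot(w, maps, axes=(0, 0))


def _local_maxima_ranked(
    stat: np.ndarray, border_px: int
) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima of a (periodic) map, sorted by value descending.

    Returns (locations (n, 2), values (n,)).
    """
    peaks = maximum_filter(stat, size=3, mode="wrap") == stat
    H, W = stat.shape
    valid = np.zeros_like(peaks)
    valid[border_px : H - border_px, border_px : W - border_px] = True
    rows, cols = np.nonzero(peaks & valid)
    vals = stat[rows, cols]
    order = np.argsort(-vals, kind="stable")
    return np.stack([rows[order], cols[order]], axis=1), vals[order]


def search_candidates(
    maps: np.ndarray, search_stats: ClassStats, config: ObserverConfig
) -> list[Candidate]:
    """Candidate locations from the search-stage feature maps.

    ``maps`` is the (n_search_features, H, W) stack in the same feature order
    as ``search_stats``.  Local maxima of the search statistic are accepted
    greedily in score order subject to pairwise separation and the border
    margin, up to ``max_candidates``.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] == 0:
        raise ValueError("maps must be a nonempty (n_features, H, W) stack")
    stat = _statistic_map(maps, search_stats, config.mode)
    locs, vals = _local_maxima_ranked(stat, config.border_px)
    accepted: list[Candidate] = []
    accepted_locs: list[np.ndarray] = []
    min_sep2 = config.min_separation_px**2
    for loc, val in zip(locs, vals):
        if accepted_locs:
            d2 = np.sum((np.array(accepted_locs) - loc) ** 2, axis=1)
            if np.any(d2 < min_sep2):
                continue
        accepted.append(Candidate(location=(int(loc[0]), int(loc[1])), search_score=float(val)))
        accepted_locs.append(loc)
        if len(accepted) >= config.max_candidates:
            break
    return accepted


# ---------------------------------------------------------------------------
# Stage 2: thresholds and branch discriminants
# ---------------------------------------------------------------------------


def _branch_masks(X: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Boolean survival mask per case and feature (strict: value must exceed)."""
    return np.atleast_2d(X) > thresholds[None, :]


def fit_branch_statistics(
    training_decision_features: np.ndarray,
    labels: np.ndarray,
    thresholds: ThresholdSet,
) -> dict[tuple[int, ...], BranchStats]:
    """Estimate class statistics for every nonempty surviving-feature branch.

    Each training case is assigned to the branch keyed by the subset of its
    features that exceed their thresholds; that branch's statistics come from
    the surviving-feature values of its own cases.  Branches with fewer than
    two cases in either class fall back to the marginal statistics of the
    surviving features over all training cases (flagged ``from_fallback``).
    """
    X = np.atleast_2d(np.asarray(training_decision_features, dtype=float))
    labels = np.asarray(labels, dtype=bool)
    t = thresholds.thresholds
    masks = _branch_masks(X, t)
    marginal = estimate_class_stats(X[labels], X[~labels])
    branches: dict[tuple[int, ...], BranchStats] = {}
    # unique nonempty survival patterns among the training cases
    seen = {tuple(int(i) for i in np.nonzero(m)[0]) for m in masks if m.any()}
    for key in sorted(seen):
        idx = list(key)
        pattern = np.zeros(X.shape[1], dtype=bool)
        pattern[idx] = True
        in_branch = np.all(masks == pattern[None, :], axis=1)
        yb = labels[in_branch]
        if yb.sum() >= 2 and (~yb).sum() >= 2:
            sub = X[in_branch][:, idx]
            stats = estimate_class_stats(sub[yb], sub[~yb])
            branches[key] = BranchStats(key, stats, from_fallback=False)
        else:
            branches[key] = BranchStats(key, marginal.subset(idx), from_fallback=True)
    return branches


def _score_matrix(
    X: np.ndarray,
    thresholds: ThresholdSet,
    branches: dict[tuple[int, ...], BranchStats],
    mode: str,
    fallback_stats: ClassStats,
    sentinel: float = SENTINEL_RATING,
) -> np.ndarray:
    """Vectorized branch scoring of a feature matrix (rows are cases)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    masks = _branch_masks(X, thresholds.thresholds)
    scores = np.full(X.shape[0], sentinel, dtype=float)
    # group rows by survival pattern to score each branch in one shot
    patterns, inverse = np.unique(masks, axis=0, return_inverse=True)
    for pi, pat in enumerate(patterns):
        rows = inverse == pi
        key = tuple(int(i) for i in np.nonzero(pat)[0])
        if not key:
            continue  # all below threshold -> sentinel
        branch = branches.get(key)
        if branch is None:
            branch = BranchStats(key, fallback_stats.subset(list(key)), from_fallback=True)
        scores[rows] = branch.score(X[rows][:, list(key)], mode)
    return scores


def score_feature_vector(
    d: np.ndarray,
    thresholds: ThresholdSet,
    branches: dict[tuple[int, ...], BranchStats],
    mode: str,
    fallback_stats: ClassStats,
) -> float:
    """Score one decision-feature vector through thresholds and its branch
    discriminant; returns the sentinel when every feature is sub-threshold."""
    d = np.asarray(d, dtype=float)
    if d.size != len(thresholds):
        raise ValueError("feature vector length must match the threshold set")
    return float(_score_matrix(d[None, :], thresholds, branches, mode, fallback_stats)[0])


def _grid_pick(
    grid: np.ndarray, vals: np.ndarray, tolerance: float, prefer: str = "low"
) -> float:
    """Grid value whose objective is within ``tolerance`` of the best.

    ``prefer="low"`` returns the lowest such value (ties to the lower
    threshold), ``prefer="high"`` the highest.  ``grid`` must be ascending."""
    ok = vals >= vals.max() - tolerance - 1e-12
    idx = int(np.argmax(ok)) if prefer == "low" else int(len(ok) - 1 - np.argmax(ok[::-1]))
    return float(grid[idx])


def _coordinate_threshold_search(
    X: np.ndarray,
    config: ObserverConfig,
    objective,
    grid_cap: Optional[np.ndarray] = None,
    tolerance: float = 0.0,
) -> ThresholdSet:
    """One coordinate-wise sweep in feature order over a per-feature grid of
    pooled-value percentiles plus -inf, maximizing ``objective(ThresholdSet)``.

    ``grid_cap`` gives an exclusive per-feature ceiling for candidate
    thresholds (values at or above it are dropped from the grid); passing the
    per-feature minimum of the signal-class training vectors guarantees no
    known-signal case is ever clipped by a fitted threshold — the sample edge
    of 30-odd signal cases is far too noisy to cut into.

    With a positive ``tolerance``, among grid values whose objective lies
    within it of the per-feature maximum the lowest threshold wins (exact
    ties always go to the lower threshold).  The training objective typically
    rises while noise candidates are pruned and falls once lesion candidates
    get clipped, so this parsimony rule settles at the near edge of the
    plateau.  Constant features get -inf."""
    k = X.shape[1]
    t = np.full(k, -np.inf)
    for i in range(k):
        col = X[:, i]
        if np.ptp(col) == 0.0:
            t[i] = -np.inf
            continue
        grid = np.concatenate(
            [[-np.inf], np.percentile(col, list(config.threshold_grid_percentiles))]
        )
        if grid_cap is not None:
            grid = grid[grid < grid_cap[i]]
        vals = np.empty(grid.size)
        for gi, cand in enumerate(grid):
            t[i] = cand
            vals[gi] = objective(ThresholdSet(t.copy()))
        t[i] = _grid_pick(grid, vals, tolerance)
    return ThresholdSet(t)


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil standard error of an empirical AUC with ``n_pos``
    positive and ``n_neg`` negative cases."""
    a = float(np.clip(auc, 0.5, 1.0))
    if n_pos < 1 or n_neg < 1:
        return 0.0
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return float(np.sqrt(max(var, 0.0)))


def fit_thresholds(
    training_decision_features: np.ndarray,
    labels: np.ndarray,
    localization_flags: np.ndarray,
    config: ObserverConfig,
) -> ThresholdSet:
    """Fit per-feature lower thresholds by coordinate-wise grid search.

    One sweep in feature order; the grid for each feature is the configured
    percentiles of its pooled training values plus -inf; the objective is the
    training LROC area of the thresholded observer scoring the given case
    vectors (branch statistics refitted for every candidate threshold); exact
    ties go to the lower threshold.
    """
    X = np.atleast_2d(np.asarray(training_decision_features, dtype=float))
    labels = np.asarray(labels, dtype=bool)
    fallback = estimate_class_stats(X[labels], X[~labels])

    def objective(ts: ThresholdSet) -> float:
        branches = fit_branch_statistics(X, labels, ts)
        ratings = _score_matrix(X, ts, branches, config.mode, fallback, config.sentinel_rating)
        return lroc_auc_from_arrays(ratings, labels, localization_flags)

    return _coordinate_threshold_search(X, config, objective)


def _rate_candidate_matrices(
    cand_mats: Sequence[np.ndarray],
    cand_flags: Sequence[np.ndarray],
    thresholds: ThresholdSet,
    branches: dict[tuple[int, ...], BranchStats],
    mode: str,
    fallback: ClassStats,
) -> tuple[np.ndarray, np.ndarray]:
    """Image-level ratings and localization flags from per-image candidate
    feature matrices: rating = best surviving candidate score (sentinel when
    none survives), flag = that candidate's localization flag."""
    n = len(cand_mats)
    ratings = np.full(n, SENTINEL_RATING)
    flags = np.zeros(n, dtype=bool)
    lengths = [m.shape[0] for m in cand_mats]
    if sum(lengths) == 0:
        return ratings, flags
    allX = np.vstack([m for m in cand_mats if m.shape[0]])
    scores = _score_matrix(allX, thresholds, branches, mode, fallback)
    pos = 0
    for i, L in enumerate(lengths):
        if L == 0:
            continue
        s = scores[pos : pos + L]
        pos += L
        surviving = s > SENTINEL_RATING
        if surviving.any():
            best = int(np.argmax(np.where(surviving, s, -np.inf)))
            ratings[i] = s[best]
            flags[i] = bool(cand_flags[i][best])
    return ratings, flags


def fit_thresholds_on_images(
    case_vectors: np.ndarray,
    case_labels: np.ndarray,
    cand_mats: Sequence[np.ndarray],
    image_labels: np.ndarray,
    cand_flags: Sequence[np.ndarray],
    config: ObserverConfig,
) -> ThresholdSet:
    """Threshold fit whose objective is the deployed observer's training LROC.

    Branch statistics are refitted from ``case_vectors`` for each candidate
    threshold, then every training image is rated as at test time — maximum
    surviving score over its candidate feature matrix — and the image-level
    LROC area is the objective.  This keeps the fitting criterion aligned
    with how the thresholds act during testing.  Three robustness rules beyond
    the plain per-case fit: the grid is capped below the signal-class
    per-feature minimum (never clip a known lesion candidate); the lowest
    threshold within tolerance of the best objective wins; and the tolerance
    is widened to at least one Hanley–McNeil standard error of the baseline
    (all ``-inf``) training LROC — a one-standard-error rule, since with small
    training sets the grid maximum routinely beats the baseline by a few pair
    swaps of pure noise, and a threshold accepted on noise routes weak test
    lesions into the reduced branches.
    """
    X = np.atleast_2d(np.asarray(case_vectors, dtype=float))
    case_labels = np.asarray(case_labels, dtype=bool)
    image_labels = np.asarray(image_labels, dtype=bool)
    fallback = estimate_class_stats(X[case_labels], X[~case_labels])

    def objective(ts: ThresholdSet) -> float:
        branches = fit_branch_statistics(X, case_labels, ts)
        ratings, flags = _rate_candidate_matrices(
            cand_mats, cand_flags, ts, branches, config.mode, fallback
        )
        return lroc_auc_from_arrays(ratings, image_labels, flags)

    cap = X[case_labels].min(axis=0) if case_labels.any() else None
    baseline = objective(ThresholdSet.unthresholded(X.shape[1]))
    se = _hanley_mcneil_se(
        baseline, int(image_labels.sum()), int((~image_labels).sum())
    )
    tolerance = max(config.threshold_objective_tolerance, se)
    return _coordinate_threshold_search(
        X, config, objective, grid_cap=cap, tolerance=tolerance
    )


def fit_search_threshold(
    cand_mats: Sequence[np.ndarray],
    cand_scores: Sequence[np.ndarray],
    cand_flags: Sequence[np.ndarray],
    image_labels: np.ndarray,
    config: ObserverConfig,
) -> float:
    """Fit the stage-1 lower threshold on the search statistic.

    Candidates whose search statistic falls below the threshold are discarded
    before the decision stage; an image left with no candidates gets the
    sentinel rating.  The grid is the configured percentiles of the pooled
    training candidate scores plus -inf, capped below the lowest score of any
    in-radius lesion candidate (never prune a known hit); the objective is the
    training image-level LROC of the plain decision discriminant over the
    surviving candidates, with full-branch statistics refitted from the
    surviving training candidates at each grid value.  Among grid values
    within ``config.threshold_objective_tolerance`` of the best objective the
    HIGHEST threshold wins — the opposite preference from the decision-feature
    fit.  The asymmetry is deliberate: the cap already guarantees no training
    hit is pruned, so extra stage-1 pruning cannot clip known signal, and
    noise-driven candidates vary from training set to training set — pruning
    them stabilizes candidate selection across trials.
    """
    image_labels = np.asarray(image_labels, dtype=bool)
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in cand_scores]) if cand_scores else np.zeros(0)
    if pooled.size == 0 or np.ptp(pooled) == 0.0:
        return float("-inf")
    hit_scores = np.concatenate(
        [
            np.asarray(s, dtype=float)[np.asarray(f, dtype=bool)]
            for s, f, lab in zip(cand_scores, cand_flags, image_labels)
            if lab
        ]
        or [np.zeros(0)]
    )
    cap = hit_scores.min() if hit_scores.size else np.inf
    grid = np.concatenate(
        [[-np.inf], np.percentile(pooled, list(config.threshold_grid_percentiles))]
    )
    grid = grid[grid < cap]

    def objective(t: float) -> float:
        mats, flags = _prune_candidates(cand_mats, cand_scores, cand_flags, t)[:2]
        # signal class: in-radius candidates of present images; noise class:
        # surviving candidates of absent images
        P = [m[f] for m, f, lab in zip(mats, flags, image_labels) if lab and f.any()]
        A = [m for m, lab in zip(mats, image_labels) if not lab and m.shape[0]]
        P = np.vstack(P) if P else np.zeros((0, cand_mats[0].shape[1]))
        A = np.vstack(A) if A else np.zeros((0, cand_mats[0].shape[1]))
        if P.shape[0] < 2 or A.shape[0] < 2:
            return -np.inf
        stats = estimate_class_stats(P, A)
        k = P.shape[1]
        branch = {tuple(range(k)): BranchStats(tuple(range(k)), stats)}
        ratings, loc = _rate_candidate_matrices(
            mats, flags, ThresholdSet.unthresholded(k), branch, config.mode, stats
        )
        return lroc_auc_from_arrays(ratings, image_labels, loc)

    vals = np.array([objective(t) for t in grid])
    return _grid_pick(grid, vals, config.threshold_objective_tolerance, prefer="high")


def _prune_candidates(
    cand_mats: Sequence[np.ndarray],
    cand_scores: Sequence[np.ndarray],
    cand_flags: Sequence[np.ndarray],
    search_threshold: float,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Drop candidates whose search statistic does not exceed the threshold.

    Each image always keeps its single strongest candidate: stage 1 must
    report at least one region of interest, so the threshold trims the
    candidate list rather than emptying it (an image is only ever sentineled
    by the decision stage).  Returns (feature matrices, localization flags,
    scores), each filtered per image."""
    if search_threshold == float("-inf"):
        return (
            [np.asarray(m) for m in cand_mats],
            [np.asarray(f, dtype=bool) for f in cand_flags],
            [np.asarray(s, dtype=float) for s in cand_scores],
        )
    mats, flags, scores = [], [], []
    for m, s, f in zip(cand_mats, cand_scores, cand_flags):
        s = np.asarray(s, dtype=float)
        keep = s > search_threshold
        if s.size and not keep.any():
            keep[int(np.argmax(s))] = True
        mats.append(np.asarray(m)[keep])
        flags.append(np.asarray(f, dtype=bool)[keep])
        scores.append(s[keep])
    return mats, flags, scores


# ---------------------------------------------------------------------------
# The fitted observer and its trainer
# ---------------------------------------------------------------------------


@dataclass
class ObserverBase:
    """Everything threshold variants share: bank, stage features, statistics,
    and the training decision-feature matrix the thresholds are fitted on."""

    bank: FilterBank
    refined_indices: tuple[int, ...]
    stage: StageAssignment
    search_stats: ClassStats
    decision_stats: ClassStats
    config: ObserverConfig
    # decision-feature training material shared by the threshold variants:
    # case vectors (present class sampled at the true lesion center, absent
    # class at search candidates of lesion-absent images) ...
    train_decision_features: np.ndarray
    train_labels: np.ndarray
    train_loc_flags: np.ndarray
    # ... and per-training-image candidate matrices for image-level objectives
    train_candidate_features: list = field(default_factory=list)
    train_image_labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    train_candidate_loc_flags: list = field(default_factory=list)
    #: per-image search-statistic values of the training candidates, and the
    #: search score backing each case vector (+inf for center-sampled rows,
    #: which are not candidates and can never be pruned)
    train_candidate_search_scores: list = field(default_factory=list)
    train_case_search_scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    #: decision features at the true lesion centers of the present training
    #: images — the fallback signal sample when too few search hits survive
    train_present_center_rows: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    @property
    def search_kernel_indices(self) -> tuple[int, ...]:
        return tuple(self.refined_indices[i] for i in self.stage.search_indices)

    @property
    def decision_kernel_indices(self) -> tuple[int, ...]:
        return tuple(self.refined_indices[i] for i in self.stage.decision_indices)


@dataclass
class FittedObserver:
    """A trained two-stage observer, ready to rate images."""

    base: ObserverBase
    thresholds: ThresholdSet
    branches: dict[tuple[int, ...], BranchStats]
    thresholded: bool
    #: stage-1 lower threshold on the search statistic (-inf disables it)
    search_threshold: float = float("-inf")

    @property
    def config(self) -> ObserverConfig:
        return self.base.config

    @property
    def bank(self) -> FilterBank:
        return self.base.bank


def _as_array(image) -> np.ndarray:
    if isinstance(image, ProjectionImage):
        return np.asarray(image.pixels, dtype=float)
    return np.asarray(image, dtype=float)


def _extract_features_at(
    correlator: BankCorrelator,
    image: np.ndarray,
    kernel_indices: Sequence[int],
    locations: np.ndarray,
) -> np.ndarray:
    """(n_locations, n_features) matrix of map values at pixel locations."""
    maps = correlator.maps(image, kernel_indices)
    rows, cols = locations[:, 0], locations[:, 1]
    return maps[:, rows, cols].T


def _search_maps(
    correlator: BankCorrelator, image: np.ndarray, base: ObserverBase
) -> np.ndarray:
    return correlator.maps(image, base.search_kernel_indices)


def rate_image(
    image, observer: FittedObserver, correlator: Optional[BankCorrelator] = None
) -> ImageRating:
    """Run the full two-stage pipeline on one image.

    Search maps give candidates; at each candidate the decision features are
    thresholded and branch-scored; sentinel-scoring candidates are discarded;
    the rating is the best surviving score and the reported location its
    candidate.  If nothing survives the image gets the sentinel rating and no
    location.
    """
    arr = _as_array(image)
    base = observer.base
    if correlator is None:
        correlator = BankCorrelator(base.bank, arr.shape)
    cands = search_candidates(_search_maps(correlator, arr, base), base.search_stats, base.config)
    if observer.thresholded and base.config.stage1_top_k is not None:
        cands = cands[: base.config.stage1_top_k]
    if cands and observer.search_threshold > float("-inf"):
        surviving = [c for c in cands if c.search_score > observer.search_threshold]
        # stage 1 always reports its best candidate even when all fall short
        cands = surviving or [max(cands, key=lambda c: c.search_score)]
    if not cands:
        return ImageRating(SENTINEL_RATING, None, ())
    locs = np.array([c.location for c in cands])
    X = _extract_features_at(correlator, arr, base.decision_kernel_indices, locs)
    scores = _score_matrix(
        X, observer.thresholds, observer.branches, base.config.mode, base.decision_stats
    )
    surviving = scores > SENTINEL_RATING
    if not surviving.any():
        return ImageRating(SENTINEL_RATING, None, tuple(cands))
    best = int(np.argmax(np.where(surviving, scores, -np.inf)))
    return ImageRating(float(scores[best]), cands[best].location, tuple(cands))


def extract_case_features(
    dataset: Dataset, base: ObserverBase, correlator: Optional[BankCorrelator] = None
) -> list[tuple[ProjectionImage, list[Candidate], np.ndarray]]:
    """Stage-1 pass over a dataset: candidates plus decision-feature matrices.

    This is the part of rating that is independent of thresholds, so multiple
    threshold variants of the same base observer can share it.
    """
    if len(dataset) == 0:
        return []
    shape = dataset.images[0].pixels.shape
    if correlator is None:
        correlator = BankCorrelator(base.bank, shape)
    out = []
    kernel_idx = list(dict.fromkeys(base.search_kernel_indices + base.decision_kernel_indices))
    pos_of = {k: i for i, k in enumerate(kernel_idx)}
    s_pos = [pos_of[k] for k in base.search_kernel_indices]
    d_pos = [pos_of[k] for k in base.decision_kernel_indices]
    for img in dataset.images:
        maps = correlator.maps(_as_array(img), kernel_idx)
        cands = search_candidates(maps[s_pos], base.search_stats, base.config)
        if cands:
            locs = np.array([c.location for c in cands])
            X = maps[d_pos][:, locs[:, 0], locs[:, 1]].T
        else:
            X = np.zeros((0, len(d_pos)))
        out.append((img, cands, X))
    return out


def score_cases(
    cases: Sequence[tuple[ProjectionImage, list[Candidate], np.ndarray]],
    observer: FittedObserver,
) -> list[CaseRecord]:
    """Threshold-and-score a pre-extracted case list into LROC case records."""
    base = observer.base
    records = []
    top_k = base.config.stage1_top_k if observer.thresholded else None
    for img, cands, X in cases:
        if top_k is not None and len(cands) > top_k:
            cands, X = cands[:top_k], X[:top_k]
        if observer.search_threshold > float("-inf") and len(cands):
            scores_1 = np.array([c.search_score for c in cands])
            keep = scores_1 > observer.search_threshold
            if not keep.any():  # stage 1 always reports its best candidate
                keep[int(np.argmax(scores_1))] = True
            cands = [c for c, k in zip(cands, keep) if k]
            X = X[keep]
        if len(cands) == 0:
            rating, loc = SENTINEL_RATING, None
        else:
            scores = _score_matrix(
                X, observer.thresholds, observer.branches, base.config.mode, base.decision_stats
            )
            surviving = scores > SENTINEL_RATING
            if surviving.any():
                best = int(np.argmax(np.where(surviving, scores, -np.inf)))
                rating, loc = float(scores[best]), cands[best].location
            else:
                rating, loc = SENTINEL_RATING, None
        records.append(
            CaseRecord(
                rating=rating,
                truth_label=img.lesion_present,
                true_center=img.lesion_center,
                reported_location=loc,
            )
        )
    return records


def rate_dataset(
    dataset: Dataset, observer: FittedObserver, correlator: Optional[BankCorrelator] = None
) -> list[CaseRecord]:
    """Rate every image of a dataset into LROC case records."""
    return score_cases(extract_case_features(dataset, observer.base, correlator), observer)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _center_feature_stats(
    dataset: Dataset,
    correlator: BankCorrelator,
    kernel_indices: Sequence[int],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrices for class-statistics estimation: lesion-present images
    sampled at the true lesion center, lesion-absent images at uniform random
    interior locations (matching where lesions are ever placed)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xAB,)))
    size = dataset.config.image_size
    m = dataset.config.lesion_margin_px
    P, A = [], []
    for img in dataset.images:
        if img.lesion_present:
            loc = np.array([img.lesion_center])
            P.append(_extract_features_at(correlator, _as_array(img), kernel_indices, loc)[0])
        else:
            loc = rng.integers(m, size - m, size=(1, 2))
            A.append(_extract_features_at(correlator, _as_array(img), kernel_indices, loc)[0])
    return np.array(P), np.array(A)


def refined_stats_from_dataset(
    dataset: Dataset,
    bank: FilterBank,
    kernel_indices: Optional[Sequence[int]] = None,
    correlator: Optional[BankCorrelator] = None,
) -> tuple[ClassStats, np.ndarray, np.ndarray]:
    """Class statistics over a kernel subset from center-sampled features.

    Returns (stats, present matrix, absent matrix); used both for refining the
    full bank (with all kernels) and for the per-study refined bank.
    """
    shape = dataset.images[0].pixels.shape
    if correlator is None:
        correlator = BankCorrelator(bank, shape)
    idx = list(range(len(bank))) if kernel_indices is None else list(kernel_indices)
    P, A = _center_feature_stats(dataset, correlator, idx, dataset.seed)
    return estimate_class_stats(P, A), P, A


def _search_hit_rate(
    spectra: list[np.ndarray],
    centers: np.ndarray,
    correlator: BankCorrelator,
    kernel_subset: Sequence[int],
    stats: ClassStats,
    config: ObserverConfig,
) -> float:
    """Fraction of lesion-present images whose top search candidate falls
    within the localization radius of the true center."""
    if config.mode == "prewhitening":
        w = whitened_delta(stats)
    else:
        w = stats.delta_d
    hits = 0
    H, W = correlator.shape
    b = config.border_px
    r2 = config.localization_radius_px**2
    for imf, center in zip(spectra, centers):
        stat = np.zeros((H, W))
        for wi, ki in zip(w, kernel_subset):
            stat += wi * np.fft.irfft2(imf * correlator._kf[ki], s=(H, W))
        interior = stat[b : H - b, b : W - b]
        flat = int(np.argmax(interior))
        loc = np.array([flat // interior.shape[1] + b, flat % interior.shape[1] + b])
        if np.sum((loc - center) ** 2) <= r2:
            hits += 1
    return hits / max(len(spectra), 1)


def fit_observer_base(
    train_dataset: Dataset,
    bank: FilterBank,
    config: ObserverConfig = ObserverConfig(),
    refined_indices: Optional[Sequence[int]] = None,
    refined_stats: Optional[tuple[ClassStats, np.ndarray, np.ndarray]] = None,
    stage_assignment: Optional[StageAssignment] = None,
) -> ObserverBase:
    """Fit everything the threshold variants share.

    Steps: estimate class statistics over the refined bank from center-sampled
    training features; greedily pick the search-stage features by training
    candidate-hit rate; run the search stage over the training images to build
    decision-feature matrices at the top candidate of each image; greedily
    pick the decision-stage features by training LROC area.

    ``refined_indices`` (kernel indices into ``bank``) normally come from a
    study-level calibration via :func:`vsmo.features.refine_bank`; by default
    the whole bank is used as the refined bank.  A precomputed
    ``stage_assignment`` (e.g. from a study-level calibration fit) skips the
    greedy stage selection; class statistics are still estimated from this
    training set.
    """
    if len(train_dataset) < 4:
        raise ValueError("training dataset too small to fit an observer")
    shape = train_dataset.images[0].pixels.shape
    correlator = BankCorrelator(bank, shape)
    refined = tuple(refined_indices) if refined_indices is not None else tuple(range(len(bank)))

    if refined_stats is None:
        full_stats, P, A = refined_stats_from_dataset(
            train_dataset, bank, refined, correlator
        )
    else:
        full_stats, P, A = refined_stats

    # --- search-stage feature selection: candidate-hit rate on present images
    if stage_assignment is not None:
        search_pos = stage_assignment.search_indices
    else:
        present = [img for img in train_dataset.images if img.lesion_present]
        spectra = [np.fft.rfft2(_as_array(img)) for img in present]
        centers = np.array([img.lesion_center for img in present])

        def search_objective(subset: tuple[int, ...]) -> float:
            kidx = [refined[i] for i in subset]
            return _search_hit_rate(
                spectra, centers, correlator, kidx, full_stats.subset(list(subset)), config
            )

        n_search = min(config.n_search_features, len(refined))
        search_pos = greedy_forward_select(len(refined), n_search, search_objective)
    search_stats = full_stats.subset(list(search_pos))
    search_kidx = [refined[i] for i in search_pos]

    # --- stage-1 pass over all training images: candidates, their 12-feature
    # vectors and localization flags.  The decision stage's signal-class
    # sample for a lesion-present image is the candidate nearest the true
    # center within the localization radius (matching the max-selected
    # locations the decision stage scores at test time); images whose search
    # stage missed the lesion contribute no signal sample.  The noise class is
    # every candidate of the lesion-absent images.
    r2 = config.localization_radius_px**2
    image_labels, cand_mats12, cand_flags, cand_scores = [], [], [], []
    present_hit_rows, present_center_rows, absent_cand_rows = [], [], []
    present_hit_scores, absent_cand_scores = [], []
    for img in train_dataset.images:
        maps12 = correlator.maps(_as_array(img), refined)
        cands = search_candidates(maps12[list(search_pos)], search_stats, config)
        locs = np.array([c.location for c in cands]).reshape(-1, 2)
        scores = np.array([c.search_score for c in cands])
        Xc = (
            maps12[:, locs[:, 0], locs[:, 1]].T
            if len(cands)
            else np.zeros((0, len(refined)))
        )
        image_labels.append(img.lesion_present)
        cand_mats12.append(Xc)
        cand_scores.append(scores)
        if img.lesion_present:
            center = np.array(img.lesion_center)
            d2 = np.sum((locs - center) ** 2, axis=1) if len(cands) else np.zeros(0)
            flags = d2 <= r2 if len(cands) else np.zeros(0, bool)
            cand_flags.append(flags)
            if flags.any():
                best = int(np.argmin(d2))
                present_hit_rows.append(Xc[best])
                present_hit_scores.append(float(scores[best]))
            r, c = img.lesion_center
            present_center_rows.append(maps12[:, r, c])
        else:
            cand_flags.append(np.zeros(len(cands), dtype=bool))
            k_keep = config.n_absent_training_candidates
            absent_cand_rows.append(Xc if k_keep is None else Xc[:k_keep])
            absent_cand_scores.append(scores if k_keep is None else scores[:k_keep])
    image_labels = np.array(image_labels, dtype=bool)
    # degenerate search stages can miss (almost) every lesion; fall back to
    # true-center samples so the statistics stay estimable
    if len(present_hit_rows) >= 2:
        P12 = np.array(present_hit_rows)
        p_scores = np.array(present_hit_scores)
    else:
        P12 = np.array(present_center_rows)
        p_scores = np.full(len(P12), np.inf)  # not candidates; never pruned
    A12 = np.vstack(absent_cand_rows) if absent_cand_rows else np.zeros((0, len(refined)))
    a_scores = (
        np.concatenate(absent_cand_scores) if absent_cand_scores else np.zeros(0)
    )
    case_X12 = np.vstack([P12, A12])
    case_labels = np.concatenate([np.ones(len(P12), bool), np.zeros(len(A12), bool)])
    case_scores = np.concatenate([p_scores, a_scores])

    # --- decision-stage feature selection: training LROC of the plain LDA
    # applied the way the observer applies it (max over candidates per image)
    def decision_objective(subset: tuple[int, ...]) -> float:
        idx = list(subset)
        stats = estimate_class_stats(case_X12[case_labels][:, idx], case_X12[~case_labels][:, idx])
        branch = BranchStats(tuple(range(len(idx))), stats)
        ts = ThresholdSet.unthresholded(len(idx))
        ratings, flags = _rate_candidate_matrices(
            [m[:, idx] for m in cand_mats12],
            cand_flags,
            ts,
            {tuple(range(len(idx))): branch},
            config.mode,
            stats,
        )
        return lroc_auc_from_arrays(ratings, image_labels, flags)

    n_dec = min(config.n_decision_features, len(refined))
    if stage_assignment is not None:
        decision_pos = stage_assignment.decision_indices
    elif config.shared_stage_features:
        decision_pos = search_pos
    else:
        decision_pos = greedy_forward_select(len(refined), n_dec, decision_objective)
    dp = list(decision_pos)
    Xd = case_X12[:, dp]
    decision_stats = estimate_class_stats(Xd[case_labels], Xd[~case_labels])

    return ObserverBase(
        bank=bank,
        refined_indices=refined,
        stage=StageAssignment(tuple(search_pos), tuple(decision_pos)),
        search_stats=search_stats,
        decision_stats=decision_stats,
        config=config,
        train_decision_features=Xd,
        train_labels=case_labels,
        train_loc_flags=np.concatenate(
            [np.ones(len(P12), bool), np.zeros(len(A12), bool)]
        ),
        train_candidate_features=[m[:, dp] for m in cand_mats12],
        train_image_labels=image_labels,
        train_candidate_loc_flags=cand_flags,
        train_candidate_search_scores=cand_scores,
        train_case_search_scores=case_scores,
        train_present_center_rows=(
            np.array(present_center_rows)[:, dp]
            if present_center_rows
            else np.zeros((0, len(dp)))
        ),
    )


def _case_rows_from_candidates(
    cand_mats: Sequence[np.ndarray],
    cand_flags: Sequence[np.ndarray],
    image_labels: np.ndarray,
    center_rows: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-sample rows from per-image candidate matrices.

    Signal class: the strongest surviving in-radius candidate of each
    lesion-present image (matrices are in descending search-score order);
    falls back to the true-center rows when fewer than two hits survive.
    Noise class: every surviving candidate of the lesion-absent images."""
    P, A = [], []
    for m, f, lab in zip(cand_mats, cand_flags, image_labels):
        if lab:
            f = np.asarray(f, dtype=bool)
            if f.any():
                P.append(np.asarray(m)[int(np.argmax(f))])
        else:
            if np.asarray(m).shape[0]:
                A.append(np.asarray(m))
    k = center_rows.shape[1] if center_rows.ndim == 2 else 0
    Pm = np.array(P) if len(P) >= 2 else center_rows
    Am = np.vstack(A) if A else np.zeros((0, k))
    X = np.vstack([Pm, Am])
    labels = np.concatenate([np.ones(len(Pm), bool), np.zeros(len(Am), bool)])
    return X, labels


def make_observer(base: ObserverBase, thresholded: bool = True) -> FittedObserver:
    """Finish training a base into a rateable observer.

    The unthresholded variant keeps every stage-1 candidate and disables all
    thresholds.  The thresholded variant refines the stage-1 candidate list
    to the ``config.stage1_top_k`` most salient regions of interest, fits the
    stage-1 search threshold and/or the decision-feature thresholds (per
    ``config.threshold_stage``), and estimates the per-branch class
    statistics from the surviving training candidates only."""
    k = base.train_decision_features.shape[1]
    config = base.config
    search_t = float("-inf")
    if not thresholded:
        thresholds = ThresholdSet.unthresholded(k)
        branches = fit_branch_statistics(
            base.train_decision_features, base.train_labels, thresholds
        )
        return FittedObserver(
            base=base, thresholds=thresholds, branches=branches, thresholded=False
        )

    cand_mats = base.train_candidate_features
    cand_flags = base.train_candidate_loc_flags
    cand_scores = base.train_candidate_search_scores
    if config.stage1_top_k is not None:
        kk = config.stage1_top_k
        cand_mats = [np.asarray(m)[:kk] for m in cand_mats]
        cand_flags = [np.asarray(f, dtype=bool)[:kk] for f in cand_flags]
        cand_scores = [np.asarray(s, dtype=float)[:kk] for s in cand_scores]
    if config.threshold_stage in ("search", "both"):
        search_t = fit_search_threshold(
            cand_mats, cand_scores, cand_flags, base.train_image_labels, config
        )
        if search_t > float("-inf"):
            cand_mats, cand_flags, cand_scores = _prune_candidates(
                cand_mats, cand_scores, cand_flags, search_t
            )
    case_X, case_labels = _case_rows_from_candidates(
        cand_mats, cand_flags, base.train_image_labels, base.train_present_center_rows
    )
    if config.threshold_stage in ("decision", "both"):
        thresholds = fit_thresholds_on_images(
            case_X,
            case_labels,
            cand_mats,
            base.train_image_labels,
            cand_flags,
            config,
        )
    else:
        thresholds = ThresholdSet.unthresholded(k)
    branches = fit_branch_statistics(case_X, case_labels, thresholds)
    return FittedObserver(
        base=base,
        thresholds=thresholds,
        branches=branches,
        thresholded=True,
        search_threshold=search_t,
    )


def fit_observer(
    train_dataset: Dataset,
    bank: FilterBank,
    config: ObserverConfig = ObserverConfig(),
    refined_indices: Optional[Sequence[int]] = None,
    thresholded: bool = True,
) -> FittedObserver:
    """End-to-end training: stage features, class statistics, thresholds and
    branch discriminants from one training dataset."""
    base = fit_observer_base(train_dataset, bank, config, refined_indices)
    return make_observer(base, thresholded=thresholded)
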