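"""Empirical ROC and LROC figures of merit with sentinel-rating handling.

In a localization ROC (LROC) study each case carries a confidence rating and,
for rated cases, a reported lesion location.  A lesion-present case counts as
a true positive only when its rating clears the operating threshold AND the
reported location falls within the localization radius of the true center.
The area under the empirical LROC curve is therefore the ROC-style pairwise
rank statistic in which an incorrectly localized present case contributes
zero regardless of its rating.

Cases whose every feature fell below threshold carry the sentinel rating
(-9999 by convention) and no location; sentinels rank strictly below every
finite rating and are mutually tied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SENTINEL_RATING",
    "CaseRecord",
    "ROCResult",
    "LROCResult",
    "localization_correct",
    "empirical_roc_auc",
    "empirical_lroc_auc",
    "auc_standard_error",
]

SENTINEL_RATING = -9999.0


@dataclass(frozen=True)
class CaseRecord:
    """One LROC unit of analysis: rating, truth, and reported location."""

    rating: float
    truth_label: bool
    true_center: Optional[tuple[float, float]] = None
    reported_location: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.truth_label != (self.true_center is not None):
            raise ValueError("true_center must be present iff truth_label is present")


@dataclass(frozen=True)
class ROCResult:
    auc: float
    n_present: int
    n_absent: int


@dataclass(frozen=True)
class LROCResult:
    auc: float
    n_present: int
    n_absent: int
    correct_localization_fraction: float
    localization_radius_px: float


def localization_correct(
    reported: Optional[Sequence[float]],
    true_center: Optional[Sequence[float]],
    radius_px: float,
) -> bool:
    """Euclidean distance test, boundary inclusive; missing locations never
    localize (sentinel cases report no location)."""
    if reported is None or true_center is None:
        return False
    d = np.hypot(reported[0] - true_center[0], reported[1] - true_center[1])
    return bool(d <= radius_px)


def _ranking_key(ratings: np.ndarray) -> np.ndarray:
    """Ratings with sentinels mapped to -inf so they sort strictly minimal."""
    out = np.asarray(ratings, dtype=float).copy()
    out[out == SENTINEL_RATING] = -np.inf
    return out


def _pairwise_auc(pos: np.ndarray, neg: np.ndarray, pos_weight: np.ndarray) -> float:
    """Rank-based pairwise area: mean over (pos, neg) pairs of
    pos_weight * (1 if pos>neg, 1/2 if tie, 0 otherwise).

    Computed by sorting the negatives and binary-searching each positive,
    O((m+n) log n) rather than the quadratic double loop.
    """
    neg_sorted = np.sort(neg)
    lo = np.searchsorted(neg_sorted, pos, side="left")   # negatives strictly below
    hi = np.searchsorted(neg_sorted, pos, side="right")  # ties end here
    wins = lo + 0.5 * (hi - lo)
    return float(np.sum(pos_weight * wins) / (pos.size * neg.size))


def _split(records: Sequence[CaseRecord]) -> tuple[list[CaseRecord], list[CaseRecord]]:
    present = [r for r in records if r.truth_label]
    absent = [r for r in records if not r.truth_label]
    if not present or not absent:
        raise ValueError("need at least one case of each class")
    return present, absent


def empirical_roc_auc(records: Sequence[CaseRecord]) -> ROCResult:
    """Nonparametric ROC area (Mann–Whitney statistic, half-credit ties)."""
    present, absent = _split(records)
    pos = _ranking_key(np.array([r.rating for r in present]))
    neg = _ranking_key(np.array([r.rating for r in absent]))
    auc = _pairwise_auc(pos, neg, np.ones(pos.size))
    return ROCResult(auc=auc, n_present=len(present), n_absent=len(absent))


def empirical_lroc_auc(records: Sequence[CaseRecord], radius_px: float) -> LROCResult:
    """Nonparametric LROC area: a present case contributes to the pairwise
    statistic only when correctly localized within ``radius_px``."""
    present, absent = _split(records)
    pos = _ranking_key(np.array([r.rating for r in present]))
    neg = _ranking_key(np.array([r.rating for r in absent]))
    loc_ok = np.array(
        [
            localization_correct(r.reported_location, r.true_center, radius_px)
            for r in present
        ],
        dtype=float,
    )
    auc = _pairwise_auc(pos, neg, loc_ok)
    return LROCResult(
        auc=auc,
        n_present=len(present),
        n_absent=len(absent),
        correct_localization_fraction=float(loc_ok.mean()),
        localization_radius_px=float(radius_px),
    )


def lroc_auc_from_arrays(
    ratings: np.ndarray, labels: np.ndarray, loc_correct: np.ndarray
) -> float:
    """Array fast path used inside observer training loops: LROC area from a
    rating vector, boolean labels and per-case localization flags (flags of
    absent cases are ignored)."""
    ratings = _ranking_key(np.asarray(ratings, dtype=float))
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need both classes")
    pos = ratings[labels]
    neg = ratings[~labels]
    w = np.asarray(loc_correct, dtype=float)[labels]
    return _pairwise_auc(pos, neg, w)


def roc_auc_from_arrays(ratings: np.ndarray, labels: np.ndarray) -> float:
    """Array fast path for the ROC area."""
    ratings = _ranking_key(np.asarray(ratings, dtype=float))
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need both classes")
    pos, neg = ratings[labels], ratings[~labels]
    return _pairwise_auc(pos, neg, np.ones(pos.size))


def auc_standard_error(trial_aucs: Sequence[float], of_mean: bool = False) -> float:
    """Spread of AUC estimates across independent training trials.

    Default is the per-trial sample standard deviation (n-1 denominator),
    quantifying how much a single trained observer's AUC moves when the
    training set is redrawn with the test set fixed.  ``of_mean=True`` returns
    SD/sqrt(n_trials) instead.
    """
    a = np.asarray(trial_aucs, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two trials")
    sd = float(a.std(ddof=1))
    return sd / np.sqrt(a.size) if of_mean else sd
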