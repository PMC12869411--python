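"""Study designs: pinhole-diameter sweep and training-set-size study.

Both experiments share a fixed workflow: simulate paired lesion-present /
lesion-absent datasets, calibrate a refined 12-feature Gabor bank once per
study, fit observer variants on fresh training data, and score a test set
with LROC methodology.  Results come back as tidy pandas tables, one row per
(variant, condition, trial), ready for plotting or CSV export.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import features as ft
from . import observer as obs
from .gabor import BankCorrelator, FilterBank, default_filter_bank
from .lroc import auc_standard_error, empirical_lroc_auc, empirical_roc_auc
from .phantoms import ApertureModel, Dataset, PhantomConfig, generate_dataset

__all__ = [
    "SweepConfig",
    "TrainingSizeConfig",
    "VARIANTS",
    "run_pinhole_sweep",
    "run_training_size_study",
    "summarize_training_study",
    "plateau_training_size",
    "write_results",
    "calibrate_refined_bank",
]

#: observer variants: (mode, thresholded, shared stage features)
VARIANTS: dict[str, tuple[str, bool, bool]] = {
    "pw": ("prewhitening", False, False),
    "npw": ("nonprewhitening", False, False),
    "pw_threshold": ("prewhitening", True, False),
    "npw_threshold": ("nonprewhitening", True, False),
    "pw_shared": ("prewhitening", False, True),
}


def _default_drel_grid() -> list[float]:
    return [round(0.2 * i, 1) for i in range(1, 19)]  # 0.2 .. 3.6


@dataclass(frozen=True)
class SweepConfig:
    """Pinhole-diameter sweep over observer variants."""

    d_rel_values: tuple[float, ...] = tuple(_default_drel_grid())
    observer_variants: tuple[str, ...] = ("pw",)
    n_train_pairs: int = 100
    n_test_pairs: int = 100
    n_calibration_pairs: int = 60
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    reference_counts: float = 5.0e4
    observer: obs.ObserverConfig = field(default_factory=obs.ObserverConfig)

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.d_rel_values):
            raise ValueError("relative diameters must be positive")
        if not self.observer_variants:
            raise ValueError("need at least one observer variant")
        unknown = set(self.observer_variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown observer variants: {sorted(unknown)}")


@dataclass(frozen=True)
class TrainingSizeConfig:
    """Training-set-size study at one aperture with a fixed test set."""

    m_values: tuple[int, ...] = (30, 50, 100, 200, 300, 400, 500)
    n_trials: int = 10
    n_test_pairs: int = 200
    n_calibration_pairs: int = 60
    fixed_test_seed: int = 20_000
    seed: int = 0
    d_rel: float = 1.0
    #: stage-feature selection is part of training and is repeated on every
    #: trial by default (the refined 12-kernel bank stays fixed per study);
    #: set True to freeze stage features from a calibration fit, which
    #: isolates statistics + threshold noise from selection noise
    fix_stage_assignment: bool = False
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    reference_counts: float = 5.0e4
    observer: obs.ObserverConfig = field(default_factory=obs.ObserverConfig)

    def __post_init__(self) -> None:
        if list(self.m_values) != sorted(self.m_values) or min(self.m_values) <= 0:
            raise ValueError("m_values must be positive and ascending")
        if self.n_trials < 2:
            raise ValueError("need at least two trials to estimate a standard error")


def _study_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=master, spawn_key=key).generate_state(1)[0])


def calibrate_refined_bank(
    bank: FilterBank,
    phantom: PhantomConfig,
    aperture: ApertureModel,
    n_pairs: int,
    seed: int,
    target_size: int = 12,
) -> list[int]:
    """Refine the full bank to ``target_size`` kernels on a dedicated
    calibration dataset: per-kernel SNRs and the feature correlation matrix
    from center-sampled features, then greedy combined-SNR selection."""
    ds = generate_dataset(phantom, aperture, n_pairs, seed)
    stats, P, A = obs.refined_stats_from_dataset(ds, bank)
    var = np.diag(stats.k_matrix)
    var = np.where(var > 0, var, 1.0)
    per_snr = np.abs(stats.delta_d) / np.sqrt(var)
    corr = stats.k_matrix / np.sqrt(np.outer(var, var))
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    rule = ft.FeaturePairRule(target_bank_size=min(target_size, len(bank)))
    return ft.refine_bank(per_snr, corr, rule)


def _dataset_hash(ds: Dataset) -> str:
    h = hashlib.sha256()
    for img in ds.images:
        h.update(np.ascontiguousarray(img.pixels))
    return h.hexdigest()[:16]


def _evaluate(
    observer: obs.FittedObserver,
    cases,
    radius: float,
) -> dict:
    records = obs.score_cases(cases, observer)
    lroc = empirical_lroc_auc(records, radius)
    roc = empirical_roc_auc(records)
    return {
        "auc_lroc": lroc.auc,
        "auc_roc": roc.auc,
        "pcl": lroc.correct_localization_fraction,
        "n_test": len(records),
    }


def _fit_variant_group(
    train_ds: Dataset,
    bank: FilterBank,
    refined: Sequence[int],
    base_config: obs.ObserverConfig,
    variants: Sequence[str],
    stage_assignments: Optional[dict] = None,
) -> dict[str, obs.FittedObserver]:
    """Fit requested variants, sharing a base per (mode, shared) combination.

    ``stage_assignments`` optionally maps (mode, shared) to a study-level
    StageAssignment so every trial uses the same stage features.
    """
    fitted: dict[str, obs.FittedObserver] = {}
    groups: dict[tuple[str, bool], list[str]] = {}
    for v in variants:
        mode, _, shared = VARIANTS[v]
        groups.setdefault((mode, shared), []).append(v)
    for (mode, shared), names in groups.items():
        cfg = replace(base_config, mode=mode, shared_stage_features=shared)
        sa = stage_assignments.get((mode, shared)) if stage_assignments else None
        base = obs.fit_observer_base(
            train_ds, bank, cfg, refined_indices=refined, stage_assignment=sa
        )
        for v in names:
            fitted[v] = obs.make_observer(base, thresholded=VARIANTS[v][1])
    return fitted


def run_pinhole_sweep(
    config: SweepConfig, bank: Optional[FilterBank] = None, verbose: bool = False
) -> pd.DataFrame:
    """LROC performance of the requested observer variants across relative
    pinhole diameters.  One row per (variant, d_rel)."""
    bank = bank or default_filter_bank()
    rows = []
    for d_rel in config.d_rel_values:
        t0 = time.time()
        aperture = ApertureModel(d_rel, config.reference_counts)
        try:
            refined = calibrate_refined_bank(
                bank,
                config.phantom,
                aperture,
                config.n_calibration_pairs,
                _study_seed(config.seed, 0, int(round(d_rel * 10))),
            )
            train_seed = _study_seed(config.seed, 1, int(round(d_rel * 10)))
            test_seed = _study_seed(config.seed, 2, int(round(d_rel * 10)))
            train_ds = generate_dataset(config.phantom, aperture, config.n_train_pairs, train_seed)
            test_ds = generate_dataset(config.phantom, aperture, config.n_test_pairs, test_seed)
            fitted = _fit_variant_group(
                train_ds, bank, refined, config.observer, config.observer_variants
            )
            # variants sharing a base share the stage-1 pass over the test set
            cases_by_base: dict[int, list] = {}
            for name, ob in fitted.items():
                bid = id(ob.base)
                if bid not in cases_by_base:
                    cases_by_base[bid] = obs.extract_case_features(test_ds, ob.base)
                metrics = _evaluate(
                    ob, cases_by_base[bid], config.observer.localization_radius_px
                )
                rows.append(
                    {
                        "variant": name,
                        "d_rel": d_rel,
                        "trial": 0,
                        **metrics,
                        "n_train_pairs": config.n_train_pairs,
                        "train_seed": train_seed,
                        "test_seed": test_seed,
                    }
                )
        except Exception as exc:  # noqa: BLE001 - cell identity in the diagnostic
            raise RuntimeError(f"pinhole sweep failed at d_rel={d_rel}") from exc
        if verbose:
            print(f"[sweep] d_rel={d_rel:4.1f} done in {time.time() - t0:6.1f}s")
    return pd.DataFrame(rows)


def run_training_size_study(
    config: TrainingSizeConfig, bank: Optional[FilterBank] = None, verbose: bool = False
) -> pd.DataFrame:
    """Thresholded vs unthresholded prewhitening observers as the per-class
    training size M grows, against one fixed test set.

    The refined 12-kernel bank comes from a dedicated calibration set so that
    trials stay comparable; stage features, class statistics and thresholds
    are refitted on every trial's fresh training data.  One row per
    (variant, M, trial).
    """
    bank = bank or default_filter_bank()
    aperture = ApertureModel(config.d_rel, config.reference_counts)
    refined = calibrate_refined_bank(
        bank, config.phantom, aperture, config.n_calibration_pairs, _study_seed(config.seed, 10)
    )
    test_ds = generate_dataset(
        config.phantom, aperture, config.n_test_pairs, config.fixed_test_seed
    )
    test_hash = _dataset_hash(test_ds)
    stage_assignments = None
    if config.fix_stage_assignment:
        calib_ds = generate_dataset(
            config.phantom, aperture, config.n_calibration_pairs, _study_seed(config.seed, 11)
        )
        cfg = replace(config.observer, mode="prewhitening", shared_stage_features=False)
        calib_base = obs.fit_observer_base(calib_ds, bank, cfg, refined_indices=refined)
        stage_assignments = {("prewhitening", False): calib_base.stage}
    rows = []
    for m in config.m_values:
        for trial in range(config.n_trials):
            t0 = time.time()
            train_seed = _study_seed(config.seed, 20, m, trial)
            try:
                train_ds = generate_dataset(config.phantom, aperture, m, train_seed)
                fitted = _fit_variant_group(
                    train_ds,
                    bank,
                    refined,
                    config.observer,
                    ("pw", "pw_threshold"),
                    stage_assignments=stage_assignments,
                )
                cases = obs.extract_case_features(test_ds, fitted["pw"].base)
                for name, ob in fitted.items():
                    metrics = _evaluate(
                        ob, cases, config.observer.localization_radius_px
                    )
                    rows.append(
                        {
                            "variant": name,
                            "m_pairs": m,
                            "total_train_cases": 2 * m,
                            "trial": trial,
                            **metrics,
                            "train_seed": train_seed,
                            "test_hash": test_hash,
                        }
                    )
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"training-size study failed at M={m}, trial={trial}"
                ) from exc
            if verbose:
                print(f"[study] M={m:4d} trial={trial} done in {time.time() - t0:6.1f}s")
    return pd.DataFrame(rows)


def summarize_training_study(table: pd.DataFrame, of_mean: bool = False) -> pd.DataFrame:
    """Per (variant, M): mean LROC AUC and the across-trial standard error."""
    out = (
        table.groupby(["variant", "m_pairs"], as_index=False)
        .agg(
            auc_lroc_mean=("auc_lroc", "mean"),
            se=("auc_lroc", lambda a: auc_standard_error(a, of_mean=of_mean)),
            n_trials=("auc_lroc", "size"),
            total_train_cases=("total_train_cases", "first"),
        )
        .sort_values(["variant", "m_pairs"])
        .reset_index(drop=True)
    )
    return out


def plateau_training_size(summary: pd.DataFrame, variant: str, tol: float = 0.2) -> int:
    """Smallest total training-case count whose SE is within ``tol`` (relative)
    of the SE at the largest training size for the given variant."""
    sub = summary[summary["variant"] == variant].sort_values("m_pairs")
    if sub.empty:
        raise ValueError(f"variant {variant!r} not present in the summary")
    plateau_se = float(sub["se"].iloc[-1])
    ok = sub[sub["se"] <= (1.0 + tol) * plateau_se]
    return int(ok["total_train_cases"].iloc[0])


def write_results(
    table: pd.DataFrame,
    out_path,
    config: Optional[object] = None,
    plots: bool = False,
) -> Path:
    """Persist a result table as CSV with a JSON run manifest alongside.

    ``out_path`` is the CSV path; the manifest (same stem, ``.manifest.json``)
    records the configuration and every seed column so any cell can be
    regenerated in isolation.  With ``plots=True`` an AUC-vs-condition figure
    with +/- 1 SE bars is written next to the CSV.
    """
    if table.empty:
        raise ValueError("refusing to write an empty result table")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False)
    manifest = {
        "columns": list(table.columns),
        "n_rows": int(len(table)),
        "seeds": {
            c: sorted(set(int(v) for v in table[c]))
            for c in table.columns
            if c.endswith("seed")
        },
        "config": _config_to_jsonable(config) if config is not None else None,
    }
    out_path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
    if plots:
        _plot_results(table, out_path.with_suffix(".png"))
    return out_path


def _config_to_jsonable(cfg) -> dict:
    import dataclasses

    def conv(v):
        if dataclasses.is_dataclass(v):
            return {f.name: conv(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if isinstance(v, (tuple, list)):
            return [conv(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return conv(cfg)


def _plot_results(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xcol = "d_rel" if "d_rel" in table.columns else "m_pairs"
    fig, ax = plt.subplots(figsize=(6, 4))
    for variant, sub in table.groupby("variant"):
        g = sub.groupby(xcol)["auc_lroc"]
        mean, sd = g.mean(), g.std(ddof=1).fillna(0.0)
        ax.errorbar(mean.index, mean.values, yerr=sd.values, marker="o", capsize=3, label=variant)
    ax.set_xlabel("relative pinhole diameter" if xcol == "d_rel" else "training pairs per class")
    ax.set_ylabel("LROC AUC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
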