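"""Persistence: datasets as flat binary arrays + JSON sidecar, observers as
JSON model files, case ratings as CSV."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import ClassStats, StageAssignment
from .gabor import FilterBank, build_filter_bank
from .lroc import CaseRecord
from .observer import (
    BranchStats,
    FittedObserver,
    ObserverBase,
    ObserverConfig,
    ThresholdSet,
)
from .phantoms import ApertureModel, Dataset, PhantomConfig, ProjectionImage

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
    "save_ratings",
    "load_ratings",
    "export_truth_csv",
]


def save_dataset(dataset: Dataset, out_dir) -> Path:
    """Write a dataset as raw binary arrays with a JSON sidecar and truth CSV.

    Layout: ``pixels.bin`` (int32, C order), ``mean_fields.bin`` (float32),
    ``meta.json`` (shape, dtypes, config, aperture, seed, truth table) and
    ``truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot persist an empty dataset")
    shape = dataset.images[0].pixels.shape
    pixels = np.stack([im.pixels for im in dataset.images]).astype(np.int32)
    means = np.stack([im.mean_field for im in dataset.images]).astype(np.float32)
    pixels.tofile(out / "pixels.bin")
    means.tofile(out / "mean_fields.bin")
    truth = _truth_frame(dataset)
    truth.to_csv(out / "truth.csv", index=False)
    meta = {
        "n_images": n,
        "image_shape": list(shape),
        "pixels_dtype": "int32",
        "mean_dtype": "float32",
        "prevalence": dataset.prevalence,
        "seed": dataset.seed,
        "config": dataclasses.asdict(dataset.config),
        "aperture": dataclasses.asdict(dataset.aperture),
        "truth": truth.to_dict(orient="list"),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def _truth_frame(dataset: Dataset) -> pd.DataFrame:
    rows = []
    for i, im in enumerate(dataset.images):
        r, c = im.lesion_center if im.lesion_center else (-1, -1)
        rows.append(
            {"index": i, "label": int(im.lesion_present), "row": r, "col": c, "seed": im.rng_seed}
        )
    return pd.DataFrame(rows)


def export_truth_csv(dataset: Dataset, path) -> Path:
    path = Path(path)
    _truth_frame(dataset).to_csv(path, index=False)
    return path


def load_dataset(in_dir) -> Dataset:
    out = Path(in_dir)
    meta = json.loads((out / "meta.json").read_text())
    n = meta["n_images"]
    shape = tuple(meta["image_shape"])
    pixels = np.fromfile(out / "pixels.bin", dtype=np.int32).reshape(n, *shape)
    means = np.fromfile(out / "mean_fields.bin", dtype=np.float32).reshape(n, *shape)
    cfg = PhantomConfig(**meta["config"])
    ap = ApertureModel(**meta["aperture"])
    truth = meta["truth"]
    images = []
    for i in range(n):
        present = bool(truth["label"][i])
        center = (truth["row"][i], truth["col"][i]) if present else None
        images.append(
            ProjectionImage(
                pixels=pixels[i].astype(np.int64),
                mean_field=means[i].astype(float),
                aperture=ap,
                lesion_present=present,
                lesion_center=center,
                rng_seed=int(truth["seed"][i]),
            )
        )
    return Dataset(
        images=images, prevalence=meta["prevalence"], seed=meta["seed"], config=cfg, aperture=ap
    )


def _np_default(o):
    """JSON fallback for numpy scalars (index tuples often carry np.int64)."""
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"Object of type {type(o).__name__} is not JSON serializable")


def _stats_to_json(s: ClassStats) -> dict:
    return {
        "d_present": s.d_present.tolist(),
        "d_absent": s.d_absent.tolist(),
        "k_matrix": s.k_matrix.tolist(),
        "n_present": s.n_present,
        "n_absent": s.n_absent,
    }


def _stats_from_json(d: dict) -> ClassStats:
    return ClassStats(
        d_present=np.array(d["d_present"]),
        d_absent=np.array(d["d_absent"]),
        k_matrix=np.array(d["k_matrix"]),
        n_present=int(d["n_present"]),
        n_absent=int(d["n_absent"]),
    )


def save_model(observer: FittedObserver, path) -> Path:
    """Serialize a fitted observer (grid spec, stage indices, statistics,
    thresholds, branches, config) to a JSON model file."""
    base = observer.base
    doc = {
        "bank_grid": base.bank.grid_spec,
        "refined_indices": list(base.refined_indices),
        "stage": {
            "search_indices": list(base.stage.search_indices),
            "decision_indices": list(base.stage.decision_indices),
        },
        "search_stats": _stats_to_json(base.search_stats),
        "decision_stats": _stats_to_json(base.decision_stats),
        "config": dataclasses.asdict(base.config),
        "thresholds": [
            None if not np.isfinite(t) else float(t) for t in observer.thresholds.thresholds
        ],
        "thresholded": observer.thresholded,
        "search_threshold": (
            None if observer.search_threshold == float("-inf") else float(observer.search_threshold)
        ),
        "branches": [
            {
                "key": list(b.branch_key),
                "stats": _stats_to_json(b.stats),
                "from_fallback": b.from_fallback,
            }
            for b in observer.branches.values()
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, default=_np_default))
    return path


def load_model(path) -> FittedObserver:
    doc = json.loads(Path(path).read_text())
    grid = doc["bank_grid"]
    bank = build_filter_bank(
        grid["ws"], grid["fc"], grid["theta"], grid["phi"], grid.get("support_px")
    )
    cfg_d = dict(doc["config"])
    cfg_d["threshold_grid_percentiles"] = tuple(cfg_d["threshold_grid_percentiles"])
    config = ObserverConfig(**cfg_d)
    base = ObserverBase(
        bank=bank,
        refined_indices=tuple(doc["refined_indices"]),
        stage=StageAssignment(
            tuple(doc["stage"]["search_indices"]), tuple(doc["stage"]["decision_indices"])
        ),
        search_stats=_stats_from_json(doc["search_stats"]),
        decision_stats=_stats_from_json(doc["decision_stats"]),
        config=config,
        train_decision_features=np.zeros((0, len(doc["thresholds"]))),
        train_labels=np.zeros(0, dtype=bool),
        train_loc_flags=np.zeros(0, dtype=bool),
    )
    thresholds = ThresholdSet(
        np.array([-np.inf if t is None else float(t) for t in doc["thresholds"]])
    )
    branches = {
        tuple(b["key"]): BranchStats(
            tuple(b["key"]), _stats_from_json(b["stats"]), bool(b["from_fallback"])
        )
        for b in doc["branches"]
    }
    st = doc.get("search_threshold")
    return FittedObserver(
        base=base,
        thresholds=thresholds,
        branches=branches,
        thresholded=doc["thresholded"],
        search_threshold=float("-inf") if st is None else float(st),
    )


def save_ratings(records: Sequence[CaseRecord], path) -> Path:
    rows = []
    for i, r in enumerate(records):
        rr, rc = r.reported_location if r.reported_location else (np.nan, np.nan)
        tr, tc = r.true_center if r.true_center else (np.nan, np.nan)
        rows.append(
            {
                "index": i,
                "rating": r.rating,
                "label": int(r.truth_label),
                "true_row": tr,
                "true_col": tc,
                "reported_row": rr,
                "reported_col": rc,
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_ratings(path) -> list[CaseRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        present = bool(row["label"])
        reported = (
            None
            if np.isnan(row["reported_row"])
            else (float(row["reported_row"]), float(row["reported_col"]))
        )
        true_center = (float(row["true_row"]), float(row["true_col"])) if present else None
        records.append(
            CaseRecord(
                rating=float(row["rating"]),
                truth_label=present,
                true_center=true_center,
                reported_location=reported,
            )
        )
    return records
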