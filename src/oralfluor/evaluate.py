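"""Patient-wise cross-validated image classification and reporting.

Protocol, per leave-one-patient-out fold:

1. hold out one patient's lesion image (with its paired healthy reference);
2. pool pixels from the remaining lesions, fit the full-pool L1-SVM, rank
   features by normalized absolute weight, and refit on the top-k;
3. score every *training* image: the image score is the arithmetic mean of
   its posterior probability map over valid pixels;
4. pick the image-score threshold on the training ROC curve with maximum
   sensitivity subject to a false-positive-rate ceiling (default 30%);
   candidate thresholds are the unique observed training scores plus one
   value above the maximum (predict-nobody is always feasible), and the
   decision rule is score >= threshold -> positive;
5. classify the held-out image with that model and threshold.

Ties on the constrained ROC point break toward lower FPR, then toward the
larger threshold.  Accumulated over folds: a confusion matrix (overall and
per histopathology grade), sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), accuracy = (TP+TN)/N, and the per-feature selection frequency
across folds.

A single-feature baseline emulating a blue-excitation autofluorescence
viewer (feature I452n+I500n, the combined NADH+FAD band share) runs the
identical protocol with no ranking step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import (
    PosteriorMap,
    TrainedModel,
    predict_posterior_map,
    resolve_pool,
    train_model,
)
from .errors import DataError
from .features import FeatureStack
from .simulate import HISTOPATHOLOGY_GRADES, POSITIVE_GRADES

logger = logging.getLogger(__name__)


@dataclass
class CohortItem:
    """One patient's extracted features, ready for cross-validation."""

    patient_id: str
    lesion_stack: FeatureStack
    histopathology: str
    site: str = ""
    total_intensity: Optional[np.ndarray] = None

    @property
    def label(self) -> int:
        return int(self.histopathology in POSITIVE_GRADES)


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class FoldResult:
    held_out_patient: str
    model: TrainedModel
    image_score: float
    threshold: float
    predicted_label: int
    true_label: int
    histopathology: str
    posterior: Optional[PosteriorMap] = None
    total_intensity: Optional[np.ndarray] = None


@dataclass
class CVReport:
    pool: str
    k: int
    C: float
    seed: int
    folds: list[FoldResult]
    confusion: ConfusionMatrix
    per_grade: dict[str, dict[str, int]]
    sensitivity: float
    specificity: float
    accuracy: float
    selection_frequency: dict[str, float]
    config: dict = field(default_factory=dict)


def image_score(posterior: PosteriorMap) -> float:
    """Mean posterior probability over the image's valid pixels."""
    vals = posterior.prob[posterior.mask.valid]
    if vals.size == 0:
        raise DataError("image has no valid pixels to score")
    return float(vals.mean())


def optimize_threshold(
    scores: Sequence[float], labels: Sequence[int], max_fpr: float = 0.30
) -> float:
    """Constrained-ROC operating point on training image scores.

    Over candidate thresholds (the unique observed scores plus one value
    above the maximum), with decision rule score >= threshold -> positive:
    keep points with FPR <= max_fpr, return the threshold maximizing
    sensitivity; ties break toward lower FPR, then toward the larger
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be matching 1-D sequences")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("threshold optimization needs both classes")
    candidates = np.append(np.unique(scores), scores.max() + 1.0)
    best: tuple[float, float, float] | None = None  # (sens, -fpr, theta)
    for theta in candidates:
        pred = scores >= theta
        sens = float((pred & (labels == 1)).sum()) / n_pos
        fpr = float((pred & (labels == 0)).sum()) / n_neg
        if fpr > max_fpr:
            continue
        key = (sens, -fpr, theta)
        if best is None or key > best:
            best = key
    assert best is not None  # theta above max is always feasible (FPR 0)
    return float(best[2])


def _confusion_from_folds(folds: Sequence[FoldResult]) -> ConfusionMatrix:
    tp = sum(1 for f in folds if f.true_label == 1 and f.predicted_label == 1)
    fn = sum(1 for f in folds if f.true_label == 1 and f.predicted_label == 0)
    tn = sum(1 for f in folds if f.true_label == 0 and f.predicted_label == 0)
    fp = sum(1 for f in folds if f.true_label == 0 and f.predicted_label == 1)
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def _per_grade(folds: Sequence[FoldResult]) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for grade in HISTOPATHOLOGY_GRADES:
        sub = [f for f in folds if f.histopathology == grade]
        if not sub:
            continue
        out[grade] = {
            "n": len(sub),
            "predicted_benign": sum(1 for f in sub if f.predicted_label == 0),
            "predicted_positive": sum(1 for f in sub if f.predicted_label == 1),
        }
    return out


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as fractions.

    Sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); accuracy =
    (TP+TN)/N.  Reporting elsewhere rounds to the nearest integer percent.
    """
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise DataError("metrics undefined: a class has no lesions")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    return sens, spec, acc


def as_percent(fraction: float) -> int:
    """Nearest-integer percent, the convention used in reports."""
    return int(round(100.0 * fraction))


def lopocv(
    cohort: Sequence[CohortItem],
    pool="absolute",
    k: int = 4,
    C: float = 1.0,
    pixel_cap: Optional[int] = 2000,
    max_fpr: float = 0.30,
    seed: int = 0,
    keep_maps: bool = True,
) -> CVReport:
    """Leave-one-patient-out cross-validation of the top-k L1-SVM pipeline."""
    names = resolve_pool(pool)
    labels = [item.label for item in cohort]
    if sum(labels) < 2 or len(labels) - sum(labels) < 2:
        raise DataError("need at least 2 patients per class for LOPOCV")
    folds: list[FoldResult] = []
    selection_counts = {n: 0 for n in names}
    for i, held_out in enumerate(cohort):
        train_items = [it for j, it in enumerate(cohort) if j != i]
        stacks_labels = [(it.lesion_stack, it.label) for it in train_items]
        model, _ = train_model(
            stacks_labels, names, k=min(k, len(names)), C=C, pixel_cap=pixel_cap, seed=seed
        )
        train_scores = [
            image_score(predict_posterior_map(model, it.lesion_stack)) for it in train_items
        ]
        theta = optimize_threshold(train_scores, [it.label for it in train_items], max_fpr)
        post = predict_posterior_map(model, held_out.lesion_stack)
        score = image_score(post)
        for f in model.selected_features:
            selection_counts[f] += 1
        folds.append(
            FoldResult(
                held_out_patient=held_out.patient_id,
                model=model,
                image_score=score,
                threshold=theta,
                predicted_label=int(score >= theta),
                true_label=held_out.label,
                histopathology=held_out.histopathology,
                posterior=post if keep_maps else None,
                total_intensity=held_out.total_intensity if keep_maps else None,
            )
        )
    cm = _confusion_from_folds(folds)
    sens, spec, acc = confusion_metrics(cm)
    n_folds = len(folds)
    return CVReport(
        pool=pool if isinstance(pool, str) else ",".join(names),
        k=min(k, len(names)),
        C=C,
        seed=seed,
        folds=folds,
        confusion=cm,
        per_grade=_per_grade(folds),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        selection_frequency={n: selection_counts[n] / n_folds for n in names},
        config={"pixel_cap": pixel_cap, "max_fpr": max_fpr},
    )


def velscope_baseline(
    cohort: Sequence[CohortItem],
    C: float = 1.0,
    pixel_cap: Optional[int] = 2000,
    max_fpr: float = 0.30,
    seed: int = 0,
    keep_maps: bool = True,
) -> CVReport:
    """Single-feature baseline (I452n+I500n) under the identical protocol."""
    return lopocv(
        cohort, pool="velscope", k=1, C=C, pixel_cap=pixel_cap,
        max_fpr=max_fpr, seed=seed, keep_maps=keep_maps,
    )


# ---------------------------------------------------------------------------
# Reporting


def _metrics_row(cv: CVReport) -> dict:
    return {
        "pool": cv.pool,
        "top_k": cv.k,
        "C": cv.C,
        "seed": cv.seed,
        "n_lesions": cv.confusion.total,
        "sensitivity": round(cv.sensitivity, 6),
        "specificity": round(cv.specificity, 6),
        "accuracy": round(cv.accuracy, 6),
        "sensitivity_pct": as_percent(cv.sensitivity),
        "specificity_pct": as_percent(cv.specificity),
        "accuracy_pct": as_percent(cv.accuracy),
    }


def _fold_record(f: FoldResult) -> dict:
    return {
        "held_out_patient": f.held_out_patient,
        "image_score": f.image_score,
        "threshold": f.threshold,
        "predicted_label": f.predicted_label,
        "true_label": f.true_label,
        "histopathology": f.histopathology,
        "model": f.model.to_dict(),
    }


def _write_overlays(cv: CVReport, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    for f in cv.folds:
        if f.posterior is None:
            continue
        fig, ax = plt.subplots(figsize=(3, 3))
        if f.total_intensity is not None:
            ax.imshow(f.total_intensity, cmap="gray", interpolation="nearest")
        red = np.zeros(f.posterior.prob.shape + (4,))
        p = np.nan_to_num(f.posterior.prob, nan=0.0)
        red[..., 0] = 1.0
        red[..., 3] = np.clip(p, 0, 1) * 0.8
        ax.imshow(red, interpolation="nearest")
        verdict = "positive" if f.predicted_label else "benign"
        color = "red" if f.predicted_label else "black"
        ax.set_title(f"{f.held_out_patient} ({f.histopathology}) -> {verdict}", color=color, fontsize=8)
        ax.axis("off")
        fig.savefig(out_dir / f"{f.held_out_patient}_posterior.png", dpi=100,
                    bbox_inches="tight")
        plt.close(fig)


def report(cvs, out_dir, overlays: bool = True) -> dict[str, Path]:
    """Write metrics, confusion matrices, selection frequencies, fold records
    and posterior-map overlays for one or more cross-validation runs."""
    if isinstance(cvs, CVReport):
        cvs = [cvs]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    metrics = pd.DataFrame([_metrics_row(cv) for cv in cvs])
    paths["metrics"] = out_dir / "metrics.csv"
    metrics.to_csv(paths["metrics"], index=False)

    confusion = {
        f"{cv.pool}_k{cv.k}": {
            "overall": {"TP": cv.confusion.tp, "FN": cv.confusion.fn,
                        "TN": cv.confusion.tn, "FP": cv.confusion.fp},
            "per_grade": cv.per_grade,
            "sensitivity_pct": as_percent(cv.sensitivity),
            "specificity_pct": as_percent(cv.specificity),
            "accuracy_pct": as_percent(cv.accuracy),
        }
        for cv in cvs
    }
    paths["confusion"] = out_dir / "confusion.json"
    paths["confusion"].write_text(json.dumps(confusion, indent=2))

    freq_rows = [
        {"pool": cv.pool, "top_k": cv.k, "feature": feat, "frequency": freq}
        for cv in cvs
        for feat, freq in cv.selection_frequency.items()
    ]
    paths["selection_frequency"] = out_dir / "selection_frequency.csv"
    pd.DataFrame(freq_rows).to_csv(paths["selection_frequency"], index=False)

    folds = {f"{cv.pool}_k{cv.k}": [_fold_record(f) for f in cv.folds] for cv in cvs}
    paths["folds"] = out_dir / "folds.json"
    paths["folds"].write_text(json.dumps(folds, indent=2))

    if overlays:
        for cv in cvs:
            _write_overlays(cv, out_dir / "overlays" / f"{cv.pool}_k{cv.k}")
    return paths
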