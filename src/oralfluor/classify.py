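"""Pixel-level L1-SVM training, embedded feature selection and posterior maps.

Training pools pixel feature vectors from every training image, each pixel
inheriting its image's binary histopathology label (dysplasia/carcinoma vs
benign) — a deliberate label-noise source, since the biopsy grades the lesion
centre, not individual pixels.  Features are z-scored on the training pixels
before the fit: the selection step compares weight magnitudes across
features, which is only meaningful on commensurate scales.

Feature selection is embedded in the linear SVM's L1 penalty: the fitted
weight magnitudes are normalized to sum to one, ranked descending (ties
broken by the canonical feature order), and the model is refit on the top-k
features only, to curb overfitting at small patient counts.  A Platt-style
logistic calibration fitted on the training decision values maps the refit
model's output to per-pixel posterior probabilities of malignancy.

The L1 solver is liblinear's squared-hinge + L1 formulation
(``LinearSVC(penalty="l1", loss="squared_hinge", dual=False)``); the variant
is recorded in every serialized model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .cube import PixelMask
from .errors import ConfigurationError, DataError
from .features import (
    ABSOLUTE_FEATURES,
    ALL_FEATURES,
    RELATIVE_FEATURES,
    VELSCOPE_FEATURE,
    FeatureStack,
)

logger = logging.getLogger(__name__)

SOLVER_VARIANT = "liblinear squared-hinge + L1 (LinearSVC dual=False)"

#: Named feature pools selectable for training.
POOLS = {
    "absolute": ABSOLUTE_FEATURES,
    "relative": RELATIVE_FEATURES,
    "both": ALL_FEATURES,
    "velscope": (VELSCOPE_FEATURE,),
}


def resolve_pool(pool) -> tuple[str, ...]:
    """Map a pool name or explicit feature sequence to a feature tuple."""
    if isinstance(pool, str):
        try:
            return POOLS[pool]
        except KeyError:
            raise ConfigurationError(
                f"unknown pool {pool!r}; choose from {sorted(POOLS)}"
            ) from None
    names = tuple(pool)
    if not names:
        raise ConfigurationError("feature pool must not be empty")
    return names


@dataclass
class FeatureRanking:
    """Features ordered by normalized absolute SVM weight."""

    normalized_weights: dict[str, float]
    order: tuple[str, ...]


@dataclass
class TrainedModel:
    """A refit top-k linear model with standardization and calibration.

    The decision value at a pixel with raw features x is
    ``d = w . (x - center) / scale + b`` and the posterior probability of the
    positive class is ``1 / (1 + exp(a*d + b0))`` with calibration (a, b0).
    """

    selected_features: tuple[str, ...]
    weights: np.ndarray
    bias: float
    center: np.ndarray
    scale: np.ndarray
    calibration: tuple[float, float]
    C: float = 1.0
    solver: str = SOLVER_VARIANT
    extra: dict = field(default_factory=dict)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.center) / self.scale
        return Z @ self.weights + self.bias

    def posterior(self, X: np.ndarray) -> np.ndarray:
        a, b0 = self.calibration
        d = self.decision_values(X)
        return 1.0 / (1.0 + np.exp(np.clip(a * d + b0, -500, 500)))

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "center": [float(c) for c in self.center],
            "scale": [float(s) for s in self.scale],
            "calibration": [float(v) for v in self.calibration],
            "C": float(self.C),
            "solver": self.solver,
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            selected_features=tuple(d["selected_features"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            calibration=(float(d["calibration"][0]), float(d["calibration"][1])),
            C=float(d.get("C", 1.0)),
            solver=d.get("solver", SOLVER_VARIANT),
            extra=d.get("extra", {}),
        )


@dataclass
class PosteriorMap:
    """Per-pixel probability of malignancy; NaN on masked pixels."""

    prob: np.ndarray
    mask: PixelMask

    def __post_init__(self) -> None:
        vals = self.prob[self.mask.valid]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise DataError("posterior probabilities must lie in [0, 1]")


def make_pixel_table(
    stacks_labels: Sequence[tuple[FeatureStack, int]],
    pool,
    pixel_cap: Optional[int] = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Pool valid pixels from training images into one feature matrix.

    Every pixel inherits its image's binary label.  If ``pixel_cap`` is set,
    at most that many pixels per image are kept via a seeded uniform
    subsample (without replacement), keeping cross-validation affordable;
    ``pixel_cap=None`` uses every valid pixel.
    """
    names = resolve_pool(pool)
    if not stacks_labels:
        raise DataError("no training images supplied")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7AB]))
    rows, labels = [], []
    for stack, label in stacks_labels:
        X = stack.matrix(names)
        if X.shape[0] == 0:
            raise DataError("an image contributed no valid pixels")
        if pixel_cap is not None and X.shape[0] > pixel_cap:
            idx = rng.choice(X.shape[0], size=pixel_cap, replace=False)
            idx.sort()
            X = X[idx]
        rows.append(X)
        labels.append(np.full(X.shape[0], int(label), dtype=int))
    return np.vstack(rows), np.concatenate(labels), names


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns pass through
    return (X - center) / scale, center, scale


def fit_l1_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Standardize and fit the L1-penalized linear SVM.

    Returns (weights, bias, center, scale); weights may contain exact zeros —
    that sparsity is what drives the feature selection.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("training pixels contain a single class")
    Z, center, scale = _standardize(np.asarray(X, dtype=float))
    svc = LinearSVC(
        C=C, penalty="l1", loss="squared_hinge", dual=False, tol=1e-4,
        max_iter=5000, random_state=0,  # liblinear shuffles internally
    )
    svc.fit(Z, y)
    return svc.coef_.ravel().copy(), float(svc.intercept_[0]), center, scale


def rank_features(weights: np.ndarray, feature_names: tuple[str, ...]) -> FeatureRanking:
    """Normalize |w| to sum 1 and sort descending.

    Ties (including the all-zero degenerate case) fall back to the canonical
    feature order, making the ranking fully deterministic.
    """
    w = np.abs(np.asarray(weights, dtype=float))
    if len(w) != len(feature_names):
        raise DataError("weight vector length must match the feature pool")
    total = w.sum()
    if total > 0:
        norm = w / total
    else:
        logger.warning("rank_features: all weights zero; falling back to canonical order")
        norm = w
    # stable sort on negated weights preserves canonical order among ties
    order_idx = np.argsort(-norm, kind="stable")
    return FeatureRanking(
        normalized_weights={n: float(v) for n, v in zip(feature_names, norm)},
        order=tuple(feature_names[i] for i in order_idx),
    )


def fit_platt_calibration(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Logistic map from decision value to positive-class probability.

    Fits p = 1/(1+exp(a*d + b)) on the training decision values with a
    weakly-regularized 1-D logistic regression (regularization only caps the
    slope on perfectly separated data).
    """
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    lr.fit(np.asarray(decision, dtype=float).reshape(-1, 1), np.asarray(y))
    # sklearn parameterizes p = sigmoid(w*d + c) = 1/(1+exp(-(w*d + c)))
    return -float(lr.coef_[0, 0]), -float(lr.intercept_[0])


def retrain_top_k(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: tuple[str, ...],
    ranking: FeatureRanking,
    k: int,
    C: float = 1.0,
) -> TrainedModel:
    """Refit the L1-SVM on the k top-ranked features and calibrate it.

    If fewer than k features carry nonzero weight, the remainder of the top-k
    is filled from zero-weight features in canonical order (with a warning).
    """
    if k < 1 or k > len(feature_names):
        raise ConfigurationError(f"k={k} out of range for pool size {len(feature_names)}")
    selected = ranking.order[:k]
    n_nonzero = sum(1 for f in selected if ranking.normalized_weights[f] > 0)
    if 0 < n_nonzero < k:
        logger.warning(
            "retrain_top_k: only %d/%d features have nonzero weight; "
            "filling from canonical order", n_nonzero, k,
        )
    cols = [feature_names.index(f) for f in selected]
    Xk = np.asarray(X, dtype=float)[:, cols]
    weights, bias, center, scale = fit_l1_svm(Xk, y, C=C)
    decision = ((Xk - center) / scale) @ weights + bias
    calibration = fit_platt_calibration(decision, y)
    return TrainedModel(
        selected_features=tuple(selected),
        weights=weights,
        bias=bias,
        center=center,
        scale=scale,
        calibration=calibration,
        C=C,
    )


def train_model(
    stacks_labels: Sequence[tuple[FeatureStack, int]],
    pool,
    k: int,
    C: float = 1.0,
    pixel_cap: Optional[int] = None,
    seed: int = 0,
) -> tuple[TrainedModel, FeatureRanking]:
    """Full training pass: pool pixels, rank by L1 weights, refit on top-k."""
    X, y, names = make_pixel_table(stacks_labels, pool, pixel_cap=pixel_cap, seed=seed)
    if len(names) == 1:
        # Single-feature pool (e.g. the VELscope surrogate): nothing to rank.
        ranking = FeatureRanking(normalized_weights={names[0]: 1.0}, order=names)
        return retrain_top_k(X, y, names, ranking, 1, C=C), ranking
    weights, _, _, _ = fit_l1_svm(X, y, C=C)
    ranking = rank_features(weights, names)
    return retrain_top_k(X, y, names, ranking, k, C=C), ranking


def predict_posterior_map(model: TrainedModel, stack: FeatureStack) -> PosteriorMap:
    """Apply a trained model pixel-wise over an image's valid pixels."""
    try:
        X = stack.matrix(model.selected_features)
    except KeyError as exc:
        raise DataError(f"feature stack lacks model feature {exc}") from exc
    prob = np.full(stack.mask.valid.shape, np.nan)
    if X.shape[0]:
        prob[stack.mask.valid] = model.posterior(X)
    return PosteriorMap(prob, stack.mask)
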