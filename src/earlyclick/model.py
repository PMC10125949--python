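"""Gradient-boosted tree classification under nested cross-validation.

The classifier is an XGBoost tree ensemble with logistic loss; rows with
missing feature values are routed by the learner's sparsity-aware default
directions, so informative missingness (an action never performed) needs no
imputation. Model selection and evaluation use nested cross-validation:
an outer k-fold loop (default k=5) estimates performance, and within each
outer training set an inner l-fold loop (default l=3) selects
hyperparameters from a grid over the number of trees {50, 100, 150}, the
maximum depth {3, 6, 9}, and the learning rate {0.01, 0.10}. Class
imbalance is handled by upsampling the minority class — replicating
minority rows until class counts match — applied to each training
partition only, never to validation rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from .features import FeatureConfig, FeatureExtractor, FeatureMatrix
from .windowing import EarlyWindowDataset

__all__ = [
    "HyperParams",
    "CVConfig",
    "FoldResult",
    "default_grid",
    "upsample",
    "fit_gbt",
    "nested_cv",
]


@dataclass(frozen=True, order=True)
class HyperParams:
    """One grid point; the ordering encodes the simpler-model tie-break."""

    n_trees: int = 100
    max_depth: int = 6
    learning_rate: float = 0.10


def default_grid() -> list[HyperParams]:
    """The full 3 x 3 x 2 study grid."""
    return [
        HyperParams(m, d, lr)
        for m, d, lr in itertools.product((50, 100, 150), (3, 6, 9), (0.01, 0.10))
    ]


@dataclass(frozen=True)
class CVConfig:
    outer_folds: int = 5
    inner_folds: int = 3
    seed: int = 0
    upsample: bool = True
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must both be >= 2")


@dataclass
class FoldResult:
    """Everything produced for one outer fold."""

    fold: int
    hyperparams: HyperParams
    model: XGBClassifier
    test_index: np.ndarray
    probabilities: np.ndarray  # predicted P(failure) for the held-out rows
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)


def upsample(
    X: pd.DataFrame, y: np.ndarray, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Replicate minority rows until class counts match.

    Added rows are exact replicas of existing minority rows, drawn with
    replacement; majority rows are untouched; balanced input is returned
    unchanged. Reproducible given ``seed``.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("upsampling requires both classes to be present")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    rng = np.random.default_rng(seed)
    minority_idx = np.flatnonzero(y == minority)
    extra = rng.choice(minority_idx, size=deficit, replace=True)
    X_up = pd.concat([X, X.iloc[extra]], axis=0)
    y_up = np.concatenate([y, y[extra]])
    return X_up, y_up


def fit_gbt(X: pd.DataFrame, y: np.ndarray, hp: HyperParams, seed: int = 0) -> XGBClassifier:
    """Fit one boosted-tree ensemble with logistic loss.

    NaN feature values are legal (sparsity-aware split finding); any other
    non-finite value is an error. Deterministic given data, hp and seed.
    """
    values = X.to_numpy(dtype=float)
    if np.isinf(values).any():
        raise ValueError("non-finite feature values other than missing (NaN) are not allowed")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = XGBClassifier(
        n_estimators=hp.n_trees,
        max_depth=hp.max_depth,
        learning_rate=hp.learning_rate,
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        importance_type="gain",
    )
    model.fit(X, y)
    return model


def _split(y: np.ndarray, k: int, seed: int, stratified: bool):
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for train, test in splitter.split(np.zeros_like(y), y):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError("a fold is missing a class; enable stratification or enlarge folds")
        yield train, test


def _inner_select(
    streams, X_fixed, y, grid, cv: CVConfig, feature_config: FeatureConfig, spec, seed: int
) -> HyperParams:
    """Inner l-fold grid search; selection by mean validation AUC.

    Ties are broken toward the simpler model: fewer trees, then smaller
    depth, then smaller learning rate.
    """
    scores: dict[HyperParams, list[float]] = {hp: [] for hp in grid}
    for j, (tr, va) in enumerate(_split(y, cv.inner_folds, seed, cv.stratified)):
        X_tr, X_va = _fold_features(streams, X_fixed, tr, va, feature_config, spec)
        y_tr, y_va = y[tr], y[va]
        if cv.upsample:
            X_tr, y_tr = upsample(X_tr, y_tr, seed=seed + 1000 + j)
        for hp in grid:
            model = fit_gbt(X_tr, y_tr, hp, seed=seed)
            prob = model.predict_proba(X_va)[:, 1]
            scores[hp].append(roc_auc_score(y_va, prob))
    best = max(grid, key=lambda hp: (np.mean(scores[hp]), _simplicity(hp)))
    return best


def _simplicity(hp: HyperParams) -> tuple:
    # larger is simpler, so negate for max()
    return (-hp.n_trees, -hp.max_depth, -hp.learning_rate)


def _fold_features(streams, X_fixed, train_idx, test_idx, feature_config, spec):
    """Featurize one split.

    With idf_scope='train' the document statistics and vocabularies are
    refitted on the training streams only; otherwise the precomputed
    subset-scope matrix is sliced.
    """
    if feature_config.idf_scope == "train" and streams is not None:
        extractor = FeatureExtractor(feature_config, spec)
        extractor.fit([streams[i] for i in train_idx])
        X_tr = extractor.transform([streams[i] for i in train_idx])
        X_te = extractor.transform([streams[i] for i in test_idx])
        return X_tr, X_te
    return X_fixed.iloc[train_idx], X_fixed.iloc[test_idx]


def nested_cv(
    data: EarlyWindowDataset | FeatureMatrix,
    grid: Sequence[HyperParams] | None = None,
    cv: CVConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> list[FoldResult]:
    """Nested cross-validation over one early-window dataset.

    ``data`` may be an :class:`EarlyWindowDataset` (features are built
    internally, honoring ``feature_config.idf_scope``) or a prebuilt
    :class:`FeatureMatrix` (subset scope only). Returns one
    :class:`FoldResult` per outer fold; every row is predicted exactly once
    out-of-fold.
    """
    grid = list(grid) if grid else default_grid()
    cv = cv or CVConfig()
    feature_config = feature_config or FeatureConfig()

    if isinstance(data, FeatureMatrix):
        if feature_config.idf_scope == "train":
            raise ValueError("idf_scope='train' requires the raw EarlyWindowDataset, not a prebuilt matrix")
        streams, X_fixed, y, spec = None, data.X, data.y, None
    else:
        streams = list(data.streams)
        y = data.labels
        spec = data.spec
        if feature_config.idf_scope == "train":
            X_fixed = None
        else:
            extractor = FeatureExtractor(feature_config, spec).fit(streams)
            X_fixed = extractor.transform(streams)

    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")

    results = []
    for i, (tr, te) in enumerate(_split(y, cv.outer_folds, cv.seed, cv.stratified)):
        inner_streams = [streams[j] for j in tr] if streams is not None else None
        inner_X = X_fixed.iloc[tr] if X_fixed is not None else None
        if len(grid) > 1:
            best = _inner_select(
                inner_streams, inner_X, y[tr], grid, cv, feature_config, spec, seed=cv.seed + 100 + i
            )
        else:
            best = grid[0]
        X_tr, X_te = _fold_features(streams, X_fixed, tr, te, feature_config, spec)
        y_tr = y[tr]
        if cv.upsample:
            X_tr, y_tr = upsample(X_tr, y_tr, seed=cv.seed + 500 + i)
        model = fit_gbt(X_tr, y_tr, best, seed=cv.seed)
        prob = model.predict_proba(X_te)[:, 1]
        results.append(
            FoldResult(
                fold=i,
                hyperparams=best,
                model=model,
                test_index=te,
                probabilities=prob,
                labels=y[te],
                feature_names=list(X_tr.columns),
            )
        )
    return results
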