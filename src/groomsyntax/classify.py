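"""Group classification from behavioral features, permutation chance
levels, and 2-D embeddings.

A multinomial logistic regression with light ridge regularization is
scored by repeated stratified k-fold cross-validation. Chance level is
estimated empirically by permuting group labels and re-running the same
cross-validation; for balanced cohorts it converges to 1/n_classes
(20% for five groups, 25% for four). t-SNE provides a 2-D visualization
of feature vectors; no novel computation is claimed there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger("groomsyntax")

DEFAULT_FOLDS = 5
DEFAULT_REPEATS = 10
DEFAULT_C = 1.0  # inverse ridge strength
DEFAULT_PERPLEXITY = 10.0


@dataclass
class ClassificationResult:
    feature_set: str
    accuracy: float
    per_class_accuracy: dict = field(default_factory=dict)
    chance: float | None = None
    cv_scheme: str = ""
    seed: int = 0


def _feature_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        features = features.drop(
            columns=[c for c in ("group_id", "session_id") if c in features.columns]
        )
        features = features.to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite (impute missing entries first)")
    return X


def _make_model(C: float, standardize: bool, seed: int | None):
    clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    return make_pipeline(StandardScaler(), clf) if standardize else clf


def _effective_folds(y: np.ndarray, k: int) -> int:
    smallest = int(pd.Series(y).value_counts().min())
    if smallest < k:
        warnings.warn(
            f"smallest class has {smallest} members; reducing folds from {k} to {smallest}",
            stacklevel=3,
        )
        return max(smallest, 2)
    return k


def classify(
    features,
    labels,
    n_folds: int = DEFAULT_FOLDS,
    n_repeats: int = DEFAULT_REPEATS,
    C: float = DEFAULT_C,
    standardize: bool = True,
    seed: int = 0,
    feature_set: str = "features",
) -> ClassificationResult:
    """Cross-validated accuracy of a multinomial logistic classifier.

    Standardization (z-score per feature) is fit on training folds only,
    inside the CV loop. Reported accuracy is the mean over
    ``n_repeats`` repetitions of stratified ``n_folds``-fold CV;
    deterministic for a fixed seed.
    """
    X = _feature_matrix(features)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 flies each")
    k = _effective_folds(y, n_folds)
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=n_repeats, random_state=seed)
    model = _make_model(C, standardize, seed)
    scores = cross_val_score(model, X, y, cv=cv, scoring="accuracy")

    # Per-class accuracy from one full round of held-out predictions.
    pred = cross_val_predict(
        model, X, y, cv=StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    )
    per_class = {c: float((pred[y == c] == c).mean()) for c in classes}
    return ClassificationResult(
        feature_set=feature_set,
        accuracy=float(scores.mean()),
        per_class_accuracy=per_class,
        cv_scheme=f"stratified {k}-fold x {n_repeats} repeats",
        seed=seed,
    )


def chance_level(
    features,
    labels,
    n_permutations: int = 100,
    n_folds: int = DEFAULT_FOLDS,
    C: float = DEFAULT_C,
    standardize: bool = True,
    seed: int = 0,
) -> dict:
    """Permutation estimate of chance classification accuracy.

    Group labels are permuted ``n_permutations`` times; each permutation
    is scored with one round of stratified k-fold CV. Returns the mean
    accuracy and the 2.5-97.5 percentile band. For balanced cohorts the
    mean approaches 1/n_classes.
    """
    if n_permutations < 10:
        warnings.warn("fewer than 10 permutations gives a crude chance estimate",
                      stacklevel=2)
    X = _feature_matrix(features)
    y = np.asarray(labels)
    k = _effective_folds(y, n_folds)
    rng = np.random.default_rng(seed)
    model = _make_model(C, standardize, seed)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        yp = rng.permutation(y)
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + i)
        accs[i] = cross_val_score(model, X, yp, cv=cv, scoring="accuracy").mean()
    lo, hi = np.percentile(accs, [2.5, 97.5])
    return {
        "mean": float(accs.mean()),
        "band": (float(lo), float(hi)),
        "accuracies": accs,
        "n_permutations": int(n_permutations),
    }


def embed_2d(
    features,
    perplexity: float = DEFAULT_PERPLEXITY,
    seed: int = 0,
) -> np.ndarray:
    """t-SNE embedding of per-fly feature vectors into 2-D.

    Deterministic for a fixed seed. Requires at least ``3 * perplexity``
    flies for a meaningful embedding.
    """
    X = _feature_matrix(features)
    if X.shape[0] < 3 * perplexity:
        raise ValueError(
            f"need at least {int(3 * perplexity)} flies for perplexity={perplexity}"
        )
    ts = TSNE(n_components=2, perplexity=perplexity, init="pca", random_state=seed)
    return ts.fit_transform(X)
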