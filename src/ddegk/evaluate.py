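"""Downstream evaluation of the learned embeddings.

The embeddings are judged the way whole-graph representations usually are:
an SVM over the vectors with grid-searched kernel and regularization,
scored by support-weighted F1 under stratified cross-validation; K-means
clustering scored by silhouette (SS) and adjusted Rand index (ARI, best of
ten consecutive runs); exact nearest-neighbor retrieval under the Euclidean
kernel; and a seeded t-SNE projection for visual inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score, f1_score, silhouette_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .errors import EmptyInput, InvalidK, TooFewPoints
from .kernel import EmbeddingMatrix, EventEmbedding, kernel_value

logger = logging.getLogger(__name__)

__all__ = ["ClassificationProtocol", "ClusteringProtocol",
           "f1_support_weighted", "classify_cv", "clustering_scores",
           "nearest_events", "project_2d"]


@dataclass
class ClassificationProtocol:
    folds: int = 10
    kernel_grid: tuple[str, ...] = ("linear", "rbf", "poly", "sigmoid")
    C_grid: tuple[float, ...] = tuple(10.0 ** e for e in range(1, 10))
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.kernel_grid or not self.C_grid:
            raise ValueError("grids must be non-empty")


@dataclass
class ClusteringProtocol:
    k: int = 2
    runs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


def f1_support_weighted(y_true, y_pred) -> float:
    """Per-class F1 = 2PR/(P+R), averaged with class-support weights."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise EmptyInput("no labels")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(f1_score(y_true, y_pred, average="weighted",
                          zero_division=0))


def _as_array(X) -> np.ndarray:
    return X.values() if isinstance(X, EmbeddingMatrix) else np.asarray(X)


def classify_cv(X, y, proto: ClassificationProtocol | None = None
                ) -> tuple[dict, float]:
    """Exhaustive SVM grid search (kernel x C) under stratified K-fold
    cross-validation; returns the best configuration and its mean
    support-weighted F1 across validation folds."""
    proto = proto or ClassificationProtocol()
    X = _as_array(X)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    folds = proto.folds
    if counts.min() < folds:
        folds = max(2, int(counts.min()))
        logger.warning("smallest class has %d members; reducing folds to %d",
                       counts.min(), folds)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=proto.seed)
    grid = GridSearchCV(
        SVC(), {"kernel": list(proto.kernel_grid), "C": list(proto.C_grid)},
        scoring="f1_weighted", cv=cv, n_jobs=1)
    grid.fit(X, y)
    return dict(grid.best_params_), float(grid.best_score_)


def clustering_scores(X, y_true, proto: ClusteringProtocol | None = None
                      ) -> tuple[float, float]:
    """(SS, ARI) of the best K-means partition over ``runs`` consecutive
    seeded runs (best = highest ARI against the true labels). SS is NaN
    when the best partition is degenerate (single cluster)."""
    proto = proto or ClusteringProtocol()
    X = _as_array(X)
    y_true = np.asarray(y_true)
    if len(X) <= proto.k:
        raise ValueError("need more samples than clusters")
    best_ari, best_labels = -np.inf, None
    for r in range(proto.runs):
        km = KMeans(n_clusters=proto.k, n_init=1,
                    random_state=proto.seed + r).fit(X)
        ari = adjusted_rand_score(y_true, km.labels_)
        if ari > best_ari:
            best_ari, best_labels = ari, km.labels_
    if len(np.unique(best_labels)) < 2:
        logger.error("degenerate single-cluster partition; SS undefined")
        return float("nan"), float(best_ari)
    ss = float(silhouette_score(X, best_labels, metric="euclidean"))
    return ss, float(best_ari)


def nearest_events(query: EventEmbedding, X: EmbeddingMatrix,
                   topk: int = 5) -> list[tuple[str, float]]:
    """Targets ranked by ascending kernel distance to the query; ties break
    on target id."""
    if topk < 1:
        raise InvalidK(f"topk={topk}")
    ranked = sorted(((r.target_id, kernel_value(query, r)) for r in X.rows),
                    key=lambda t: (t[1], t[0]))
    return ranked[:topk]


def project_2d(X, seed: int = 0) -> np.ndarray:
    """Seeded t-SNE projection of the embedding rows to 2 dimensions."""
    X = _as_array(X)
    n = len(X)
    if n < 3:
        raise TooFewPoints(f"n={n} < 3")
    perplexity = float(min(30.0, max(2.0, (n - 1) / 3.0)))
    tsne = TSNE(n_components=2, random_state=seed, init="random",
                perplexity=perplexity)
    return tsne.fit_transform(X)
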