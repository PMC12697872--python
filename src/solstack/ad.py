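"""Applicability-domain (AD) analysis.

Two complementary AD definitions over the standardized descriptor space:

* **Euclidean**: a query is in-domain when its distance to the training
  centroid is at or below the empirical coverage-level quantile (default
  95th percentile) of the training molecules' own distances. A k-nearest-
  neighbor mean-distance aggregation is available as an alternative.
* **Density**: the training set is embedded into two dimensions with t-SNE,
  a Gaussian kernel density (Scott bandwidth) is estimated on the embedded
  cloud, and the in-domain region is the highest density region (HDR)
  holding the coverage level of the training mass; a query is inside when
  its density reaches the HDR cutoff. Because t-SNE has no native
  out-of-sample transform, queries are placed at the inverse-distance
  weighted average of the embedded coordinates of their k = 10 nearest
  training neighbors in descriptor space; joint re-embedding of train +
  query is available behind a flag but is non-inductive (the training
  embedding then depends on the queries).

Quantiles use linear interpolation between order statistics throughout.
Both constructions make the training self-coverage equal the coverage level
up to 1/n rounding. The fitted thresholds are dataset- and seed-specific
values, stored on the model, never constants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.manifold import TSNE
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)


@dataclass
class ADModel:
    method: str                   # "euclidean" | "density"
    coverage_level: float
    threshold: float              # distance percentile or HDR density level
    # euclidean
    centroid: np.ndarray | None = None
    train_distances: np.ndarray | None = field(default=None, repr=False)
    knn_k: int | None = None      # set -> kNN mean distance instead of centroid
    knn_index: NearestNeighbors | None = field(default=None, repr=False)
    # density
    embedding: np.ndarray | None = field(default=None, repr=False)
    train_X: np.ndarray | None = field(default=None, repr=False)
    kde: gaussian_kde | None = field(default=None, repr=False)
    embed_seed: int | None = None
    oos_neighbors: int = 10
    #: largest mean k-NN distance observed among training molecules; the
    #: k-NN placement of a query farther than this from its neighbors is an
    #: extrapolation, so such queries are outside the domain by definition
    max_neighbor_distance: float | None = None


@dataclass
class ADMembership:
    inside: np.ndarray  # bool per query
    score: np.ndarray   # distance (euclidean) or density (density)


def fit_euclidean_ad(train_X_std: np.ndarray, coverage_level: float = 0.95,
                     knn_k: int | None = None) -> ADModel:
    """Fit the Euclidean-distance AD on standardized training descriptors.

    The in-domain score is the distance to the training centroid (or, with
    ``knn_k`` set, the mean distance to the k nearest training molecules);
    the threshold is the coverage-level quantile of the training scores.
    """
    X = np.asarray(train_X_std, dtype=float)
    if X.shape[0] < 20:
        warnings.warn("fewer than 20 training molecules: the AD quantile "
                      "threshold is unstable")
    if knn_k is not None:
        index = NearestNeighbors(n_neighbors=knn_k + 1).fit(X)
        d, _ = index.kneighbors(X)
        dist = d[:, 1:].mean(axis=1)  # exclude self
        return ADModel(method="euclidean", coverage_level=coverage_level,
                       threshold=float(np.quantile(dist, coverage_level)),
                       train_distances=dist, knn_k=knn_k, knn_index=index)
    centroid = X.mean(axis=0)
    dist = np.linalg.norm(X - centroid, axis=1)
    return ADModel(method="euclidean", coverage_level=coverage_level,
                   threshold=float(np.quantile(dist, coverage_level)),
                   centroid=centroid, train_distances=dist)


def fit_density_ad(train_X_std: np.ndarray, coverage_level: float = 0.95,
                   embed_seed: int = 0, embed: bool = True,
                   perplexity: float = 30.0, oos_neighbors: int = 10) -> ADModel:
    """Fit the density-HDR AD on standardized training descriptors.

    With ``embed=False`` the input is taken as already two-dimensional and
    the KDE is fitted on it directly (useful when coordinates come from an
    external embedding, or for testing the HDR machinery against analytic
    densities).
    """
    X = np.asarray(train_X_std, dtype=float)
    if X.shape[0] < 50:
        warnings.warn("fewer than 50 training molecules: density estimate "
                      "is unreliable")
    if embed:
        emb = TSNE(n_components=2, random_state=embed_seed,
                   perplexity=min(perplexity, (X.shape[0] - 1) / 3),
                   init="pca").fit_transform(X)
    else:
        if X.shape[1] != 2:
            raise ValueError("embed=False requires 2-D input coordinates")
        emb = X
    if np.allclose(emb.std(axis=0), 0):
        raise ValueError("degenerate embedding: all points coincident")
    kde = gaussian_kde(emb.T)  # Scott's rule bandwidth
    dens = kde(emb.T)
    # 95% HDR cutoff = 5th percentile of training-point densities
    level = float(np.quantile(dens, 1.0 - coverage_level))
    k = min(oos_neighbors + 1, X.shape[0])
    d_self, _ = NearestNeighbors(n_neighbors=k).fit(X).kneighbors(X)
    max_nbr = float(d_self[:, 1:].mean(axis=1).max())
    return ADModel(method="density", coverage_level=coverage_level,
                   threshold=level, embedding=emb, train_X=X, kde=kde,
                   embed_seed=embed_seed, oos_neighbors=oos_neighbors,
                   max_neighbor_distance=max_nbr)


def _embed_queries(model: ADModel, Xq: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-sample placement: inverse-distance weighted k-NN average.

    Also returns each query's mean neighbor distance in descriptor space;
    placement is only an interpolation while that distance stays within the
    range seen among training molecules.
    """
    nn = NearestNeighbors(n_neighbors=min(model.oos_neighbors,
                                          len(model.train_X)))
    nn.fit(model.train_X)
    d, idx = nn.kneighbors(Xq)
    w = 1.0 / np.maximum(d, 1e-12)
    w /= w.sum(axis=1, keepdims=True)
    return np.einsum("qk,qkd->qd", w, model.embedding[idx]), d.mean(axis=1)


def ad_membership(model: ADModel, query_X_std: np.ndarray,
                  joint: bool = False) -> ADMembership:
    """Classify queries as inside/outside the AD; boundary counts inside.

    For the density method, ``joint=True`` re-embeds training and query
    molecules together (non-inductive: the AD then depends on the query set)
    instead of the default k-NN out-of-sample placement.
    """
    Xq = np.asarray(query_X_std, dtype=float)
    if Xq.ndim != 2:
        raise ValueError("query matrix must be 2-D")
    if model.method == "euclidean":
        ref = model.centroid if model.knn_k is None else None
        if Xq.shape[1] != (len(ref) if ref is not None
                           else model.knn_index.n_features_in_):
            raise ValueError("feature-space mismatch with the fitted AD")
        if model.knn_k is None:
            score = np.linalg.norm(Xq - model.centroid, axis=1)
        else:
            d, _ = model.knn_index.kneighbors(Xq)
            score = d[:, :model.knn_k].mean(axis=1)
        return ADMembership(inside=score <= model.threshold, score=score)
    if model.method == "density":
        if Xq.shape[1] != model.train_X.shape[1]:
            raise ValueError("feature-space mismatch with the fitted AD")
        if joint:
            both = np.vstack([model.train_X, Xq])
            emb = TSNE(n_components=2, random_state=model.embed_seed,
                       perplexity=min(30.0, (both.shape[0] - 1) / 3),
                       init="pca").fit_transform(both)
            kde = gaussian_kde(emb[: len(model.train_X)].T)
            level = float(np.quantile(kde(emb[: len(model.train_X)].T),
                                      1.0 - model.coverage_level))
            score = kde(emb[len(model.train_X):].T)
            return ADMembership(inside=score >= level, score=score)
        emb_q, nbr_dist = _embed_queries(model, Xq)
        score = model.kde(emb_q.T)
        inside = score >= model.threshold
        if model.max_neighbor_distance is not None:
            inside &= nbr_dist <= model.max_neighbor_distance
        return ADMembership(inside=inside, score=score)
    raise ValueError(f"unknown AD method {model.method!r}")


def training_self_coverage(model: ADModel) -> float:
    """Fraction of the training set inside its own AD (≈ coverage level)."""
    if model.method == "euclidean":
        return float(np.mean(model.train_distances <= model.threshold))
    return float(np.mean(model.kde(model.embedding.T) >= model.threshold))


def ad_shrink_experiment(train_X_std: np.ndarray, y: np.ndarray,
                         coverages: list[float],
                         model_factory: Callable[[], object],
                         n_folds: int = 5, seed: int = 0,
                         min_molecules: int = 50) -> list[dict]:
    """Cross-validated error as the AD is tightened around the centroid.

    For each coverage level the training set is restricted to its in-AD
    molecules and the given model is scored by k-fold CV RMSE. Levels
    leaving fewer than ``min_molecules`` rows are skipped with a warning.
    Returns one row dict (coverage, n_kept, rmse) per retained level.
    """
    if len(coverages) < 3:
        raise ValueError("need at least 3 coverage levels")
    X = np.asarray(train_X_std, dtype=float)
    y = np.asarray(y, dtype=float)
    centroid = X.mean(axis=0)
    dist = np.linalg.norm(X - centroid, axis=1)
    rows = []
    for cov in coverages:
        thr = np.quantile(dist, cov)
        keep = dist <= thr
        n_kept = int(keep.sum())
        if n_kept < min_molecules:
            warnings.warn(f"coverage {cov}: only {n_kept} molecules, skipped")
            continue
        Xk, yk = X[keep], y[keep]
        pred = np.full(n_kept, np.nan)
        for tr, te in KFold(n_splits=n_folds, shuffle=True,
                            random_state=seed).split(Xk):
            est = model_factory()
            est.fit(Xk[tr], yk[tr])
            pred[te] = est.predict(Xk[te])
        rows.append({"coverage": float(cov), "n_kept": n_kept,
                     "rmse": float(np.sqrt(np.mean((pred - yk) ** 2)))})
    return rows
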