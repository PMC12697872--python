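"""Base learners, stacking ensembles and class re-balancing.

Four statistical learners (random forest, XGBoost, LightGBM, RBF-kernel
SVM) are combined by stacking: out-of-fold base predictions form the design
matrix of a linear meta-learner (MLR / Lasso / Ridge for regression,
logistic regression on concatenated per-class probabilities for
classification), after which the bases are refitted on the full training
set for inference. The arithmetic mean of the three stacking regressors is
the Ensemble-Mean predictor; the spread of its members per molecule is kept
as a self-agreement signal for reliability triage.

Class re-balancing (random under/over-sampling, SMOTE, Borderline-1/2,
SMOTE+ENN) is implemented here directly on top of nearest-neighbor queries
and is applied to training folds only — evaluation folds are never touched.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression, Ridge
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier, XGBRegressor

log = logging.getLogger(__name__)

#: hyperparameters used when a spec does not override them; kept deliberately
#: modest so that a full stacking fit stays cheap on mid-sized datasets
DEFAULT_BASE_HYPERPARAMS: dict[str, dict[str, Any]] = {
    "rf": {"n_estimators": 200, "n_jobs": 1},
    "xgb": {"n_estimators": 300, "learning_rate": 0.1, "max_depth": 6,
            "tree_method": "hist", "n_jobs": 1, "verbosity": 0},
    "lgbm": {"n_estimators": 300, "learning_rate": 0.1, "n_jobs": 1,
             "verbose": -1},
    "svm": {"kernel": "rbf", "C": 10.0},
}


@dataclass
class BaseSpec:
    """One base learner: algorithm name + hyperparameter overrides."""

    algorithm: str  # rf | xgb | lgbm | svm
    hyperparameters: dict[str, Any] = field(default_factory=dict)


@dataclass
class MetaSpec:
    """Meta-learner: mlr | lasso | ridge (regression), logistic (classif.)."""

    algorithm: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)


def default_base_specs() -> list[BaseSpec]:
    return [BaseSpec(a) for a in ("rf", "xgb", "lgbm", "svm")]


def _make_base(algorithm: str, task: str, hyperparameters: dict[str, Any],
               seed: int):
    params = dict(DEFAULT_BASE_HYPERPARAMS.get(algorithm, {}))
    params.update(hyperparameters)
    if algorithm == "rf":
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        return cls(random_state=seed, **params)
    if algorithm == "xgb":
        cls = XGBRegressor if task == "regression" else XGBClassifier
        return cls(random_state=seed, **params)
    if algorithm == "lgbm":
        cls = LGBMRegressor if task == "regression" else LGBMClassifier
        return cls(random_state=seed, **params)
    if algorithm == "svm":
        if task == "regression":
            return SVR(**params)
        return SVC(probability=True, random_state=seed, **params)
    raise ValueError(f"unknown base algorithm {algorithm!r}")


def _make_meta(spec: MetaSpec, task: str, seed: int):
    params = dict(spec.hyperparameters)
    if task == "regression":
        if spec.algorithm == "mlr":
            return LinearRegression(**params)
        if spec.algorithm == "lasso":
            params.setdefault("alpha", 0.001)
            return Lasso(random_state=seed, **params)
        if spec.algorithm == "ridge":
            params.setdefault("alpha", 1.0)
            return Ridge(random_state=seed, **params)
        raise ValueError(f"unknown regression meta-learner {spec.algorithm!r}")
    if spec.algorithm == "logistic":
        params.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=seed, **params)
    raise ValueError(f"unknown classification meta-learner {spec.algorithm!r}")


def _check_finite(X: np.ndarray) -> None:
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")


def fit_base(algorithm: str, X: np.ndarray, y: np.ndarray, task: str = "regression",
             hyperparameters: dict[str, Any] | None = None, seed: int = 0):
    """Fit a single base learner on standardized features."""
    _check_finite(np.asarray(X))
    est = _make_base(algorithm, task, hyperparameters or {}, seed)
    est.fit(X, y)
    return est


def tune_hyperparameters(algorithm: str, X: np.ndarray, y: np.ndarray,
                         grid: dict[str, Sequence[Any]], task: str = "regression",
                         n_folds: int = 5, seed: int = 0) -> dict[str, Any]:
    """Exhaustive grid search scored by cross-validated RMSE / accuracy.

    Grid points are visited in the order implied by the grid dict; ties are
    broken toward the earlier point, so the search is deterministic.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X, y = np.asarray(X), np.asarray(y)
    splitter = _splitter(task, n_folds, seed)
    keys = list(grid)
    best_score, best_params = None, None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        scores = []
        for tr, te in splitter.split(X, y if task == "classification" else None):
            if len(tr) < 2:
                raise ValueError("fold with fewer than 2 samples")
            est = _make_base(algorithm, task, params, seed)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[te])
            if task == "regression":
                scores.append(-float(np.sqrt(np.mean((pred - y[te]) ** 2))))
            else:
                scores.append(float(np.mean(pred == y[te])))
        score = float(np.mean(scores))
        if best_score is None or score > best_score:
            best_score, best_params = score, params
    return best_params


def _splitter(task: str, n_folds: int, seed: int):
    if task == "classification":
        return StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return KFold(n_splits=n_folds, shuffle=True, random_state=seed)


@dataclass
class StackedModel:
    """A fitted stacking ensemble (out-of-fold meta protocol)."""

    task: str
    base_specs: list[BaseSpec]
    meta_spec: MetaSpec
    n_folds: int
    seed: int
    classes_: np.ndarray | None = None
    base_models_: list[Any] = field(default_factory=list, repr=False)
    meta_model_: Any = None
    fold_assignment_: np.ndarray | None = None   # fold index per training row
    oof_design_: np.ndarray | None = None        # out-of-fold meta design
    n_features_: int | None = None
    fitted: bool = False

    # -- inference -------------------------------------------------------
    def _check(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature-space mismatch: expected {self.n_features_} features")
        _check_finite(X)
        return X

    def _meta_design(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for est in self.base_models_:
            if self.task == "regression":
                cols.append(est.predict(X).reshape(-1, 1))
            else:
                cols.append(_proba_full(est, X, self.classes_))
        return np.hstack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self._check(X)
        Z = self._meta_design(X)
        return self.meta_model_.predict(Z)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("predict_proba is classification-only")
        X = self._check(X)
        Z = self._meta_design(X)
        proba = self.meta_model_.predict_proba(Z)
        return proba / proba.sum(axis=1, keepdims=True)


def _proba_full(est, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Probability matrix aligned to the full class list (zeros if absent)."""
    p = est.predict_proba(X)
    out = np.zeros((X.shape[0], len(classes)))
    lookup = {c: i for i, c in enumerate(classes)}
    for j, c in enumerate(est.classes_):
        out[:, lookup[c]] = p[:, j]
    return out


def fit_stacking(base_specs: list[BaseSpec], meta_spec: MetaSpec,
                 X: np.ndarray, y: np.ndarray, task: str = "regression",
                 n_folds: int = 5, seed: int = 0) -> StackedModel:
    """Fit a stacking ensemble with a strict out-of-fold meta protocol.

    The meta-learner sees only predictions made by base models that did not
    train on the row in question; bases are then refitted on the full data
    for inference. Classification uses the concatenated per-class
    probability columns of every base as the meta design.
    """
    models = fit_stacking_multi(base_specs, [meta_spec], X, y, task=task,
                                n_folds=n_folds, seed=seed)
    return models[0]


def fit_stacking_multi(base_specs: list[BaseSpec], meta_specs: list[MetaSpec],
                       X: np.ndarray, y: np.ndarray, task: str = "regression",
                       n_folds: int = 5, seed: int = 0) -> list[StackedModel]:
    """Fit several stacking ensembles that share the same base learners.

    The expensive part of stacking — out-of-fold base predictions and the
    full-data refits — is identical for every meta-learner, so fitting the
    three regression metas at once costs one stacking run.
    """
    if len(base_specs) < 2:
        raise ValueError("stacking needs at least 2 base learners")
    if n_folds < 2:
        raise ValueError("stacking needs at least 2 folds")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_finite(X)

    classes = np.unique(y) if task == "classification" else None
    if task == "classification":
        counts = np.bincount(y.astype(int))
        if counts[counts > 0].min() < n_folds:
            raise ValueError(
                "stratified folds impossible: a class has fewer samples "
                f"than n_folds={n_folds}")
    splitter = _splitter(task, n_folds, seed)
    fold_assignment = np.empty(len(y), dtype=int)
    width = 1 if task == "regression" else len(classes)
    oof = np.full((len(y), width * len(base_specs)), np.nan)
    for f, (tr, te) in enumerate(splitter.split(X, y if task == "classification" else None)):
        fold_assignment[te] = f
        for b, spec in enumerate(base_specs):
            est = _make_base(spec.algorithm, task, spec.hyperparameters, seed)
            est.fit(X[tr], y[tr])
            if task == "regression":
                oof[te, b] = est.predict(X[te])
            else:
                oof[te, b * width:(b + 1) * width] = _proba_full(est, X[te], classes)
    assert np.isfinite(oof).all()

    full_bases = [
        fit_base(s.algorithm, X, y, task, s.hyperparameters, seed)
        for s in base_specs
    ]
    out = []
    for meta_spec in meta_specs:
        meta = _make_meta(meta_spec, task, seed)
        meta.fit(oof, y)
        out.append(StackedModel(
            task=task, base_specs=list(base_specs), meta_spec=meta_spec,
            n_folds=n_folds, seed=seed, classes_=classes,
            base_models_=full_bases, meta_model_=meta,
            fold_assignment_=fold_assignment, oof_design_=oof,
            n_features_=X.shape[1], fitted=True,
        ))
    return out


@dataclass
class EnsembleMean:
    """Arithmetic mean of the three stacking regressors.

    Member spread (sample SD over the three predictions) is retained per
    molecule as a self-agreement signal.
    """

    members: list[StackedModel]

    def __post_init__(self):
        if len(self.members) != 3:
            raise ValueError("Ensemble-Mean is defined over exactly 3 members")
        feats = {m.n_features_ for m in self.members}
        if len(feats) != 1:
            raise ValueError("members fitted on different feature spaces")

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (mean prediction, member SD) per row."""
        preds = np.column_stack([m.predict(X) for m in self.members])
        return preds.mean(axis=1), preds.std(axis=1, ddof=1)


def ensemble_mean_predict(members: list[StackedModel], X: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Functional form of :meth:`EnsembleMean.predict`."""
    return EnsembleMean(list(members)).predict(X)


# ---------------------------------------------------------------------------
# class re-balancing

RESAMPLING_TECHNIQUES = ("RandomUnder", "RandomOver", "SMOTE",
                         "Borderline1", "Borderline2", "SMOTEENN")


def resample_training(X: np.ndarray, y_class: np.ndarray, technique: str,
                      seed: int = 0, k_neighbors: int = 5,
                      m_neighbors: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Re-balance a training split; never apply to evaluation folds.

    Under-sampling draws every class down to the minority count; the
    over-sampling family raises every class to the majority count, either by
    duplication or by SMOTE-style interpolation between same-class nearest
    neighbors (Borderline variants restrict interpolation to points near the
    class boundary; SMOTE+ENN cleans the oversampled set with an edited
    nearest-neighbor pass). Inputs are never modified in place.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_class)
    if len(np.unique(y)) < 2:
        raise ValueError("re-sampling needs at least 2 classes")
    rng = np.random.default_rng(seed)
    if technique == "RandomUnder":
        return _random_under(X, y, rng)
    if technique == "RandomOver":
        return _random_over(X, y, rng)
    if technique == "SMOTE":
        return _smote(X, y, rng, k_neighbors)
    if technique == "Borderline1":
        return _borderline(X, y, rng, k_neighbors, m_neighbors, kind=1)
    if technique == "Borderline2":
        return _borderline(X, y, rng, k_neighbors, m_neighbors, kind=2)
    if technique == "SMOTEENN":
        Xs, ys = _smote(X, y, rng, k_neighbors)
        return _enn(Xs, ys)
    raise ValueError(f"unknown re-sampling technique {technique!r}")


def _class_indices(y: np.ndarray) -> dict[Any, np.ndarray]:
    return {c: np.flatnonzero(y == c) for c in np.unique(y)}


def _random_under(X, y, rng):
    by_class = _class_indices(y)
    target = min(len(ix) for ix in by_class.values())
    keep = np.concatenate([
        rng.choice(ix, size=target, replace=False) for ix in by_class.values()
    ])
    keep.sort()
    return X[keep].copy(), y[keep].copy()


def _random_over(X, y, rng):
    by_class = _class_indices(y)
    target = max(len(ix) for ix in by_class.values())
    rows = []
    for ix in by_class.values():
        rows.append(ix)
        deficit = target - len(ix)
        if deficit:
            rows.append(rng.choice(ix, size=deficit, replace=True))
    keep = np.concatenate(rows)
    return X[keep].copy(), y[keep].copy()


def _synthesize(X_cls: np.ndarray, seeds: np.ndarray, nn_pool: np.ndarray,
                n_new: int, rng, k: int, gap_hi: float = 1.0) -> np.ndarray:
    """SMOTE interpolation: new points on segments seed -> one of its k NN."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(nn_pool)))
    nn.fit(nn_pool)
    _, idx = nn.kneighbors(X_cls[seeds] if seeds is not None else X_cls)
    new = np.empty((n_new, X_cls.shape[1]))
    base = X_cls[seeds] if seeds is not None else X_cls
    for t in range(n_new):
        i = rng.integers(len(base))
        # skip column 0 (self) when pool == seeds source
        j = idx[i][rng.integers(1, idx.shape[1])] if idx.shape[1] > 1 else idx[i][0]
        u = rng.uniform(0, gap_hi)
        new[t] = base[i] + u * (nn_pool[j] - base[i])
    return new


def _smote(X, y, rng, k):
    by_class = _class_indices(y)
    target = max(len(ix) for ix in by_class.values())
    X_out, y_out = [X], [y]
    for c, ix in by_class.items():
        deficit = target - len(ix)
        if deficit == 0:
            continue
        if len(ix) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples; SMOTE impossible")
        kk = k
        if len(ix) <= k:
            kk = len(ix) - 1
            warnings.warn(f"class {c!r}: reducing SMOTE neighbors to {kk}")
        new = _synthesize(X[ix], None, X[ix], deficit, rng, kk)
        X_out.append(new)
        y_out.append(np.full(deficit, c, dtype=y.dtype))
    return np.vstack(X_out), np.concatenate(y_out)


def _borderline(X, y, rng, k, m, kind):
    by_class = _class_indices(y)
    target = max(len(ix) for ix in by_class.values())
    nn_all = NearestNeighbors(n_neighbors=min(m + 1, len(X))).fit(X)
    X_out, y_out = [X], [y]
    for c, ix in by_class.items():
        deficit = target - len(ix)
        if deficit == 0:
            continue
        _, nbr = nn_all.kneighbors(X[ix])
        n_maj = (y[nbr[:, 1:]] != c).sum(axis=1)
        m_eff = nbr.shape[1] - 1
        danger = ix[(n_maj >= m_eff / 2) & (n_maj < m_eff)]
        if len(danger) == 0:  # no borderline points: fall back to plain SMOTE
            danger = ix
        if len(ix) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        kk = min(k, len(ix) - 1)
        danger_pos = np.searchsorted(ix, danger)
        if kind == 1:
            new = _synthesize(X[ix], danger_pos, X[ix], deficit, rng, kk)
        else:
            # Borderline-2: half of the synthetics interpolate toward
            # majority-class neighbors, with a shortened gap
            n_min = deficit - deficit // 2
            new_min = _synthesize(X[ix], danger_pos, X[ix], n_min, rng, kk)
            maj_pool = X[y != c]
            new_maj = _synthesize(X[danger], None, maj_pool, deficit // 2,
                                  rng, min(k, len(maj_pool) - 1), gap_hi=0.5)
            new = np.vstack([new_min, new_maj])
        X_out.append(new)
        y_out.append(np.full(len(new), c, dtype=y.dtype))
    return np.vstack(X_out), np.concatenate(y_out)


def _enn(X, y, n_neighbors: int = 3):
    """Edited nearest neighbors: drop points whose 3-NN majority disagrees."""
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    keep = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        votes = y[idx[i, 1:]]
        vals, counts = np.unique(votes, return_counts=True)
        if vals[np.argmax(counts)] != y[i]:
            keep[i] = False
    if not keep.any():
        return X, y
    return X[keep], y[keep]


# ---------------------------------------------------------------------------
# benchmarking helper

def stacking_benchmark(X: np.ndarray, y: np.ndarray,
                       base_specs: list[BaseSpec] | None = None,
                       meta_spec: MetaSpec | None = None,
                       n_folds: int = 5, seed: int = 0) -> dict[str, Any]:
    """Cross-validated RMSE of each base learner vs the stacking ensemble.

    Base CV RMSE is computed from out-of-fold predictions on a shared fold
    split. The stacking RMSE reuses those out-of-fold base predictions as
    the meta design and cross-validates the meta-learner on it, so neither
    level ever scores a row it trained on.
    """
    base_specs = base_specs or default_base_specs()
    meta_spec = meta_spec or MetaSpec("lasso")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(splitter.split(X))
    oof = np.full((len(y), len(base_specs)), np.nan)
    for tr, te in folds:
        for b, spec in enumerate(base_specs):
            est = _make_base(spec.algorithm, "regression", spec.hyperparameters, seed)
            est.fit(X[tr], y[tr])
            oof[te, b] = est.predict(X[te])
    base_rmse = {
        spec.algorithm: float(np.sqrt(np.mean((oof[:, b] - y) ** 2)))
        for b, spec in enumerate(base_specs)
    }
    stack_pred = np.full(len(y), np.nan)
    for tr, te in folds:
        meta = _make_meta(meta_spec, "regression", seed)
        meta.fit(oof[tr], y[tr])
        stack_pred[te] = meta.predict(oof[te])
    return {
        "base_rmse": base_rmse,
        "stacking_rmse": float(np.sqrt(np.mean((stack_pred - y) ** 2))),
    }
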