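"""End-to-end predictor: curated table in, fitted dual-perspective model out.

Wires the stages together: descriptor computation, collinearity pruning,
z-scoring, the three stacking regressors (Lasso/Ridge/MLR meta) forming the
Ensemble-Mean, a LightGBM classifier on importance-selected features, and
the two applicability-domain models. Everything downstream (prediction,
reliability triage, the CLI) talks to the fitted :class:`SolubilityPredictor`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from lightgbm import LGBMClassifier

from .ad import ADModel, fit_density_ad, fit_euclidean_ad
from .chem import Molecule
from .curation import CuratedCompound
from .descriptors import (
    ScaleParams,
    apply_scale,
    compute_descriptors,
    prune_correlated,
    select_by_importance,
    standardize,
)
from .models import (
    BaseSpec,
    EnsembleMean,
    MetaSpec,
    default_base_specs,
    fit_stacking_multi,
)

log = logging.getLogger(__name__)


@dataclass
class SolubilityPredictor:
    """A fitted dual-perspective solubility model."""

    feature_names: list[str]          # pruned descriptor set (regression)
    scale: ScaleParams
    clf_feature_idx: np.ndarray       # classifier subset, indexes feature_names
    ensemble: EnsembleMean
    classifier: Any
    ad_euclid: ADModel
    ad_density: ADModel | None
    seed: int
    train_smiles: list[str] = field(default_factory=list, repr=False)

    def featurize(self, mols: list[Molecule]) -> np.ndarray:
        """Standardized descriptor rows aligned to the training features.

        Raises if a molecule lacks a finite value for any retained feature
        (such structures are outside what the model can score).
        """
        dm = compute_descriptors(mols)
        cols = []
        for name in self.feature_names:
            if name not in dm.feature_names:
                raise ValueError(
                    f"descriptor {name!r} unavailable for this query batch")
            cols.append(dm.column(name))
        X = np.column_stack(cols)
        if not np.isfinite(X).all():
            bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
            raise ValueError(
                f"non-finite descriptors for query rows {bad.tolist()}")
        return apply_scale(X, self.scale)

    def predict_logS(self, X_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ensemble-Mean Log S and member SD per row."""
        return self.ensemble.predict(X_std)

    def predict_class(self, X_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Classifier class labels and row-normalized 7-class probabilities."""
        Xc = X_std[:, self.clf_feature_idx]
        raw = self.classifier.predict_proba(Xc)
        proba = np.zeros((X_std.shape[0], 7))
        for j, c in enumerate(self.classifier.classes_):
            proba[:, int(c)] = raw[:, j]
        proba /= proba.sum(axis=1, keepdims=True)
        return proba.argmax(axis=1), proba


def train_pipeline(compounds: list[CuratedCompound], seed: int = 0,
                   base_specs: list[BaseSpec] | None = None,
                   n_folds: int = 5, corr_threshold: float = 0.9,
                   importance_threshold: float = 0.01,
                   coverage_level: float = 0.95,
                   fit_density: bool = True,
                   importance_trees: int = 500) -> SolubilityPredictor:
    """Fit the full dual-perspective model on a curated table.

    The three stacking regressors share one set of base learners (the
    out-of-fold protocol is identical for every meta-learner), so the
    Ensemble-Mean costs a single stacking run.
    """
    if len(compounds) < 50:
        raise ValueError("need at least 50 curated compounds to train")
    mols = [c.molecule for c in compounds]
    y = np.array([c.logS for c in compounds])
    y_class = np.array([c.sol_class for c in compounds], dtype=int)

    dm = compute_descriptors(mols)
    if dm.failed_rows:
        raise ValueError(f"descriptor failure for training rows {dm.failed_rows}")
    sel = prune_correlated(dm.values, dm.feature_names, corr_threshold)
    X = dm.values[:, sel.kept_idx]
    X_std, scale = standardize(X)
    log.info("feature pipeline: %d descriptors -> %d after |R| pruning",
             dm.values.shape[1], X.shape[1])

    base_specs = base_specs or default_base_specs()
    members = fit_stacking_multi(
        base_specs,
        [MetaSpec("lasso"), MetaSpec("ridge"), MetaSpec("mlr")],
        X_std, y, task="regression", n_folds=n_folds, seed=seed,
    )

    clf_sel = select_by_importance(X_std, y_class, sel.kept_features,
                                   importance_threshold, seed=seed,
                                   n_trees=importance_trees)
    clf_idx = clf_sel.kept_idx
    if len(clf_idx) == 0:  # degenerate: threshold wiped everything
        clf_idx = np.arange(X_std.shape[1])
    classifier = LGBMClassifier(n_estimators=300, learning_rate=0.1,
                                n_jobs=1, verbose=-1, random_state=seed)
    classifier.fit(X_std[:, clf_idx], y_class)

    ad_e = fit_euclidean_ad(X_std, coverage_level)
    ad_d = (fit_density_ad(X_std, coverage_level, embed_seed=seed)
            if fit_density else None)

    return SolubilityPredictor(
        feature_names=sel.kept_features,
        scale=scale,
        clf_feature_idx=clf_idx,
        ensemble=EnsembleMean(members),
        classifier=classifier,
        ad_euclid=ad_e,
        ad_density=ad_d,
        seed=seed,
        train_smiles=[m.canonical_smiles for m in mols],
    )
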