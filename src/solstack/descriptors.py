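"""Two-dimensional descriptor block and feature pipeline.

The full RDKit descriptor set (molecular properties, topology, connectivity,
constitution) is computed per molecule. Descriptors that fail for any
molecule in the batch — typical for metal-containing structures, where
e.g. Gasteiger-charge based descriptors are undefined — are dropped
globally so the matrix stays rectangular and NaN-free. Highly collinear
descriptors are then pruned (|Pearson R| above a threshold), the survivors
are z-scored on the training rows, and, for classification only, features
are further filtered by random-forest importance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import Descriptors
from rdkit import Chem
from sklearn.ensemble import RandomForestClassifier

from .chem import Molecule

log = logging.getLogger(__name__)

DESCRIPTOR_NAMES: tuple[str, ...] = tuple(name for name, _ in Descriptors.descList)


@dataclass
class DescriptorMatrix:
    """Rectangular descriptor block with feature bookkeeping."""

    compound_ids: list[str]
    feature_names: list[str]
    values: np.ndarray                       # compounds x features
    dropped_features: list[str] = field(default_factory=list)
    failed_rows: list[int] = field(default_factory=list)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]


@dataclass
class FeatureSelection:
    corr_threshold: float
    importance_threshold: float | None
    kept_features: list[str]
    kept_idx: np.ndarray


@dataclass
class ScaleParams:
    """Per-feature z-scoring statistics, fitted on training rows only."""

    mean: np.ndarray
    sd: np.ndarray   # population SD; zero-SD features are emitted as 0


def compute_descriptors(mols: list[Molecule]) -> DescriptorMatrix:
    """Compute the full RDKit descriptor vector for each molecule.

    A descriptor raising or returning a non-finite value for any molecule is
    removed for the whole batch (its name is recorded); a molecule for which
    every descriptor fails is flagged in ``failed_rows`` rather than imputed.
    """
    n = len(mols)
    values = np.full((n, len(DESCRIPTOR_NAMES)), np.nan)
    for i, m in enumerate(mols):
        rdmol = Chem.MolFromSmiles(m.canonical_smiles)
        if rdmol is None:
            continue
        for j, (_, fn) in enumerate(Descriptors.descList):
            try:
                values[i, j] = fn(rdmol)
            except Exception:  # descriptor undefined for this structure
                pass
    row_ok = np.isfinite(values).any(axis=1)
    failed_rows = list(np.flatnonzero(~row_ok))
    finite_cols = (np.isfinite(values[row_ok]).all(axis=0)
                   if row_ok.any() else np.ones(values.shape[1], dtype=bool))
    dropped = [n_ for n_, ok in zip(DESCRIPTOR_NAMES, finite_cols) if not ok]
    if dropped:
        log.info("dropped %d descriptors undefined for some molecule: %s",
                 len(dropped), dropped)
    return DescriptorMatrix(
        compound_ids=[m.canonical_smiles for m in mols],
        feature_names=[n_ for n_, ok in zip(DESCRIPTOR_NAMES, finite_cols) if ok],
        values=values[:, finite_cols],
        dropped_features=dropped,
        failed_rows=failed_rows,
    )


def prune_correlated(values: np.ndarray, feature_names: list[str],
                     corr_threshold: float = 0.9) -> FeatureSelection:
    """Greedily remove features too correlated with an earlier-kept one.

    Scanning in the native feature order, a feature is dropped when its
    absolute Pearson correlation with any already-kept feature exceeds the
    threshold. Constant (zero-variance) columns, for which Pearson R is
    undefined, are removed up front. Deterministic for a fixed column order.
    """
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    sd = values.std(axis=0)
    variable = sd > 0
    kept: list[int] = []
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    for j in range(values.shape[1]):
        if not variable[j]:
            continue
        if all(abs(corr[j, k]) <= corr_threshold for k in kept):
            kept.append(j)
    idx = np.asarray(kept, dtype=int)
    return FeatureSelection(
        corr_threshold=corr_threshold,
        importance_threshold=None,
        kept_features=[feature_names[j] for j in kept],
        kept_idx=idx,
    )


def standardize(values: np.ndarray, fit_rows: np.ndarray | None = None
                ) -> tuple[np.ndarray, ScaleParams]:
    """Z-score each column using statistics of the fit rows only.

    ``fit_rows`` is an index/boolean selector of the training rows (defaults
    to all rows). Columns with zero SD on the fit rows are emitted as zeros.
    """
    fit = values if fit_rows is None else values[fit_rows]
    if fit.shape[0] == 0:
        raise ValueError("fit_rows selects no rows")
    params = ScaleParams(mean=fit.mean(axis=0), sd=fit.std(axis=0))
    return apply_scale(values, params), params


def apply_scale(values: np.ndarray, params: ScaleParams) -> np.ndarray:
    """Apply previously fitted z-scoring to (possibly held-out) rows."""
    sd = np.where(params.sd > 0, params.sd, 1.0)
    return (values - params.mean) / sd


def select_by_importance(values: np.ndarray, class_labels: np.ndarray,
                         feature_names: list[str],
                         importance_threshold: float = 0.01,
                         seed: int = 0, n_trees: int = 500) -> FeatureSelection:
    """Keep features whose random-forest importance reaches the threshold.

    Used for the classification task only; the regression task keeps the
    full pruned descriptor set. Impurity importances of a seeded forest are
    normalized to sum to one before thresholding.
    """
    labels = np.asarray(class_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("importance selection needs at least two classes")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(values, labels)
    imp = forest.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    kept = np.flatnonzero(imp >= importance_threshold)
    return FeatureSelection(
        corr_threshold=math.nan,
        importance_threshold=importance_threshold,
        kept_features=[feature_names[j] for j in kept],
        kept_idx=kept,
    )
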