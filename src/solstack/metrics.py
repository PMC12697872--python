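"""Regression and classification metric suite.

Regression quality is reported as RMSE, R², MAPD and the two range metrics
%LogS±0.7 and %LogS±1.0 (share of predictions within 0.7 / 1.0 log units of
the reference — roughly one / two times the typical interlaboratory error).
Classification reports accuracy plus macro-averaged precision/recall/F1 and
one-vs-rest macro AUC and average precision; macro averaging is chosen
because the solubility classes are heavily imbalanced. The consistency
analysis compares the class implied by a regression prediction with the
class emitted by the classifier.

MAPD is computed on the Log S scale, consistent with every other regression
metric here; the boundary |error| = δ counts as within δ (inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .curation import assign_class, logS_to_gL


@dataclass
class MetricsReport:
    task: str
    n: int
    # regression
    rmse: float | None = None
    r2: float | None = None
    mapd: float | None = None            # %, on Log S values
    pct_within_07: float | None = None   # %
    pct_within_10: float | None = None   # %
    # classification
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    auc: float | None = None
    ap: float | None = None
    confusion: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k != "confusion" and v is not None}
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
        return d


def regression_metrics(y_true, y_pred) -> MetricsReport:
    """Evaluate Log S predictions against reference Log S values."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    err = y_pred - y_true
    sse = float(np.sum(err ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if np.any(y_true == 0):
        warnings.warn("zero reference value: MAPD undefined, reported missing")
        mapd = None
    else:
        mapd = float(100.0 * np.mean(np.abs(err / y_true)))
    return MetricsReport(
        task="regression",
        n=len(y_true),
        rmse=float(np.sqrt(np.mean(err ** 2))),
        r2=1.0 - sse / sst if sst > 0 else None,
        mapd=mapd,
        pct_within_07=float(100.0 * np.mean(np.abs(err) <= 0.7)),
        pct_within_10=float(100.0 * np.mean(np.abs(err) <= 1.0)),
    )


def classification_metrics(y_true, y_pred, y_prob: np.ndarray | None = None,
                           labels=None) -> MetricsReport:
    """Evaluate class predictions; AUC/AP need the probability matrix.

    Precision/recall/F1 are macro-averaged. AUC and AP are one-vs-rest,
    macro-averaged over classes present in ``y_true``; classes absent from
    the reference are excluded with a warning. ``labels`` gives the column
    order of ``y_prob`` (defaults to 0..6).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    labels = np.arange(7) if labels is None else np.asarray(labels)
    present = np.unique(y_true)
    auc = ap = None
    if y_prob is not None:
        y_prob = np.asarray(y_prob, dtype=float)
        if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        absent = [c for c in labels if c not in present]
        if absent:
            warnings.warn(f"classes {absent} absent from y_true; "
                          "excluded from macro AUC/AP")
        aucs, aps = [], []
        for j, c in enumerate(labels):
            if c not in present:
                continue
            onevr = (y_true == c).astype(int)
            if onevr.all():  # single-class reference: AUC undefined
                continue
            aucs.append(roc_auc_score(onevr, y_prob[:, j]))
            aps.append(average_precision_score(onevr, y_prob[:, j]))
        auc = float(np.mean(aucs)) if aucs else None
        ap = float(np.mean(aps)) if aps else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division in empty classes
        return MetricsReport(
            task="classification",
            n=len(y_true),
            accuracy=float(accuracy_score(y_true, y_pred)),
            precision=float(precision_score(y_true, y_pred, labels=present,
                                            average="macro", zero_division=0)),
            recall=float(recall_score(y_true, y_pred, labels=present,
                                      average="macro", zero_division=0)),
            f1=float(f1_score(y_true, y_pred, labels=present,
                              average="macro", zero_division=0)),
            auc=auc,
            ap=ap,
            confusion=confusion_matrix(y_true, y_pred, labels=labels),
        )


def regression_to_class(y_pred_logS, mol_weights) -> np.ndarray:
    """Convert Log S predictions to Pharmacopoeia classes via g/L."""
    y_pred_logS = np.asarray(y_pred_logS, dtype=float)
    mol_weights = np.asarray(mol_weights, dtype=float)
    if np.any(mol_weights <= 0):
        raise ValueError("molecular weights must be positive")
    return np.array([
        assign_class(logS_to_gL(ls, mw))
        for ls, mw in np.broadcast(y_pred_logS, mol_weights)
    ])


def consistency(reg_classes, clf_classes) -> tuple[float, float]:
    """Agreement between regression-derived and classifier classes.

    Returns ``(exact-match %, within-one-class %)``; the regression and
    classification perspectives are considered consistent for a molecule
    when their classes differ by at most one.
    """
    reg = np.asarray(reg_classes, dtype=int)
    clf = np.asarray(clf_classes, dtype=int)
    if reg.shape != clf.shape:
        raise ValueError("length mismatch")
    if len(reg) == 0:
        raise ValueError("empty inputs")
    diff = np.abs(reg - clf)
    return (float(100.0 * np.mean(diff == 0)),
            float(100.0 * np.mean(diff <= 1)))
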