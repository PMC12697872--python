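"""Reliability triage for predictions on unlabeled molecules.

A prediction for a molecule with no experimental value is only as good as
the evidence behind it. Four independent trust signals are checked per
molecule:

1. inside the Euclidean-distance applicability domain;
2. inside the density-HDR applicability domain;
3. the class implied by the Ensemble-Mean regression agrees with the
   classifier's class (within one class by default — adjacent classes are
   treated as agreement);
4. the three stacking regressors agree with each other (member SD at or
   below a tolerance, default 0.5 log units, the typical interlaboratory
   error).

Molecules meeting all four criteria form Group A (most reliable), three
Group B, two Group C, and one or none Group D. The four-signal set is this
package's reconstruction of a reliability workflow that is usually drawn,
not enumerated; every criterion can be toggled off, in which case a
disabled criterion counts as met.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ad import ad_membership
from .chem import SmilesParseError, canonicalize
from .curation import logS_to_gL
from .metrics import consistency, regression_to_class

GROUPS = ("A", "B", "C", "D")


@dataclass
class ReliabilityConfig:
    agreement_sd: float = 0.5       # log units, criterion 4 tolerance
    class_tolerance: int = 1        # criterion 3: |reg - clf| <= tolerance
    use_euclidean_ad: bool = True
    use_density_ad: bool = True
    use_class_agreement: bool = True
    use_member_sd: bool = True


def assign_group(n_criteria_met: int) -> str:
    """Map the number of satisfied criteria (0–4) to a reliability group."""
    if not 0 <= n_criteria_met <= 4:
        raise ValueError(f"criteria count {n_criteria_met} outside 0..4")
    return {4: "A", 3: "B", 2: "C"}.get(n_criteria_met, "D")


def criteria_flags(inside_euclid: np.ndarray, inside_density: np.ndarray,
                   reg_classes: np.ndarray, clf_classes: np.ndarray,
                   member_sd: np.ndarray,
                   config: ReliabilityConfig | None = None) -> np.ndarray:
    """Evaluate the four trust criteria from precomputed signals.

    Returns a boolean (n, 4) array; a criterion disabled in the config is
    reported as satisfied for every molecule.
    """
    config = config or ReliabilityConfig()
    n = len(reg_classes)
    flags = np.ones((n, 4), dtype=bool)
    if config.use_euclidean_ad:
        flags[:, 0] = np.asarray(inside_euclid, dtype=bool)
    if config.use_density_ad:
        flags[:, 1] = np.asarray(inside_density, dtype=bool)
    if config.use_class_agreement:
        flags[:, 2] = (np.abs(np.asarray(reg_classes, dtype=int)
                              - np.asarray(clf_classes, dtype=int))
                       <= config.class_tolerance)
    if config.use_member_sd:
        flags[:, 3] = np.asarray(member_sd, dtype=float) <= config.agreement_sd
    return flags


def evaluate_criteria(pipeline, X_std: np.ndarray, mol_weights: np.ndarray,
                      config: ReliabilityConfig | None = None
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Run all trust signals for a standardized query batch.

    Returns the (n, 4) criteria flags and a frame with the underlying
    predictions (Ensemble-Mean Log S, member SD, both class views, AD
    scores). Requires a pipeline with both AD models fitted when the AD
    criteria are enabled.
    """
    config = config or ReliabilityConfig()
    pred_logS, member_sd = pipeline.predict_logS(X_std)
    clf_classes, _ = pipeline.predict_class(X_std)
    reg_classes = regression_to_class(pred_logS, mol_weights)
    mem_e = ad_membership(pipeline.ad_euclid, X_std)
    if pipeline.ad_density is None:
        if config.use_density_ad:
            raise RuntimeError("density AD not fitted on this pipeline")
        inside_d = np.ones(len(pred_logS), dtype=bool)
        dens_score = np.full(len(pred_logS), np.nan)
    else:
        mem_d = ad_membership(pipeline.ad_density, X_std)
        inside_d, dens_score = mem_d.inside, mem_d.score
    flags = criteria_flags(mem_e.inside, inside_d, reg_classes, clf_classes,
                           member_sd, config)
    detail = pd.DataFrame({
        "pred_logS": pred_logS,
        "member_sd": member_sd,
        "pred_class_reg": reg_classes,
        "pred_class_clf": clf_classes,
        "euclid_distance": mem_e.score,
        "density": dens_score,
    })
    return flags, detail


def populate(smiles: list[str], pipeline,
             config: ReliabilityConfig | None = None
             ) -> tuple[pd.DataFrame, dict]:
    """Predict, triage and tabulate a list of unlabeled molecules.

    Returns the populated table (one row per parseable molecule, with both
    class views, the four criteria flags and the A–D group) and a summary
    with group fractions, the predicted class distribution, and the
    exact / within-one-class consistency between the two model views.
    Unparsable SMILES are listed in the summary, never silently dropped.
    """
    config = config or ReliabilityConfig()
    mols, unparsable = [], []
    for s in smiles:
        try:
            mols.append(canonicalize(s))
        except SmilesParseError:
            unparsable.append(s)
    if not mols:
        empty = pd.DataFrame(columns=[
            "canonical_smiles", "pred_logS", "pred_S_gL", "pred_class_reg",
            "pred_class_clf", "member_sd", "crit1", "crit2", "crit3",
            "crit4", "group"])
        return empty, {"n": 0, "unparsable": unparsable,
                       "group_fractions": {}, "class_distribution": {},
                       "consistency_exact_pct": None,
                       "consistency_within_one_pct": None}
    X_std = pipeline.featurize(mols)
    mw = np.array([m.mol_weight for m in mols])
    flags, detail = evaluate_criteria(pipeline, X_std, mw, config)
    n_met = flags.sum(axis=1)
    groups = np.array([assign_group(int(k)) for k in n_met])
    table = pd.DataFrame({
        "canonical_smiles": [m.canonical_smiles for m in mols],
        "pred_logS": detail["pred_logS"],
        "pred_S_gL": [logS_to_gL(ls, w)
                      for ls, w in zip(detail["pred_logS"], mw)],
        "pred_class_reg": detail["pred_class_reg"],
        "pred_class_clf": detail["pred_class_clf"],
        "member_sd": detail["member_sd"],
        "crit1": flags[:, 0],
        "crit2": flags[:, 1],
        "crit3": flags[:, 2],
        "crit4": flags[:, 3],
        "group": groups,
    })
    exact, within1 = consistency(table["pred_class_reg"], table["pred_class_clf"])
    summary = {
        "n": len(table),
        "unparsable": unparsable,
        "group_fractions": {g: float(np.mean(groups == g)) for g in GROUPS},
        "class_distribution": {int(c): int(k) for c, k in
                               table["pred_class_reg"].value_counts().items()},
        "consistency_exact_pct": exact,
        "consistency_within_one_pct": within1,
    }
    return table, summary
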