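"""Shared fixtures: synthetic datasets and fitted pipelines.

Everything is generated programmatically; the expensive fixtures
(the 2000-compound benchmark set and the pipeline trained on it) are
session-scoped so the acceptance tests amortize one build.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import solstack as ss

warnings.filterwarnings("ignore", message="X does not have valid feature names")


@pytest.fixture(scope="session")
def small_dataset():
    """120 molecules with noisy multi-source records (default conditions)."""
    spec = ss.SyntheticSpec(n_compounds=120, seed=7)
    mols, truth, records = ss.make_dataset(spec)
    return spec, mols, truth, records


@pytest.fixture(scope="session")
def bench2000():
    """Benchmark conditions: 2000 compounds, one record each, noise SD 0.5."""
    spec = ss.SyntheticSpec(n_compounds=2000, seed=201,
                            duplicate_rate=0.0, outlier_rate=0.0)
    mols, truth, records = ss.make_dataset(spec)
    compounds, _ = ss.curate_dataset(records)
    truth_by_smiles = {m.canonical_smiles: t for m, t in zip(mols, truth.logS)}
    true_logS = np.array([truth_by_smiles[c.molecule.canonical_smiles]
                          for c in compounds])
    return {"spec": spec, "truth": truth, "compounds": compounds,
            "true_logS": true_logS}


@pytest.fixture(scope="session")
def features2000(bench2000):
    """Pruned, standardized descriptor block of the benchmark compounds."""
    mols = [c.molecule for c in bench2000["compounds"]]
    dm = ss.compute_descriptors(mols)
    sel = ss.prune_correlated(dm.values, dm.feature_names, 0.9)
    X_std, scale = ss.standardize(dm.values[:, sel.kept_idx])
    return X_std


@pytest.fixture(scope="session")
def trained_pipeline(bench2000):
    """Full dual-perspective model on the first 1600 benchmark compounds."""
    train = bench2000["compounds"][:1600]
    return ss.train_pipeline(train, seed=0)


@pytest.fixture(scope="session")
def tiny_pipeline():
    """A fast, small pipeline for interface-level tests."""
    spec = ss.SyntheticSpec(n_compounds=150, seed=31,
                            duplicate_rate=0.0, outlier_rate=0.0)
    _, _, records = ss.make_dataset(spec)
    compounds, _ = ss.curate_dataset(records)
    light = [ss.BaseSpec("rf", {"n_estimators": 60}),
             ss.BaseSpec("lgbm", {"n_estimators": 80}),
             ss.BaseSpec("svm", {})]
    return ss.train_pipeline(compounds, seed=1, base_specs=light,
                             importance_trees=150), compounds
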