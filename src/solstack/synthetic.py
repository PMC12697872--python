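"""Synthetic solubility datasets with a known generating model.

Real multi-source solubility tables have a handful of statistical features
the pipeline must cope with: a near-normal Log S distribution whose bulk
sits around −5..−2, molecular weights mostly between 200 and 300 g/mol,
the same compound reported by several sources with ~0.5 log unit scatter,
occasional gross outliers, and a class histogram dominated by the poorly
soluble classes 5–6. This module generates molecule libraries from a small
fragment grammar and labels them with a descriptor-linear ground truth
(hydrophobicity-dominated, mirroring the empirical dominance of calculated
log P over aqueous solubility), so that every pipeline stage has an exactly
recoverable target.

The ground truth is deliberately a statistical stand-in, not a physical
solubility model: passing tests on it demonstrates that the machinery
(curation, feature pipeline, stacking, AD, triage) behaves as specified,
not that the models would reach any particular accuracy on laboratory data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .chem import Molecule, SolubilityRecord, Unit, canonicalize

# chain units that concatenate into valid linear SMILES (interior-safe)
_INTERIOR_UNITS = (
    "C", "CC", "CCC", "O", "N", "CO", "CN", "S",
    "C(C)", "C(=O)", "C(C)(C)", "c1ccccc1", "C1CCCCC1",
    "c1ccc(cc1)", "c1ccncc1", "C1CCNCC1", "C(=O)N", "C(=O)O",
)
# valence-1 units: only usable as the final token
_TERMINAL_UNITS = ("", "O", "N", "Cl", "F", "Br", "C(F)(F)F", "C#N", "C(=O)O")
# covalently written metal-containing caps used to exercise the
# metal-descriptor-failure path (kept charge-neutral)
_METAL_UNITS = ("O[Na]", "O[K]", "C[Sn](C)C")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_compounds: int = 2000
    seed: int = 0
    logS_mean: float = -3.5    # log units, bulk of the distribution
    logS_sd: float = 1.8
    mw_range: tuple[float, float] = (150.0, 450.0)
    noise_sd: float = 0.5      # log units, the typical interlaboratory error
    duplicate_rate: float = 0.5   # fraction of compounds with >1 source
    outlier_rate: float = 0.02    # fraction of records grossly perturbed
    # generating model: logS = a * cLogP + b * MW + c (pre-calibration)
    coeff_clogp: float = -1.0
    coeff_mw: float = -0.003
    intercept: float = -0.5
    calibrate: bool = True     # affinely rescale to hit logS_mean/logS_sd
    clip_range: tuple[float, float] = (-14.0, 2.0)
    include_metals: bool = False
    max_units: int = 8


@dataclass
class GroundTruth:
    """The recorded generating model, for parameter-recovery tests."""

    logS: np.ndarray
    coeff_clogp: float         # effective (post-calibration) coefficients
    coeff_mw: float
    intercept: float
    clipped: np.ndarray        # mask of values altered by clipping


def generate_library(spec: SyntheticSpec) -> list[Molecule]:
    """Assemble ``n_compounds`` unique molecules from the fragment grammar.

    Deterministic under ``spec.seed``; raises if the grammar cannot supply
    enough unique structures in the requested weight window.
    """
    rng = np.random.default_rng(spec.seed)
    seen: dict[str, Molecule] = {}
    lo, hi = spec.mw_range
    max_tries = 400 * spec.n_compounds + 1000
    tries = 0
    while len(seen) < spec.n_compounds and tries < max_tries:
        tries += 1
        n_units = int(rng.integers(2, spec.max_units + 1))
        parts = [str(rng.choice(_INTERIOR_UNITS)) for _ in range(n_units)]
        term_pool = _TERMINAL_UNITS + (_METAL_UNITS if spec.include_metals else ())
        parts.append(str(rng.choice(term_pool)))
        smiles = "".join(parts)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        mw = Descriptors.MolWt(mol)
        if not (lo <= mw <= hi):
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen[can] = canonicalize(can)
    if len(seen) < spec.n_compounds:
        raise RuntimeError(
            f"fragment grammar exhausted at {len(seen)} unique molecules; "
            "widen mw_range or extend the fragment set")
    return list(seen.values())


def assign_true_logS(molecules: list[Molecule], spec: SyntheticSpec) -> GroundTruth:
    """Label molecules with the descriptor-linear ground truth.

    ``logS = a·cLogP + b·MW + c``; with ``spec.calibrate`` the raw values
    are affinely mapped so that the library mean/SD match
    ``spec.logS_mean``/``spec.logS_sd``, and the *effective* coefficients of
    the resulting (still linear) model are recorded for recovery tests.
    """
    clogp = np.array([
        Crippen.MolLogP(Chem.MolFromSmiles(m.canonical_smiles))
        for m in molecules
    ])
    mw = np.array([m.mol_weight for m in molecules])
    raw = spec.coeff_clogp * clogp + spec.coeff_mw * mw + spec.intercept
    a, b, c = spec.coeff_clogp, spec.coeff_mw, spec.intercept
    if spec.calibrate and len(molecules) >= 2 and raw.std() > 0:
        scale = spec.logS_sd / raw.std()
        shift = spec.logS_mean - scale * raw.mean()
        raw = scale * raw + shift
        a, b, c = scale * a, scale * b, scale * c + shift
    clipped = (raw < spec.clip_range[0]) | (raw > spec.clip_range[1])
    logS = np.clip(raw, *spec.clip_range)
    return GroundTruth(logS=logS, coeff_clogp=a, coeff_mw=b, intercept=c,
                       clipped=clipped)


def apply_ground_truth(molecules: list[Molecule], gt: GroundTruth) -> np.ndarray:
    """Evaluate a recorded generating model on new molecules (no clipping).

    Lets query sets share the exact ground truth of a training library, e.g.
    out-of-domain molecules labeled by the same descriptor-linear model.
    """
    clogp = np.array([
        Crippen.MolLogP(Chem.MolFromSmiles(m.canonical_smiles))
        for m in molecules
    ])
    mw = np.array([m.mol_weight for m in molecules])
    return gt.coeff_clogp * clogp + gt.coeff_mw * mw + gt.intercept


def emit_records(molecules: list[Molecule], true_logS: np.ndarray,
                 spec: SyntheticSpec) -> list[SolubilityRecord]:
    """Emit noisy multi-source records for a labeled library.

    Each compound appears once, or (with probability ``duplicate_rate``)
    2–5 times as if reported by independent sources, each observation
    perturbed by N(0, noise_sd). A fraction ``outlier_rate`` of records is
    additionally shifted by ±(2–4) log units — gross transcription or assay
    errors the curation stage must absorb. Units are randomized over the
    full unit enum and the stored value converted accordingly.
    """
    rng = np.random.default_rng(spec.seed + 1)
    units = list(Unit)
    records: list[SolubilityRecord] = []
    for mol, ls in zip(molecules, np.asarray(true_logS, dtype=float)):
        n_rep = int(rng.integers(2, 6)) if rng.random() < spec.duplicate_rate else 1
        for r in range(n_rep):
            obs = ls + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            if rng.random() < spec.outlier_rate:
                obs += rng.choice([-1.0, 1.0]) * rng.uniform(2.0, 4.0)
            unit = units[int(rng.integers(len(units)))]
            if unit is Unit.LOGS:
                value = obs
            elif unit is Unit.MOL_L:
                value = 10.0 ** obs
            else:  # g/L and mg/mL are numerically identical
                value = 10.0 ** obs * mol.mol_weight
            records.append(SolubilityRecord(
                raw_smiles=mol.canonical_smiles,
                value=float(value),
                unit=unit,
                temperature_C=25.0,
                solvent="water",
                source_id=f"src_{r:02d}",
            ))
    return records


def make_dataset(spec: SyntheticSpec
                 ) -> tuple[list[Molecule], GroundTruth, list[SolubilityRecord]]:
    """Library + ground truth + noisy records in one call."""
    mols = generate_library(spec)
    truth = assign_true_logS(mols, spec)
    return mols, truth, emit_records(mols, truth.logS, spec)
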