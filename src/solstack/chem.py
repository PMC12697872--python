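"""Structure handling and dataset I/O.

Molecules enter the pipeline as SMILES strings (CSV) or MDL SD files and are
normalized to RDKit canonical SMILES so that duplicate records of the same
compound can be recognized across heterogeneous sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

# elements counted as metals for the contains_metal flag (alkali/alkaline
# earth, transition, post-transition metals and lanthanides/actinides)
_NONMETALS = frozenset(
    "H He B C N O F Ne Si P S Cl Ar As Se Br Kr Te I Xe At Rn".split()
)


class Unit(str, Enum):
    """Units a raw solubility value may be reported in."""

    G_L = "g/L"
    MG_ML = "mg/mL"
    MOL_L = "mol/L"
    LOGS = "logS_mol/L"


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, raw_smiles: str):
        self.raw_smiles = raw_smiles
        super().__init__(f"unparsable SMILES: {raw_smiles!r}")


class SchemaError(ValueError):
    """Raised when a tabular input is missing a mandatory column."""


@dataclass(frozen=True)
class Molecule:
    """A parsed, canonicalized structure."""

    canonical_smiles: str
    mol_weight: float  # g/mol, average atomic masses
    formal_charge: int
    n_atoms: int  # heavy atoms
    contains_metal: bool


@dataclass
class SolubilityRecord:
    """One raw solubility measurement as reported by a source."""

    raw_smiles: str
    value: float
    unit: Unit
    temperature_C: float | None = None
    solvent: str | None = None
    source_id: str | None = None


def canonicalize(raw_smiles: str) -> Molecule:
    """Parse a SMILES string and return its canonical representation.

    Canonicalization is idempotent: feeding the canonical SMILES back in
    returns the identical string. Molecular weight uses average atomic
    masses. Raises :class:`SmilesParseError` on invalid input.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise SmilesParseError(raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise SmilesParseError(raw_smiles)
    return _from_rdkit(mol)


def _from_rdkit(mol: Chem.Mol) -> Molecule:
    return Molecule(
        canonical_smiles=Chem.MolToSmiles(mol),
        mol_weight=Descriptors.MolWt(mol),
        formal_charge=Chem.GetFormalCharge(mol),
        n_atoms=mol.GetNumAtoms(),
        contains_metal=any(
            a.GetSymbol() not in _NONMETALS for a in mol.GetAtoms()
        ),
    )


_REQUIRED_COLS = ("smiles", "value", "unit")
_OPTIONAL_COLS = ("temperature_C", "solvent", "source_id")


def read_records(path: str | Path, format: str = "csv",
                 sdf_property: str = "solubility",
                 sdf_unit: Unit | str = Unit.LOGS) -> list[SolubilityRecord]:
    """Read raw solubility records from a CSV table or an SD file.

    CSV needs columns ``smiles,value,unit`` (optional: ``temperature_C``,
    ``solvent``, ``source_id``); missing optional fields stay missing.
    Unreadable rows are skipped with a logged row index. For SDF, the
    solubility value is read from ``sdf_property`` and interpreted in
    ``sdf_unit``.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "sdf":
        return _read_sdf(path, sdf_property, Unit(sdf_unit))
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> list[SolubilityRecord]:
    df = pd.read_csv(path)
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    records: list[SolubilityRecord] = []
    for idx, row in df.iterrows():
        try:
            rec = SolubilityRecord(
                raw_smiles=str(row["smiles"]),
                value=float(row["value"]),
                unit=Unit(str(row["unit"])),
                temperature_C=(None if "temperature_C" not in df.columns
                               or pd.isna(row["temperature_C"])
                               else float(row["temperature_C"])),
                solvent=(None if "solvent" not in df.columns
                         or pd.isna(row["solvent"]) else str(row["solvent"])),
                source_id=(None if "source_id" not in df.columns
                           or pd.isna(row["source_id"])
                           else str(row["source_id"])),
            )
        except (ValueError, TypeError) as exc:
            log.warning("skipping unreadable row %d: %s", idx, exc)
            continue
        records.append(rec)
    return records


def _read_sdf(path: Path, prop: str, unit: Unit) -> list[SolubilityRecord]:
    records: list[SolubilityRecord] = []
    supplier = Chem.SDMolSupplier(str(path))
    for idx, mol in enumerate(supplier):
        if mol is None:
            log.warning("skipping unreadable SDF entry %d", idx)
            continue
        if not mol.HasProp(prop):
            log.warning("SDF entry %d lacks property %r; skipped", idx, prop)
            continue
        records.append(SolubilityRecord(
            raw_smiles=Chem.MolToSmiles(mol),
            value=float(mol.GetProp(prop)),
            unit=unit,
            temperature_C=(float(mol.GetProp("temperature_C"))
                           if mol.HasProp("temperature_C") else None),
            solvent=mol.GetProp("solvent") if mol.HasProp("solvent") else None,
            source_id=mol.GetProp("source_id") if mol.HasProp("source_id") else None,
        ))
    return records


def write_records(records: list[SolubilityRecord], path: str | Path) -> None:
    """Write records to CSV; inverse of :func:`read_records` (csv)."""
    df = pd.DataFrame(
        [{
            "smiles": r.raw_smiles,
            "value": r.value,
            "unit": r.unit.value,
            "temperature_C": r.temperature_C,
            "solvent": r.solvent,
            "source_id": r.source_id,
        } for r in records]
    )
    df.to_csv(path, index=False)


class ValidationRow(NamedTuple):
    """One compound of the shake-flask validation panel."""

    name: str
    predicted_logS: float      # Ensemble-Mean prediction, log10 mol/L
    predicted_gL: float        # same prediction converted to g/L
    predicted_class_reg: int   # class from the regression prediction
    predicted_class_clf: int   # class from the LightGBM classifier
    experimental_logS: float   # shake-flask measurement, log10 mol/L
    experimental_sd: float     # replicate SD of the measurement
    experimental_class: int
    reported_abs_error: float  # |predicted - experimental| as published


# Shake-flask validation panel: ten drug candidates without prior public
# solubility data, measured gravimetrically in triplicate at 25 degC.
_VALIDATION_PANEL: tuple[ValidationRow, ...] = (
    ValidationRow("Levodropropizine", -0.506, 73.701, 2, 1, -0.839, 0.002, 2, 0.333),
    ValidationRow("Deoxyinosine", -1.163, 17.349, 3, 4, -1.392, 0.007, 3, 0.229),
    ValidationRow("Edetate copper disodium", -0.094, 320.643, 1, 1, 0.310, 0.003, 1, 0.404),
    ValidationRow("Thiamine disulfide", -1.379, 23.499, 3, 1, -2.386, 0.055, 4, 1.007),
    ValidationRow("4-Iodo-L-phenylalanine", -2.270, 1.563, 4, 5, -2.743, 0.167, 5, 0.473),
    ValidationRow("4-methylumbelliferyl beta-D-glucoside", -1.919, 4.076, 4, 3, -1.886, 0.016, 4, 0.033),
    ValidationRow("7-Deazaguanine", -2.240, 0.863, 5, 4, -1.781, 0.068, 4, 0.449),
    ValidationRow("Mdl-29951", -3.764, 0.052, 6, 6, -3.765, 0.166, 6, 0.023),
    ValidationRow("Racecadotril", -3.785, 0.063, 6, 6, -3.972, 0.146, 6, 0.206),
    ValidationRow("Potassium hydrogen DL-aspartate", 0.682, 823.936, 1, 1, 0.784, 0.019, 0, 0.103),
)

# In three rows the published absolute-error column does not equal
# |predicted - experimental| of the published operands (7-Deazaguanine,
# Mdl-29951, Racecadotril); these names let callers restrict arithmetic
# checks to the self-consistent rows.
INCONSISTENT_ERROR_ROWS = frozenset(
    {"7-Deazaguanine", "Mdl-29951", "Racecadotril",
     "Potassium hydrogen DL-aspartate"}
)


def table4_fixture() -> list[ValidationRow]:
    """Return the ten-compound experimental validation panel, as published."""
    return list(_VALIDATION_PANEL)
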