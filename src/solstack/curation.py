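"""Training-table curation.

Raw multi-source solubility records are converted to log10 mol/L (Log S),
filtered, grouped by canonical structure, and merged into one consensus
value per compound. Interlaboratory scatter in solubility measurement is
commonly around 0.5 log unit, so duplicate groups whose sample SD exceeds
that are cleaned by iterative outlier removal before averaging. Each curated
compound also carries its European Pharmacopoeia solubility class (0-6),
defined by the volume of water needed to dissolve one gram of substance.
"""

from __future__ import annotations

import logging
import math
import re
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .chem import Molecule, SmilesParseError, SolubilityRecord, Unit, canonicalize

log = logging.getLogger(__name__)

#: mL of water required to dissolve 1 g, upper bounds of classes 0..5
#: (class 6 = "practically insoluble", above the last bound)
CLASS_BOUNDS_ML_PER_G = (1.0, 10.0, 30.0, 100.0, 1000.0, 10000.0)

CLASS_NAMES = (
    "very soluble",
    "freely soluble",
    "soluble",
    "sparingly soluble",
    "slightly soluble",
    "very slightly soluble",
    "practically insoluble or insoluble",
)


@dataclass
class CurationConfig:
    """Tunable thresholds of the duplicate-merging protocol."""

    sd_threshold: float = 0.5      # log units; max SD tolerated for a merge
    duplicate_tol: float = 0.01    # log units; closer values = one occurrence
    temp_window_C: tuple[float, float] = (23.0, 27.0)  # 25 +/- 2 degC
    min_records_keep: int = 2      # never remove outliers below this count


@dataclass
class CuratedCompound:
    """A canonical molecule with its consensus Log S and class label."""

    molecule: Molecule
    logS: float
    n_sources: int
    sd_logS: float | None  # sample SD of merge survivors; None if < 2
    sol_class: int


@dataclass
class CurationReport:
    n_records_in: int = 0
    n_records_kept: int = 0
    n_compounds: int = 0
    drops_by_reason: Counter = field(default_factory=Counter)
    n_parse_failures: int = 0
    #: per-compound SD of merge survivors, compounds with >= 3 sources
    sd_multi_source: list[float] = field(default_factory=list)

    @property
    def mean_sd_multi_source(self) -> float | None:
        if not self.sd_multi_source:
            return None
        return float(np.mean(self.sd_multi_source))


def to_logS(value: float, unit: Unit | str, mol_weight: float) -> float:
    """Convert a solubility value to Log S = log10 of mol/L.

    g/L and mg/mL are divided by the molecular weight before the log;
    mol/L is logged directly; Log S values pass through unchanged.
    """
    unit = Unit(unit)
    if unit is Unit.LOGS:
        return float(value)
    if value <= 0:
        raise ValueError(f"non-positive solubility {value} with linear unit {unit.value}")
    if mol_weight <= 0:
        raise ValueError("mol_weight must be positive")
    if unit in (Unit.G_L, Unit.MG_ML):  # mg/mL == g/L numerically
        return math.log10(value / mol_weight)
    return math.log10(value)  # mol/L


def logS_to_gL(logS: float, mol_weight: float) -> float:
    """Convert Log S (log10 mol/L) back to g/L."""
    if mol_weight <= 0:
        raise ValueError("mol_weight must be positive")
    return 10.0 ** logS * mol_weight


def assign_class(S_gL: float) -> int:
    """Map a solubility in g/L to the seven-class Pharmacopoeia index.

    The classes are defined by mL of water per gram of solute (1000/S):
    class 0 below 1 mL ("very soluble") up to class 6 at 10000 mL or more
    ("practically insoluble"). Boundaries fall to the less-soluble class on
    the mL scale (intervals left-closed), i.e. the more-soluble side in S.
    """
    if S_gL < 0:
        raise ValueError("solubility must be non-negative")
    if S_gL == 0:
        return 6
    ml_per_g = 1000.0 / S_gL
    return bisect_right(CLASS_BOUNDS_ML_PER_G, ml_per_g)


def logS_to_class(logS: float, mol_weight: float) -> int:
    """Compose :func:`logS_to_gL` and :func:`assign_class`."""
    return assign_class(logS_to_gL(logS, mol_weight))


def filter_record(rec: SolubilityRecord, mol: Molecule,
                  cfg: CurationConfig | None = None) -> tuple[bool, str | None]:
    """Decide whether a record enters the training table.

    Single-atom structures and net-charged species are excluded; records at
    temperatures outside the room-temperature window or in non-aqueous
    solvents are excluded when those fields are present. Salts, inorganics
    and metal-containing molecules are deliberately kept. Returns
    ``(keep, reason)`` where ``reason`` is a machine-readable drop code.
    """
    cfg = cfg or CurationConfig()
    if mol.n_atoms <= 1:
        return False, "single_atom"
    if mol.formal_charge != 0:
        return False, "charged"
    if rec.temperature_C is not None:
        lo, hi = cfg.temp_window_C
        if not (lo <= rec.temperature_C <= hi):
            return False, "temperature"
    if rec.solvent is not None and rec.solvent.strip().lower() not in ("water", "h2o", "aqueous"):
        return False, "solvent"
    return True, None


def _collapse_near_duplicates(values: list[float], tol: float) -> list[float]:
    # values within tol of each other count as a single occurrence;
    # greedy clustering over the sorted list, each cluster -> its mean
    if tol <= 0:
        return sorted(values)
    out: list[float] = []
    cluster: list[float] = []
    for v in sorted(values):
        if not cluster or v - cluster[0] < tol:
            cluster.append(v)
        else:
            out.append(float(np.mean(cluster)))
            cluster = [v]
    out.append(float(np.mean(cluster)))
    return out


def merge_duplicates(values: list[float] | np.ndarray,
                     cfg: CurationConfig | None = None) -> tuple[float, list[float]]:
    """Merge multi-source Log S values into one consensus value.

    Values closer than ``duplicate_tol`` are first collapsed to a single
    occurrence. One or two remaining values are averaged unconditionally.
    With more, the value farthest from the current mean is removed
    repeatedly while the sample SD exceeds ``sd_threshold`` and more than
    ``min_records_keep`` values remain. Ties on distance-to-mean are broken
    toward the value farther from the median, then toward the lower value.

    Returns ``(consensus mean, surviving values)``.
    """
    cfg = cfg or CurationConfig()
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cannot merge an empty list of values")
    vals = _collapse_near_duplicates(vals, cfg.duplicate_tol)
    while len(vals) > max(2, cfg.min_records_keep):
        if np.std(vals, ddof=1) <= cfg.sd_threshold:
            break
        mean = float(np.mean(vals))
        median = float(np.median(vals))
        # farthest from mean; ties -> farther from median, then lower value
        vals.sort(key=lambda v: (-abs(v - mean), -abs(v - median), v))
        vals.pop(0)
    return float(np.mean(vals)), sorted(vals)


def curate_dataset(records: list[SolubilityRecord],
                   cfg: CurationConfig | None = None
                   ) -> tuple[list[CuratedCompound], CurationReport]:
    """Run the full curation workflow over raw records.

    Records are parsed and grouped by canonical SMILES, filtered, converted
    to Log S, and merged per compound; each compound gets its Pharmacopoeia
    class from the consensus value. The report accounts for every input
    record (kept + dropped + unparsable = input).
    """
    cfg = cfg or CurationConfig()
    report = CurationReport(n_records_in=len(records))
    groups: dict[str, tuple[Molecule, list[float]]] = {}
    for rec in records:
        try:
            mol = canonicalize(rec.raw_smiles)
        except SmilesParseError:
            report.n_parse_failures += 1
            report.drops_by_reason["parse_error"] += 1
            continue
        keep, reason = filter_record(rec, mol, cfg)
        if not keep:
            report.drops_by_reason[reason] += 1
            continue
        try:
            logS = to_logS(rec.value, rec.unit, mol.mol_weight)
        except ValueError:
            report.drops_by_reason["bad_value"] += 1
            continue
        groups.setdefault(mol.canonical_smiles, (mol, []))[1].append(logS)
        report.n_records_kept += 1

    compounds: list[CuratedCompound] = []
    for smiles, (mol, vals) in groups.items():
        consensus, survivors = merge_duplicates(vals, cfg)
        sd = float(np.std(survivors, ddof=1)) if len(survivors) >= 2 else None
        if len(vals) >= 3 and sd is not None:
            report.sd_multi_source.append(sd)
        compounds.append(CuratedCompound(
            molecule=mol,
            logS=consensus,
            n_sources=len(vals),
            sd_logS=sd,
            sol_class=logS_to_class(consensus, mol.mol_weight),
        ))
    report.n_compounds = len(compounds)
    return compounds, report


def exclude_overlap(train: list[CuratedCompound],
                    test_sets: list[list[Molecule]]
                    ) -> tuple[list[CuratedCompound], int]:
    """Drop training compounds that occur in any external test set.

    Prevents data leakage between the training repository and evaluation
    sets; matching is by canonical SMILES. Returns the reduced list and the
    number removed.
    """
    held_out = {m.canonical_smiles for ts in test_sets for m in ts}
    kept = [c for c in train if c.molecule.canonical_smiles not in held_out]
    return kept, len(train) - len(kept)


@dataclass
class ExternalRecord:
    """A free-text database entry (e.g. a DrugBank solubility annotation)."""

    raw_smiles: str
    description: str                 # e.g. "7.3 mg/mL", "< 0.01 g/L"
    source: str | None = None
    temperature_C: float | None = None
    solvent: str | None = None


@dataclass
class ExternalResult:
    keep: bool
    reason: str | None = None        # drop code when keep is False
    logS: float | None = None        # None for class-only records
    sol_class: int | None = None
    class_only: bool = False


_VALUE_RE = re.compile(
    r"^\s*(?P<rel><|>|<=|>=|less than|greater than)?\s*"
    r"(?P<num>[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*"
    r"(?P<unit>g/L|mg/mL|mol/L)\s*$",
    re.IGNORECASE,
)

_UNIT_ALIASES = {"g/l": Unit.G_L, "mg/ml": Unit.MG_ML, "mol/l": Unit.MOL_L}


def curate_external_records(records: list[ExternalRecord],
                            cfg: CurationConfig | None = None
                            ) -> list[ExternalResult]:
    """Apply the external-database exclusion rules to free-text records.

    Entries with unspecified source, temperature, solvent or units are
    dropped, as are entries outside the room-temperature window or in
    non-aqueous solvents. Bounded descriptions such as "< 0.01 g/L" cannot
    yield a Log S value but map unambiguously to a class, so they are kept
    as class-only records.
    """
    cfg = cfg or CurationConfig()
    out: list[ExternalResult] = []
    for rec in records:
        if rec.source is None:
            out.append(ExternalResult(False, "no_source"))
            continue
        if rec.temperature_C is None:
            out.append(ExternalResult(False, "no_temperature"))
            continue
        if rec.solvent is None:
            out.append(ExternalResult(False, "no_solvent"))
            continue
        lo, hi = cfg.temp_window_C
        if not (lo <= rec.temperature_C <= hi):
            out.append(ExternalResult(False, "temperature"))
            continue
        if rec.solvent.strip().lower() not in ("water", "h2o", "aqueous"):
            out.append(ExternalResult(False, "solvent"))
            continue
        m = _VALUE_RE.match(rec.description)
        if m is None:
            out.append(ExternalResult(False, "no_units"))
            continue
        try:
            mw = canonicalize(rec.raw_smiles).mol_weight
        except SmilesParseError:
            out.append(ExternalResult(False, "parse_error"))
            continue
        unit = _UNIT_ALIASES[m.group("unit").lower()]
        value = float(m.group("num"))
        if value <= 0:
            out.append(ExternalResult(False, "bad_value"))
            continue
        logS = to_logS(value, unit, mw)
        if m.group("rel"):
            rel = m.group("rel").lower()
            S_gL = logS_to_gL(logS, mw)
            cls = assign_class(S_gL)
            # a bound only pins the class if the open side stays in-class;
            # "< x" can only move toward less soluble (higher class), so it
            # is unambiguous for the top class; symmetric for "> x"/class 0.
            if rel in ("<", "<=", "less than") and cls == 6:
                out.append(ExternalResult(True, sol_class=6, class_only=True))
            elif rel in (">", ">=", "greater than") and cls == 0:
                out.append(ExternalResult(True, sol_class=0, class_only=True))
            else:
                out.append(ExternalResult(False, "ambiguous_range"))
            continue
        out.append(ExternalResult(True, logS=logS,
                                  sol_class=logS_to_class(logS, mw)))
    return out
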