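"""Copy-number estimation and MR-solution triage.

The Matthews coefficient Vm = V_cell / (Z x M_asu) (Å³/Da) relates unit-cell
volume to asymmetric-unit mass; solvent fraction follows as 1 - 1.23/Vm.
Candidate copy numbers are scanned and the count whose solvent content lands
closest to 50% (while staying above 25%) is selected.

Solution triage applies the standard score thresholds: refined R_free bands
GOOD (< 0.35) / MARGINAL (<= 0.5) / POOR (> 0.5), a Phaser LLG gain of 60 as
a strong success indicator, MOLREP TF/sigma above 8 for correct placement,
and a density-modification trace with CC > 25% and mean chain length >= 10
residues as independent confirmation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Sequence

import pandas as pd

from .errors import GeometryError

#: Matthews constant relating Vm to protein volume fraction (Å³/Da).
MATTHEWS_PROTEIN_DENSITY = 1.23

#: Mean amino-acid residue mass used when no sequence is given (Da).
DEFAULT_RESIDUE_MASS = 110.0

#: Average residue masses (Da, water of condensation already removed).
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
    "X": 110.0,
}
_WATER_MASS = 18.0153

#: Triage thresholds.
R_FREE_GOOD = 0.35
R_FREE_MARGINAL = 0.5
LLG_STRONG = 60.0
TF_SIGMA_STRONG = 8.0
SHELXE_CC_MIN = 25.0
SHELXE_ACL_MIN = 10.0


@dataclass
class CellParameters:
    """Unit-cell edges (Å) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise GeometryError("cell edges must be positive")
        for angle in (self.alpha, self.beta, self.gamma):
            if not 0.0 < angle < 180.0:
                raise GeometryError(f"cell angle {angle} outside (0, 180)")
        if self._discriminant() <= 0:
            raise GeometryError("cell angles give a non-positive metric determinant")

    def _discriminant(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg


def cell_volume(cell: CellParameters) -> float:
    """Unit-cell volume (Å³): abc sqrt(1 - cos²α - cos²β - cos²γ + 2cosαcosβcosγ)."""
    disc = cell._discriminant()
    if disc <= 0:
        raise GeometryError("non-positive volume discriminant")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


class MatthewsResult(NamedTuple):
    vm: float           # Matthews coefficient, Å³/Da
    solvent: float      # solvent fraction (can be <= 0 with the warning set)
    low_solvent_warning: bool


def matthews(cell: CellParameters, z_asu_per_cell: int, asu_mass: float) -> MatthewsResult:
    """Matthews coefficient and solvent fraction for a given ASU mass.

    ``z_asu_per_cell`` is the number of asymmetric units in the cell (the
    space-group multiplicity, e.g. 2 for P2₁).  A Vm at or below 1.23 Å³/Da
    leaves no room for solvent; the result is flagged rather than raised.
    """
    if asu_mass <= 0:
        raise ValueError("asymmetric-unit mass must be positive")
    if z_asu_per_cell < 1:
        raise ValueError("z_asu_per_cell must be >= 1")
    vm = cell_volume(cell) / (z_asu_per_cell * asu_mass)
    solvent = 1.0 - MATTHEWS_PROTEIN_DENSITY / vm
    return MatthewsResult(vm, solvent, solvent <= 0.0)


class CopyEstimate(NamedTuple):
    n: int
    vm: float
    solvent: float
    warning: bool


def sequence_mass(sequence: str) -> float:
    """Average protein mass (Da) of a one-letter sequence, plus one water."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(RESIDUE_MASS[c] for c in sequence.upper()) + _WATER_MASS


def estimate_copies(cell: CellParameters, z_asu_per_cell: int,
                    residue_count: int,
                    mean_residue_mass: float = DEFAULT_RESIDUE_MASS,
                    sequence: str | None = None) -> CopyEstimate:
    """Number of molecules expected in the asymmetric unit.

    Candidate counts n = 1, 2, ... are evaluated while the solvent fraction
    stays at or above 0.25; among those the n with solvent closest to 0.50
    wins (ties to the larger n).  If even one copy leaves under 25% solvent
    the estimate falls back to n = 1 with a warning.  An exact sequence, when
    supplied, replaces the residue-count x mean-mass approximation.
    """
    if residue_count < 1:
        raise ValueError("residue_count must be >= 1")
    mol_mass = sequence_mass(sequence) if sequence else residue_count * mean_residue_mass
    candidates: list[tuple[int, MatthewsResult]] = []
    n = 1
    while True:
        result = matthews(cell, z_asu_per_cell, n * mol_mass)
        if result.solvent < 0.25:
            break
        candidates.append((n, result))
        n += 1
    if not candidates:
        result = matthews(cell, z_asu_per_cell, mol_mass)
        return CopyEstimate(1, result.vm, result.solvent, True)
    best_n, best = min(candidates, key=lambda item: (abs(item[1].solvent - 0.5), -item[0]))
    return CopyEstimate(best_n, best.vm, best.solvent, False)


class Category(str, Enum):
    GOOD = "GOOD"
    MARGINAL = "MARGINAL"
    POOR = "POOR"
    UNKNOWN = "UNKNOWN"


@dataclass
class SolutionScores:
    """Per-search-model MR / refinement / tracing scores (absent = None)."""

    model_id: str
    phaser_llg: float | None = None
    phaser_tfz: float | None = None
    molrep_rf_sigma: float | None = None
    molrep_tf_sigma: float | None = None
    r_work: float | None = None
    r_free: float | None = None
    shelxe_cc: float | None = None
    shelxe_acl: float | None = None

    def __post_init__(self) -> None:
        for attr in ("r_work", "r_free"):
            value = getattr(self, attr)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{attr} {value} outside [0, 1]")
        if self.shelxe_cc is not None and not -100.0 <= self.shelxe_cc <= 100.0:
            raise ValueError(f"shelxe_cc {self.shelxe_cc} outside [-100, 100]")
        if self.shelxe_acl is not None and self.shelxe_acl < 0:
            raise ValueError(f"shelxe_acl {self.shelxe_acl} negative")


@dataclass
class SolutionAssessment:
    category: Category
    flags: dict[str, bool] = field(default_factory=dict)


def categorize(scores: SolutionScores) -> SolutionAssessment:
    """Band a refined solution by R_free and set the success flags.

    R_free < 0.35 is GOOD, up to and including 0.5 MARGINAL, above POOR; a
    missing R_free gives UNKNOWN.  Flags: LLG >= 60 (strong Phaser success),
    TF/sigma > 8 (MOLREP placement), CC > 25 with mean chain length >= 10
    (successful trace).
    """
    if scores.r_free is None:
        category = Category.UNKNOWN
    elif scores.r_free < R_FREE_GOOD:
        category = Category.GOOD
    elif scores.r_free <= R_FREE_MARGINAL:
        category = Category.MARGINAL
    else:
        category = Category.POOR
    flags = {
        "phaser_llg_strong": scores.phaser_llg is not None
                             and scores.phaser_llg >= LLG_STRONG,
        "molrep_tf_strong": scores.molrep_tf_sigma is not None
                            and scores.molrep_tf_sigma > TF_SIGMA_STRONG,
        "shelxe_success": scores.shelxe_cc is not None and scores.shelxe_acl is not None
                          and scores.shelxe_cc > SHELXE_CC_MIN
                          and scores.shelxe_acl >= SHELXE_ACL_MIN,
    }
    return SolutionAssessment(category, flags)


_SCORE_COLUMNS = ("model_id", "phaser_llg", "phaser_tfz", "molrep_rf_sigma",
                  "molrep_tf_sigma", "r_work", "r_free", "shelxe_cc", "shelxe_acl")


def rank_solutions(scores: Sequence[SolutionScores]) -> pd.DataFrame:
    """Ranked summary table: ascending R_free, absent values last.

    Ties in R_free break by model id; rows without an R_free keep their input
    order at the bottom.  Each row carries all scores, the category and the
    success flags.
    """
    def sort_key(item: tuple[int, SolutionScores]):
        idx, s = item
        if s.r_free is None:
            return (1, 0.0, "", idx)
        return (0, s.r_free, s.model_id, idx)

    rows = []
    for _, s in sorted(enumerate(scores), key=sort_key):
        assessment = categorize(s)
        row = {col: getattr(s, col) for col in _SCORE_COLUMNS}
        row["category"] = assessment.category.value
        row.update(assessment.flags)
        rows.append(row)
    columns = list(_SCORE_COLUMNS) + ["category", "phaser_llg_strong",
                                      "molrep_tf_strong", "shelxe_success"]
    return pd.DataFrame(rows, columns=columns)
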