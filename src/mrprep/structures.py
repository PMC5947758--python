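"""Coordinate containers for molecular-replacement search models.

The hierarchy is deliberately small: a :class:`StructureModel` holds ordered
chains of ordered residues of atoms, plus the entry-level metadata (resolution,
R value) that redundancy reduction uses to pick cluster representatives.
Residue numbers carry target numbering after renumbering; the original
homologue numbering is preserved in ``source_number``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import StructureError

#: Standard one-letter codes accepted in sequences ('X' = unknown).
AA1 = "ACDEFGHIKLMNPQRSTVWYX"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"


def three_to_one(name: str) -> str:
    """One-letter code for a three-letter residue name ('X' if unknown)."""
    return THREE_TO_ONE.get(name.upper(), "X")


@dataclass
class AtomRecord:
    """One atom: name, element, Cartesian position (Å), occupancy, B (Å²)."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0.0:
            raise StructureError(f"atom {self.name!r}: negative B factor {self.b_factor}")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.position.copy(),
                          self.occupancy, self.b_factor, self.alt_loc)


@dataclass
class Residue:
    """A residue: number (target numbering once renumbered), name, atoms.

    ``source_number`` keeps the original homologue numbering after
    renumbering; ``target_aa`` records the aligned target residue type when a
    non-identical side chain has been pruned.
    """

    number: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""
    source_number: int | None = None
    target_aa: str = ""

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_ca(self) -> bool:
        return self.atom("CA") is not None

    def copy(self) -> "Residue":
        return Residue(self.number, self.name, [a.copy() for a in self.atoms],
                       self.insertion_code, self.source_number, self.target_aa)


@dataclass
class Chain:
    """An ordered run of residues under one chain identifier."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class StructureModel:
    """A (possibly multi-chain) coordinate model with entry metadata.

    After search-model preparation a model has at most one chain; helpers
    below assume the single-chain case and raise otherwise.
    """

    id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: float | None = None
    r_value: float | None = None
    rmsd: float | None = None  # r.m.s.d.-from-centroid annotation, Å

    def copy(self) -> "StructureModel":
        m = StructureModel(self.id, [c.copy() for c in self.chains],
                           self.resolution, self.r_value, self.rmsd)
        return m

    @property
    def single_chain(self) -> Chain:
        if len(self.chains) != 1:
            raise StructureError(
                f"model {self.id!r}: expected exactly one chain, found {len(self.chains)}")
        return self.chains[0]

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def ca_positions(self) -> dict[int, np.ndarray]:
        """Residue number -> CA coordinate for the single chain."""
        out: dict[int, np.ndarray] = {}
        for res in self.single_chain.residues:
            ca = res.atom("CA")
            if ca is not None:
                out[res.number] = ca.position
        return out

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply x -> R x + t to every atom in place."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        for res in self.residues():
            for atom in res.atoms:
                atom.position = rotation @ atom.position + translation

    def sequence(self) -> str:
        """One-letter sequence of the single chain, in residue order."""
        return "".join(three_to_one(r.name) for r in self.single_chain.residues)
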