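import numpy as np
import pytest

from mrprep import (AtomRecord, Chain, FamilySpec, PairwiseAlignment, Residue,
                    StructureModel, make_family, make_target,
                    superpose_to_centroid)

# Hand-built 3-residue toy PDB (fixed columns), independent of write_pdb.
TOY_PDB = """\
HEADER    TOY PROTEIN
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 20.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 20.00           C
ATOM      3  C   ALA A   1      12.759   7.095  -4.968  1.00 20.00           C
ATOM      4  O   ALA A   1      13.560   7.322  -5.878  1.00 20.00           O
ATOM      5  CB  ALA A   1      12.173   4.661  -4.874  1.00 20.00           C
ATOM      6  N   GLY A   2      12.817   7.725  -3.797  1.00 21.00           N
ATOM      7  CA  GLY A   2      13.861   8.719  -3.528  1.00 21.00           C
ATOM      8  C   GLY A   2      13.293  10.122  -3.709  1.00 21.00           C
ATOM      9  O   GLY A   2      12.089  10.313  -3.866  1.00 21.00           O
ATOM     10  N   SER A   3      14.167  11.123  -3.678  1.00 22.00           N
ATOM     11  CA  SER A   3      13.769  12.515  -3.838  1.00 22.00           C
ATOM     12  C   SER A   3      14.902  13.451  -3.433  1.00 22.00           C
ATOM     13  O   SER A   3      16.069  13.071  -3.497  1.00 22.00           O
ATOM     14  CB  SER A   3      13.376  12.785  -5.292  1.00 22.00           C
ATOM     15  OG  SER A   3      12.286  11.968  -5.692  1.00 22.00           O
END
"""


def build_residue(number: int, name: str, atom_names: list[str],
                  offset: float = 0.0) -> Residue:
    """Residue with the given atoms on a simple non-degenerate layout."""
    atoms = []
    for i, atom_name in enumerate(atom_names):
        element = atom_name[0] if atom_name[0] in "NCOS" else "C"
        pos = np.array([offset + 0.9 * i, 1.3 * ((i * 7) % 3), 0.7 * ((i * 5) % 4)])
        atoms.append(AtomRecord(atom_name, element, pos, 1.0, 15.0 + i))
    return Residue(number, name, atoms, source_number=number)


FULL_SIDECHAINS = {
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "GLY": ["N", "CA", "C", "O"],
    "ALA": ["N", "CA", "C", "O", "CB"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
}


def build_model(res_specs: list[tuple[int, str]], model_id: str = "toy") -> StructureModel:
    """Single-chain model with full side chains for the listed residues."""
    residues = [build_residue(num, name, FULL_SIDECHAINS[name], offset=4.0 * k)
                for k, (num, name) in enumerate(res_specs)]
    return StructureModel(model_id, [Chain("A", residues)])


def identity_alignment(sequence: str) -> PairwiseAlignment:
    n = len(sequence)
    return PairwiseAlignment(sequence, sequence, 1.0,
                             tuple((i, i) for i in range(1, n + 1)))


@pytest.fixture(scope="session")
def tiered_family():
    """Seeded two-tier noise family: (target, members, seqs, injected sd map)."""
    spec = FamilySpec(n_residues=200, n_members=10, identity=0.3,
                      core_sd=0.2, loop_sd=2.0, loop_fraction=0.5,
                      rigid_motion=True, seed=11)
    target, _seq = make_target(spec.n_residues, spec.seed)
    models, seqs, sd_map = make_family(target, spec)
    return target, models, seqs, sd_map


@pytest.fixture(scope="session")
def tiered_superposed(tiered_family):
    _target, models, _seqs, _sd = tiered_family
    return superpose_to_centroid(models)
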