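"""Alignment-guided homologue editing into MR-ready search models.

Three protocols are offered, mirroring the standard preparation options:

* ``cgamma_mixed`` — the Schwarzenbacher-style mixed model: residues aligned
  to an identical target residue keep all atoms; non-identical residues are
  pruned to the Cγ atom (backbone + CB + the single γ-position atom of the
  homologue residue type); unaligned residues are deleted.
* ``polyalanine`` — backbone plus Cβ only, every residue renamed ALA.
* ``unmodified`` — renumbering/deletion only.

Editing never fabricates atoms, never moves coordinates and carries the
original B factors through unchanged.  Models are renumbered into target
numbering first, which is what later makes position-based superposition of
the edited homologues meaningful.
"""

from __future__ import annotations

from enum import Enum

from .errors import AlignmentError, StructureError
from .seqdata import PairwiseAlignment
from .structures import Chain, Residue, StructureModel, three_to_one


class EditProtocol(Enum):
    """Homologue-modification protocol."""

    CGAMMA_MIXED = "cgamma_mixed"
    POLYALANINE = "polyalanine"
    UNMODIFIED = "unmodified"


#: Backbone + Cβ atoms retained for pruned and polyalanine residues.
BACKBONE_CB = ("N", "CA", "C", "O", "CB")

#: The single γ-position atom per residue type; residues without an entry
#: either have CG (most types) or no γ atom at all (GLY, ALA).
GAMMA_ATOM = {
    "SER": "OG",
    "THR": "OG1",
    "CYS": "SG",
    "ILE": "CG1",
    "VAL": "CG1",
}


def _gamma_atom_name(res_name: str) -> str:
    return GAMMA_ATOM.get(res_name.upper(), "CG")


def _is_renumbered(model: StructureModel, aln: PairwiseAlignment) -> bool:
    """True when the model already carries target numbering under ``aln``."""
    targets = set(aln.target_positions)
    residues = model.single_chain.residues
    if not residues:
        return False
    return all(r.source_number is not None and r.number in targets for r in residues)


def renumber_to_target(model: StructureModel, aln: PairwiseAlignment) -> StructureModel:
    """Renumber model residues into target numbering via the alignment.

    The i-th residue of the (single) chain corresponds to the i-th ungapped
    position of the hit row.  Residues at unaligned hit positions (insertions
    relative to the target) are deleted; original numbering is preserved in
    ``source_number``.  Already-renumbered models pass through unchanged.
    """
    chain = model.single_chain
    if _is_renumbered(model, aln):
        return model.copy()
    hit_len = len(aln.hit_row.replace("-", ""))
    if len(chain.residues) != hit_len:
        raise AlignmentError(
            f"model {model.id!r} has {len(chain.residues)} residues but the "
            f"alignment hit row has {hit_len} positions")
    h2t = aln.hit_to_target()
    chars = aln.target_chars()
    seen: set[int] = set()
    new_residues: list[Residue] = []
    for i, res in enumerate(chain.residues, start=1):
        t = h2t.get(i)
        if t is None:
            continue  # insertion relative to the target: main-chain deletion
        if t in seen:
            raise AlignmentError(f"alignment maps two residues to target position {t}")
        seen.add(t)
        new = res.copy()
        new.source_number = res.number
        new.number = t
        new.insertion_code = ""
        new.target_aa = chars[t][0]
        new_residues.append(new)
    out = model.copy()
    out.chains = [Chain(chain.id, new_residues)]
    return out


def sculpt_cgamma(model: StructureModel, aln: PairwiseAlignment) -> StructureModel:
    """Mixed model: prune non-identical side chains to the Cγ atom.

    Applies renumbering first when needed.  Identical aligned residues keep
    every atom; non-identical ones keep backbone + CB + the γ atom of the
    homologue residue type, with the homologue residue name kept and the
    target residue type recorded in ``target_aa``.  B factors are untouched.
    """
    out = renumber_to_target(model, aln)
    chars = aln.target_chars()
    for res in out.single_chain.residues:
        if not res.has_ca:
            raise StructureError(f"residue {res.number} ({res.name}) lacks a CA atom")
        target_aa, _hit_aa = chars[res.number]
        res.target_aa = target_aa
        if three_to_one(res.name) == target_aa:
            continue
        keep = set(BACKBONE_CB) | {_gamma_atom_name(res.name)}
        res.atoms = [a for a in res.atoms if a.name in keep]
    return out


def make_polyalanine(model: StructureModel) -> StructureModel:
    """Reduce every residue to backbone + Cβ and rename it ALA.

    No Cβ is fabricated for glycine; coordinates and B factors pass through.
    """
    out = model.copy()
    for res in out.residues():
        res.atoms = [a for a in res.atoms if a.name in BACKBONE_CB]
        res.name = "ALA"
    return out


def apply_protocol(model: StructureModel, aln: PairwiseAlignment,
                   protocol: EditProtocol | str) -> StructureModel:
    """Dispatch to one of the three editing protocols (renumbering included)."""
    protocol = EditProtocol(protocol) if not isinstance(protocol, EditProtocol) else protocol
    if protocol is EditProtocol.CGAMMA_MIXED:
        return sculpt_cgamma(model, aln)
    if protocol is EditProtocol.POLYALANINE:
        return make_polyalanine(renumber_to_target(model, aln))
    return renumber_to_target(model, aln)
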