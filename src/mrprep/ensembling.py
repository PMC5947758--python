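"""Variance-ranked ensemble truncation and r.m.s.d. annotation.

From a superposed family the base ensemble keeps every residue of every
member (including residues outside the common core — the "110%" level in
interactive use).  Derived ensembles retain, at each percentage level, the
ceil(p% x |core|) core positions of lowest Cα variance, so the least
variable 5% survives at the bottom of the ladder and levels are nested.
Member r.m.s.d. annotations are recomputed per level after re-superposing
each member onto the centroid restricted to the retained positions, so the
annotation describes the model actually written out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structures import Chain, StructureModel
from .superposition import SuperposedEnsemble, kabsch

#: Default truncation step (percent) giving 20 derived ensembles.
DEFAULT_STEP = 5

#: Constants of the exponential identity -> r.m.s.d. estimate (Å).
RMSD_IDENTITY_SCALE = 0.4
RMSD_IDENTITY_RATE = 1.87


@dataclass
class TruncationLevel:
    """A truncation level: percent retained (None marks the base ensemble)."""

    percent: int | None
    retained_positions: tuple[int, ...]

    @property
    def is_base(self) -> bool:
        return self.percent is None

    @property
    def label(self) -> str:
        # the untruncated base is conventionally displayed as "110%"
        return "base" if self.percent is None else str(self.percent)


@dataclass
class EnsembleSearchModel:
    """A truncated (or base) ensemble with per-member r.m.s.d. annotations."""

    level: TruncationLevel
    members: list[StructureModel]
    member_rmsd: list[float]
    domain: int | None = None

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


def truncation_levels(step: int = DEFAULT_STEP) -> list[int]:
    """Descending percentage levels 100, 100-step, ..., step.

    ``step`` must divide 100, so the default of 5 yields 20 levels and a
    step of 10 yields 10.
    """
    if not isinstance(step, int) or not 1 <= step <= 100 or 100 % step != 0:
        raise ValueError(f"step must be an integer divisor of 100 in [1, 100], got {step}")
    return list(range(100, 0, -step))


def retained_at(ensemble: SuperposedEnsemble, percent: int) -> tuple[int, ...]:
    """The ceil(percent% x |core|) lowest-variance core positions, in residue order.

    Ties in variance break by ascending residue number, which makes the
    levels nested and the selection deterministic.
    """
    if not 1 <= percent <= 100:
        raise ValueError(f"percent must be in [1, 100], got {percent}")
    core = ensemble.core_positions
    k = math.ceil(percent / 100.0 * len(core))
    order = sorted(range(len(core)), key=lambda i: (ensemble.variance[i], core[i]))
    chosen = sorted(core[i] for i in order[:k])
    return tuple(chosen)


def _truncate_member(member: StructureModel, retained: set[int]) -> StructureModel:
    out = member.copy()
    chain = out.single_chain
    out.chains = [Chain(chain.id, [r for r in chain.residues if r.number in retained])]
    return out


def build_ensembles(superposed: SuperposedEnsemble,
                    step: int = DEFAULT_STEP,
                    domain: int | None = None) -> list[EnsembleSearchModel]:
    """Base ensemble plus one truncated ensemble per level.

    The base keeps all residues of all members and carries the core
    r.m.s.d. annotations from the superposition.  Numeric levels truncate
    members to the retained positions and re-fit each member onto the
    centroid restricted to those positions before measuring its r.m.s.d.
    Levels with fewer than three retained positions are aligned by centroid
    translation only (a rotation is no longer determined).
    """
    out: list[EnsembleSearchModel] = []
    base_level = TruncationLevel(None, superposed.core_positions)
    out.append(EnsembleSearchModel(base_level,
                                   [m.copy() for m in superposed.members],
                                   list(superposed.member_rmsd),
                                   domain))
    core = superposed.core_positions
    index_of = {p: i for i, p in enumerate(core)}
    for percent in truncation_levels(step):
        retained = retained_at(superposed, percent)
        idx = [index_of[p] for p in retained]
        centroid_sub = superposed.centroid[idx]
        members: list[StructureModel] = []
        rmsds: list[float] = []
        for member in superposed.members:
            truncated = _truncate_member(member, set(retained))
            cas = member.ca_positions()
            coords = np.array([cas[p] for p in retained])
            if len(retained) >= 3:
                try:
                    tr, rmsd = kabsch(centroid_sub, coords)
                    truncated.transform(tr.rotation, tr.translation)
                except Exception:
                    rmsd = _translate_only(truncated, coords, centroid_sub)
            else:
                rmsd = _translate_only(truncated, coords, centroid_sub)
            truncated.rmsd = rmsd
            members.append(truncated)
            rmsds.append(rmsd)
        out.append(EnsembleSearchModel(TruncationLevel(percent, retained),
                                       members, rmsds, domain))
    return out


def _translate_only(truncated: StructureModel, coords: np.ndarray,
                    centroid_sub: np.ndarray) -> float:
    shift = centroid_sub.mean(axis=0) - coords.mean(axis=0)
    truncated.transform(np.eye(3), shift)
    moved = coords + shift
    return float(np.sqrt(np.mean(np.sum((moved - centroid_sub) ** 2, axis=1))))


def extract_single(ensemble_model: EnsembleSearchModel, member_id: str) -> StructureModel:
    """One member of an ensemble as a standalone annotated search model."""
    for member, rmsd in zip(ensemble_model.members, ensemble_model.member_rmsd):
        if member.id == member_id:
            out = member.copy()
            out.rmsd = rmsd
            return out
    raise LookupError(f"member {member_id!r} not in ensemble "
                      f"(have {ensemble_model.member_ids})")


def rmsd_from_identity(identity: float,
                       scale: float = RMSD_IDENTITY_SCALE,
                       rate: float = RMSD_IDENTITY_RATE) -> float:
    """Initial r.m.s.d. estimate (Å) from sequence identity.

    Uses the exponential divergence relationship common in MR likelihood
    calibration: rmsd = scale * exp(rate * (1 - identity)).  At full identity
    this is ``scale`` (0.40 Å by default) and it grows smoothly as identity
    falls, reaching ~1.6 Å at 25% identity.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity must be in (0, 1], got {identity}")
    return scale * math.exp(rate * (1.0 - identity))
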