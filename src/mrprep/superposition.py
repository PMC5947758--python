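"""Rigid-body superposition and per-position Cα variance across homologues.

The workhorse is the Kabsch least-squares fit (SVD form, reflections
corrected).  A set of edited, target-renumbered homologues is brought into a
common frame by iterating member-onto-centroid fits until the centroid stops
moving; structural correspondence comes from the shared target numbering.
The per-position mean squared deviation of member CA atoms about the centroid
is the variance signal that ensemble truncation consumes, and each member is
annotated with its r.m.s.d. from the centroid over the common core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CoreError, GeometryError
from .structures import StructureModel

_ORTHO_TOL = 1e-9
_DEGENERACY_TOL = 1e-8


@dataclass
class RigidTransform:
    """A proper rotation plus translation: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("rigid transform needs a 3x3 rotation and a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise GeometryError("rotation columns are not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise GeometryError("rotation is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SuperposedEnsemble:
    """Members in a common frame with core statistics.

    ``core_positions`` are the target-residue numbers holding a CA in every
    member; ``centroid`` and ``variance`` are per-core-position mean CA
    coordinates (Å) and mean squared deviations (Å²); ``member_rmsd`` is each
    member's r.m.s.d. from the centroid over the core (Å).
    """

    members: list[StructureModel]
    core_positions: tuple[int, ...]
    centroid: np.ndarray
    variance: np.ndarray
    member_rmsd: list[float]
    transforms: list[RigidTransform]


def _check_nondegenerate(centered: np.ndarray, label: str) -> None:
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < _DEGENERACY_TOL * max(1.0, s[0]):
        raise GeometryError(f"{label} coordinates are (near-)collinear")


def kabsch(fixed: np.ndarray, moving: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``moving`` onto ``fixed``.

    Returns the proper rigid transform minimizing the summed squared CA
    distances, and the minimized r.m.s.d. (Å).  Requires at least three
    non-collinear point pairs.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise GeometryError(f"coordinate sets differ in shape: {fixed.shape} vs {moving.shape}")
    if fixed.ndim != 2 or fixed.shape[1] != 3 or fixed.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 points of shape (n, 3)")
    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    f0 = fixed - cf
    m0 = moving - cm
    _check_nondegenerate(f0, "fixed")
    _check_nondegenerate(m0, "moving")
    h = m0.T @ f0
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cf - rotation @ cm
    transform = RigidTransform(rotation, translation)
    moved = transform.apply(moving)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return transform, rmsd


def core_positions(members: list[StructureModel]) -> tuple[int, ...]:
    """Target positions holding a CA atom in every member, ascending."""
    if not members:
        raise CoreError("no members supplied")
    sets = [set(m.ca_positions()) for m in members]
    core = set.intersection(*sets)
    if not core:
        raise CoreError("no position is present (with a CA) in every member")
    return tuple(sorted(core))


def _core_coords(member: StructureModel, positions: tuple[int, ...]) -> np.ndarray:
    cas = member.ca_positions()
    return np.array([cas[p] for p in positions])


def superpose_to_centroid(members: list[StructureModel],
                          tol: float = 1e-6,
                          max_iter: int = 100) -> SuperposedEnsemble:
    """Iteratively superpose members onto their evolving centroid.

    The frame is anchored on the first member; each pass fits every member's
    original coordinates onto the current centroid over the core positions
    and recomputes the centroid as the per-position mean, until the maximum
    centroid shift drops below ``tol`` Å (or ``max_iter`` passes).
    """
    if len(members) < 2:
        raise ValueError("superposition needs at least two members")
    core = core_positions(members)
    if len(core) < 3:
        raise CoreError(f"core of {len(core)} positions is too small to superpose")
    originals = [_core_coords(m, core) for m in members]
    centroid = originals[0].copy()
    transforms = [RigidTransform.identity() for _ in members]
    for _ in range(max_iter):
        current = []
        for i, orig in enumerate(originals):
            transforms[i], _ = kabsch(centroid, orig)
            current.append(transforms[i].apply(orig))
        new_centroid = np.mean(current, axis=0)
        shift = float(np.max(np.abs(new_centroid - centroid)))
        centroid = new_centroid
        if shift < tol:
            break
    fitted = [tr.apply(orig) for tr, orig in zip(transforms, originals)]
    sq_dev = np.array([np.sum((f - centroid) ** 2, axis=1) for f in fitted])  # (n, k)
    variance = sq_dev.mean(axis=0)
    member_rmsd = [float(np.sqrt(np.mean(row))) for row in sq_dev]
    placed = []
    for member, tr in zip(members, transforms):
        moved = member.copy()
        moved.transform(tr.rotation, tr.translation)
        placed.append(moved)
    return SuperposedEnsemble(placed, core, centroid, variance, member_rmsd, transforms)


def pairwise_rmsd(a: StructureModel, b: StructureModel) -> float:
    """Kabsch r.m.s.d. over the target-numbered CA positions shared by a and b."""
    shared = core_positions([a, b])
    if len(shared) < 3:
        raise CoreError(f"only {len(shared)} shared CA positions; need at least 3")
    _, rmsd = kabsch(_core_coords(a, shared), _core_coords(b, shared))
    return rmsd
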