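"""Deterministic synthetic fixtures: target folds, homologue families, hits.

Everything the pipeline consumes can be generated here with a seed, so the
full preparation workflow is exercisable without any database download.

The synthetic target is a meander of idealized α-helical segments joined by
planar arc turns: consecutive Cα atoms sit ~3.8 Å apart, the chain is
self-avoiding, and backbone atoms (N, C, O, Cβ) are placed by idealized
local geometry around the Cα trace.  Homologue families add per-residue
isotropic Gaussian displacements with two noise tiers — a conserved core and
a contiguous mobile ("loop") region — which is the statistical structure the
variance-based truncation is designed to exploit.  The generators return the
injected per-position noise map so recovery can be tested.  What these
fixtures do NOT emulate: real side-chain packing, crystallographic data, or
insertion/deletion structure variation between homologues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import write_fasta, write_hit_table, write_pdb
from .search_clustering import SearchHit
from .seqdata import SequenceRecord
from .structures import AtomRecord, Chain, ONE_TO_THREE, Residue, StructureModel

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# mutation alphabet excludes glycine so mutated residues keep a valid CB
_AA_MUT = _AA20.replace("G", "")

_HELIX_RISE = 1.5       # Å per residue along the helix axis
_HELIX_RADIUS = 2.3     # Å
_HELIX_TWIST = 100.0    # degrees per residue
_CA_STEP = 3.8          # Å, turn-step length
_TURN_ANGLE = 36.0      # degrees per turn step (5 steps = 180 degrees)
_HELIX_LEN = 15
_TURN_LEN = 4


@dataclass
class FamilySpec:
    """Conditions for a synthetic homologue family."""

    n_residues: int = 200
    n_members: int = 10
    identity: float = 0.3
    core_sd: float = 0.2      # Å, conserved-core per-axis noise
    loop_sd: float = 2.0      # Å, mobile-region per-axis noise
    loop_fraction: float = 0.5
    rigid_motion: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("identity must be in (0, 1]")
        if self.core_sd < 0 or self.loop_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.loop_fraction < 1.0:
            raise ValueError("loop_fraction must be in [0, 1)")


def _rot_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t), 0.0],
                     [math.sin(t), math.cos(t), 0.0],
                     [0.0, 0.0, 1.0]])


def _meander_ca_trace(n: int) -> np.ndarray:
    """Self-avoiding Cα trace: alternating helices and 180-degree arc turns."""
    pts: list[np.ndarray] = []
    axis = np.array([1.0, 0.0, 0.0])
    p_ref = np.array([0.0, 0.0, 1.0])  # helix circle reference vector
    origin = np.zeros(3)
    first_segment = True
    while len(pts) < n:
        # helix segment (parametric, so consecutive spacing is the ideal chord)
        q_ref = np.cross(axis, p_ref)
        start_j = 0 if first_segment else 1
        if not first_segment:
            origin = pts[-1] - _HELIX_RADIUS * p_ref
        for j in range(start_j, _HELIX_LEN + start_j):
            if len(pts) >= n:
                return np.array(pts[:n])
            theta = math.radians(_HELIX_TWIST * j)
            pts.append(origin + _HELIX_RISE * j * axis
                       + _HELIX_RADIUS * (math.cos(theta) * p_ref + math.sin(theta) * q_ref))
        first_segment = False
        # arc turn in the x-y plane, bending toward +y and reversing the axis
        sign = 1.0 if axis[0] > 0 else -1.0
        direction = axis.copy()
        for _ in range(_TURN_LEN):
            if len(pts) >= n:
                return np.array(pts[:n])
            direction = _rot_z(sign * _TURN_ANGLE) @ direction
            pts.append(pts[-1] + _CA_STEP * direction)
        axis = _rot_z(sign * _TURN_ANGLE * (_TURN_LEN + 1)) @ axis
        axis = axis / np.linalg.norm(axis)
    return np.array(pts[:n])


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        return np.array([0.0, 0.0, 1.0])
    return v / norm


def _backbone_from_ca(ca: np.ndarray, sequence: str, model_id: str) -> StructureModel:
    """Idealized N/CA/C/O(/CB) placement around a Cα trace."""
    n = len(ca)
    residues: list[Residue] = []
    for i in range(n):
        d_prev = _unit(ca[i] - ca[i - 1]) if i > 0 else _unit(ca[i + 1] - ca[i])
        d_next = _unit(ca[i + 1] - ca[i]) if i < n - 1 else _unit(ca[i] - ca[i - 1])
        normal = np.cross(d_prev, d_next)
        if np.linalg.norm(normal) < 1e-6:
            helper = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(helper, d_next)) > 0.9:
                helper = np.array([1.0, 0.0, 0.0])
            normal = np.cross(d_next, helper)
        normal = _unit(normal)
        pos_n = ca[i] - 1.46 * _unit(d_prev + 0.4 * normal)
        pos_c = ca[i] + 1.52 * _unit(d_next - 0.4 * normal)
        pos_o = pos_c + 1.23 * _unit(normal - 0.5 * d_next)
        aa = sequence[i]
        atoms = [AtomRecord("N", "N", pos_n, 1.0, 20.0),
                 AtomRecord("CA", "C", ca[i], 1.0, 20.0),
                 AtomRecord("C", "C", pos_c, 1.0, 20.0),
                 AtomRecord("O", "O", pos_o, 1.0, 20.0)]
        if aa != "G":
            pos_cb = ca[i] + 1.53 * _unit(normal - 0.35 * (d_prev + d_next))
            atoms.append(AtomRecord("CB", "C", pos_cb, 1.0, 20.0))
        residues.append(Residue(i + 1, ONE_TO_THREE[aa], atoms, source_number=i + 1))
    return StructureModel(model_id, [Chain("A", residues)])


def make_target(n_residues: int, seed: int) -> tuple[StructureModel, SequenceRecord]:
    """A synthetic target fold plus its (seeded, random) sequence."""
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list(_AA20), size=n_residues))
    ca = _meander_ca_trace(n_residues)
    model = _backbone_from_ca(ca, sequence, "target")
    return model, SequenceRecord("target", sequence)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_family(target: StructureModel, spec: FamilySpec
                ) -> tuple[list[StructureModel], list[SequenceRecord], np.ndarray]:
    """Homologue family: target + two-tier coordinate noise + sequence drift.

    Every member gets the same contiguous mobile region (so its variance is
    recoverable across the family), per-residue isotropic Gaussian
    displacements applied rigidly to all atoms of the residue, an optional
    random rigid-body motion, and a mutated sequence hitting the requested
    identity.  Returns (models, sequence records, injected per-position sd).
    """
    rng = np.random.default_rng(spec.seed)
    residues = target.single_chain.residues
    n = len(residues)
    target_seq = target.sequence()
    loop_len = int(round(spec.loop_fraction * n))
    loop_start = int(rng.integers(0, n - loop_len + 1)) if loop_len > 0 else 0
    sd_map = np.full(n, spec.core_sd, dtype=float)
    sd_map[loop_start:loop_start + loop_len] = spec.loop_sd

    n_mut = int(round((1.0 - spec.identity) * n))
    models: list[StructureModel] = []
    seqs: list[SequenceRecord] = []
    for m in range(spec.n_members):
        member = target.copy()
        member.id = f"hom{m + 1:02d}"
        mut_positions = set(rng.choice(n, size=n_mut, replace=False).tolist())
        chars = list(target_seq)
        for i, res in enumerate(member.single_chain.residues):
            if i in mut_positions:
                options = [c for c in _AA_MUT if c != chars[i]]
                chars[i] = options[int(rng.integers(len(options)))]
                res.name = ONE_TO_THREE[chars[i]]
            disp = rng.normal(0.0, sd_map[i] if sd_map[i] > 0 else 0.0, size=3) \
                if sd_map[i] > 0 else np.zeros(3)
            for atom in res.atoms:
                atom.position = atom.position + disp
        if spec.rigid_motion:
            rotation = _random_rotation(rng)
            translation = rng.uniform(-20.0, 20.0, size=3)
            member.transform(rotation, translation)
        member.resolution = round(float(rng.uniform(1.2, 3.0)), 2)
        member.r_value = round(float(rng.uniform(0.15, 0.25)), 3)
        models.append(member)
        seqs.append(SequenceRecord(member.id, "".join(chars),
                                   member.resolution, member.r_value))
    return models, seqs, sd_map


def make_hits(target: SequenceRecord,
              clusters: list[tuple[int, int, int, tuple[float, float]]],
              seed: int) -> tuple[str, str]:
    """Hit-table + Stockholm text for engineered multi-domain hit layouts.

    Each cluster is (midpoint, extent, n_hits, (score_lo, score_hi)).  Hit
    rows cover the requested span of the target (with small within-tolerance
    jitter), so span derivation and domain clustering recover the layout.
    Returns (hit table text, Stockholm text), the table sorted by descending
    score.
    """
    rng = np.random.default_rng(seed)
    n = len(target.sequence)
    rows: list[tuple[str, str]] = [(target.id, target.sequence)]
    hits: list[SearchHit] = []
    for c_idx, (midpoint, extent, n_hits, (lo, hi)) in enumerate(clusters, start=1):
        first = midpoint - extent // 2
        last = first + extent - 1
        if extent < 1 or first < 1 or last > n:
            raise ValueError(
                f"cluster {c_idx}: span (midpoint={midpoint}, extent={extent}) "
                f"outside target of length {n}")
        scores = sorted(rng.uniform(lo, hi, size=n_hits), reverse=True)
        for h_idx in range(n_hits):
            jitter_m = int(rng.integers(-3, 4))
            jitter_e = int(rng.integers(-6, 7))
            f = max(1, first + jitter_m - jitter_e // 2)
            l = min(n, last + jitter_m + (jitter_e - jitter_e // 2))
            chars = []
            for pos in range(1, n + 1):
                if f <= pos <= l:
                    c = target.sequence[pos - 1]
                    if rng.random() < 0.3:
                        c = _AA_MUT[int(rng.integers(len(_AA_MUT)))]
                    chars.append(c)
                else:
                    chars.append("-")
            hit_id = f"hit_d{c_idx}_{h_idx + 1:02d}"
            rows.append((hit_id, "".join(chars)))
            hits.append(SearchHit(hit_id, round(float(scores[h_idx]), 1)))
    hits.sort(key=lambda h: -h.score)
    table_text = write_hit_table(hits)
    sto_lines = ["# STOCKHOLM 1.0", ""]
    width = max(len(r[0]) for r in rows) + 2
    for rid, row in rows:
        sto_lines.append(f"{rid:<{width}s}{row}")
    sto_lines.append("//")
    return table_text, "\n".join(sto_lines) + "\n"


def write_family_inputs(out_dir: str | Path,
                        spec: FamilySpec | None = None) -> dict[str, Path]:
    """Write a complete single-domain input set for the preparation pipeline.

    Produces target.fasta, db.fasta (homologue sequences with metadata),
    msa.sto, hits.tab and homologues/<id>.pdb under ``out_dir``; returns the
    paths.  Fully deterministic given the spec.
    """
    spec = spec or FamilySpec()
    out_dir = Path(out_dir)
    (out_dir / "homologues").mkdir(parents=True, exist_ok=True)
    target_model, target_seq = make_target(spec.n_residues, spec.seed)
    models, seqs, _sd = make_family(target_model, spec)

    rng = np.random.default_rng(spec.seed + 1)
    scores = sorted(rng.uniform(30.0, 60.0, size=spec.n_members), reverse=True)
    hits = [SearchHit(s.id, round(float(scores[i]), 1)) for i, s in enumerate(seqs)]

    rows = [(target_seq.id, target_seq.sequence)] + [(s.id, s.sequence) for s in seqs]
    width = max(len(r[0]) for r in rows) + 2
    sto = "\n".join(["# STOCKHOLM 1.0", ""]
                    + [f"{rid:<{width}s}{row}" for rid, row in rows]
                    + ["//"]) + "\n"

    paths = {
        "target": out_dir / "target.fasta",
        "db": out_dir / "db.fasta",
        "msa": out_dir / "msa.sto",
        "hits": out_dir / "hits.tab",
        "structures": out_dir / "homologues",
    }
    paths["target"].write_text(write_fasta([target_seq]))
    paths["db"].write_text(write_fasta(seqs))
    paths["msa"].write_text(sto)
    paths["hits"].write_text(write_hit_table(hits))
    for model in models:
        (out_dir / "homologues" / f"{model.id}.pdb").write_text(write_pdb(model))
    return paths
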