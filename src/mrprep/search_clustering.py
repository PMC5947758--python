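"""Hit filtering, sequence-redundancy reduction and domain clustering.

The sequence search (phmmer-style) returns scored matches plus a multiple
sequence alignment of target and homologues.  This module prepares the
sequence database (His-tag and short-fragment removal, redundancy levels),
applies the score cutoff, extracts per-hit pairwise alignments from the MSA,
derives each hit's midpoint/extent footprint on the target, and groups hits
into numbered "domains" by a seed-relative midpoint/extent tolerance rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio import Align

from .errors import SpanError
from .seqdata import MultipleAlignment, PairwiseAlignment, SequenceRecord

#: Redundancy levels offered for the sequence database (percent identity).
REDUNDANCY_LEVELS = (100, 95, 90, 70, 50)

#: Default phmmer-style score cutoff separating homologues from noise.
DEFAULT_SCORE_CUTOFF = 20.0

#: Default domain-clustering tolerances (residues, measured to the seed).
DEFAULT_MID_TOL = 10
DEFAULT_EXT_TOL = 25

_HIS_TAG = re.compile(r"^H{4,}|H{4,}$")
_MIN_DB_LENGTH = 10


@dataclass
class SearchHit:
    """One sequence-search match against the target."""

    id: str
    score: float
    alignment: PairwiseAlignment | None = None
    midpoint: int | None = None
    extent: int | None = None
    domain: int | None = None


@dataclass
class DomainCluster:
    """A numbered group of hits covering the same stretch of the target."""

    number: int
    seed_id: str
    members: list[SearchHit] = field(default_factory=list)
    seed_midpoint: int = 0
    seed_extent: int = 0


def preprocess_sequence_db(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Strip terminal His tags and drop fragments shorter than ten residues.

    A His tag is read conservatively as a run of four or more consecutive
    histidines at either terminus.
    """
    out: list[SequenceRecord] = []
    for rec in records:
        seq = _HIS_TAG.sub("", _HIS_TAG.sub("", rec.sequence))
        if len(seq) < _MIN_DB_LENGTH:
            continue
        out.append(replace(rec, sequence=seq))
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # terminal gaps are free so fragments align onto their parents
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity with the shorter sequence as denominator.

    Scoring: match +1, mismatch 0, gap open -10, gap extend -0.5, end gaps
    free.  Identity is the count of identical aligned pairs divided by the
    length of the shorter sequence, so a perfect fragment scores 1.0 against
    its parent.
    """
    if not a or not b:
        raise ValueError("sequence_identity requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    aln = _make_aligner().align(a, b)[0]
    matches = 0
    for (ta, te), (qa, qe) in zip(*aln.aligned):
        for i in range(te - ta):
            if a[ta + i] == b[qa + i]:
                matches += 1
    return matches / min(len(a), len(b))


def reduce_redundancy(records: list[SequenceRecord], level: int = 95) -> list[SequenceRecord]:
    """Collapse near-identical sequences at a redundancy level.

    Level 100 returns the input unchanged.  Otherwise single-linkage clusters
    are formed over pairs with identity strictly greater than ``level``%, and
    each cluster is represented by the entry with the best (numerically
    smallest) resolution, then the lowest R value, then the lexicographically
    first id.  Output preserves input order of the representatives.
    """
    if level not in REDUNDANCY_LEVELS:
        raise ValueError(f"redundancy level must be one of {REDUNDANCY_LEVELS}, got {level}")
    if level == 100 or len(records) <= 1:
        return list(records)

    threshold = level / 100.0
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if sequence_identity(records[i].sequence, records[j].sequence) > threshold:
                parent[find(i)] = find(j)

    clusters: dict[int, list[SequenceRecord]] = {}
    for i, rec in enumerate(records):
        clusters.setdefault(find(i), []).append(rec)

    def preference(rec: SequenceRecord) -> tuple[float, float, str]:
        res = rec.resolution if rec.resolution is not None else float("inf")
        rv = rec.r_value if rec.r_value is not None else float("inf")
        return (res, rv, rec.id)

    representatives = {min(members, key=preference).id for members in clusters.values()}
    return [rec for rec in records if rec.id in representatives]


def filter_hits(hits: list[SearchHit], cutoff: float = DEFAULT_SCORE_CUTOFF) -> list[SearchHit]:
    """Keep hits scoring at least ``cutoff``, in descending-score order."""
    kept = [h for h in hits if h.score >= cutoff]
    kept.sort(key=lambda h: -h.score)  # stable: equal scores keep input order
    return kept


def extract_pairwise(msa: MultipleAlignment, target_id: str, hit_id: str) -> PairwiseAlignment:
    """Pull a target/hit pairwise alignment out of the search MSA.

    Columns gapped in both rows are deleted; identity is computed over the
    match columns (both rows occupied); the mapping pairs 1-based ungapped
    positions of target and hit at every match column.
    """
    t_row_full = msa.row(target_id)
    h_row_full = msa.row(hit_id)
    t_chars: list[str] = []
    h_chars: list[str] = []
    mapping: list[tuple[int, int]] = []
    tpos = hpos = 0
    identical = 0
    for tc, hc in zip(t_row_full, h_row_full):
        if tc == "-" and hc == "-":
            continue
        if tc != "-":
            tpos += 1
        if hc != "-":
            hpos += 1
        if tc != "-" and hc != "-":
            mapping.append((tpos, hpos))
            if tc == hc:
                identical += 1
        t_chars.append(tc)
        h_chars.append(hc)
    identity = identical / len(mapping) if mapping else 0.0
    return PairwiseAlignment("".join(t_chars), "".join(h_chars), identity, tuple(mapping))


def hit_span(alignment: PairwiseAlignment) -> tuple[int, int]:
    """(midpoint, extent) of the hit footprint in target numbering.

    Extent spans first to last aligned target position inclusive; the
    midpoint is rounded half-up to an integer residue index.
    """
    if not alignment.mapping:
        raise SpanError("alignment has no match columns")
    positions = alignment.target_positions
    first, last = positions[0], positions[-1]
    extent = last - first + 1
    midpoint = (first + last + 1) // 2  # round half-up
    return midpoint, extent


def cluster_domains(hits: list[SearchHit],
                    mid_tol: int = DEFAULT_MID_TOL,
                    ext_tol: int = DEFAULT_EXT_TOL) -> list[DomainCluster]:
    """Greedy seeded clustering of hits into numbered domains.

    The highest-scoring unassigned hit (ties broken by id) seeds a new
    cluster; every unassigned hit whose midpoint and extent are both within
    tolerance OF THE SEED joins it.  Clusters are numbered from 1 in creation
    order, and each hit's ``domain`` field is set.
    """
    for h in hits:
        if h.midpoint is None or h.extent is None:
            raise ValueError(f"hit {h.id!r} has no midpoint/extent; derive spans first")
    unassigned = sorted(hits, key=lambda h: (-h.score, h.id))
    clusters: list[DomainCluster] = []
    while unassigned:
        seed = unassigned[0]
        number = len(clusters) + 1
        members = [h for h in unassigned
                   if abs(h.midpoint - seed.midpoint) <= mid_tol
                   and abs(h.extent - seed.extent) <= ext_tol]
        for h in members:
            h.domain = number
        clusters.append(DomainCluster(number, seed.id, members,
                                      seed.midpoint, seed.extent))
        unassigned = [h for h in unassigned if h.domain is None]
    return clusters
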