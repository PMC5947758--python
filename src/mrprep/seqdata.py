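"""Sequence-side containers: records, multiple alignments, pairwise alignments."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AlignmentError
from .structures import AA1


@dataclass
class SequenceRecord:
    """One database or target sequence with optional entry metadata."""

    id: str
    sequence: str
    resolution: float | None = None
    r_value: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(AA1) - {"-"}
        if bad:
            raise AlignmentError(
                f"record {self.id!r}: invalid sequence characters {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MultipleAlignment:
    """An ordered id -> gapped-row mapping with a fixed column count."""

    rows: dict[str, str]
    n_columns: int = 0

    def __post_init__(self) -> None:
        if self.rows:
            lengths = {len(r) for r in self.rows.values()}
            if len(lengths) != 1:
                raise AlignmentError(f"ragged alignment rows: lengths {sorted(lengths)}")
            self.n_columns = lengths.pop()

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[seq_id]
        except KeyError:
            raise LookupError(f"id {seq_id!r} not present in alignment") from None


@dataclass
class PairwiseAlignment:
    """Two gapped rows (target on top) plus identity and the position mapping.

    ``mapping`` pairs 1-based ungapped positions (target, hit) for every
    column in which both rows have a residue; it is strictly increasing in
    both coordinates by construction.
    """

    target_row: str
    hit_row: str
    identity: float
    mapping: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.target_row) != len(self.hit_row):
            raise AlignmentError(
                f"pairwise rows differ in length: {len(self.target_row)} vs {len(self.hit_row)}")
        if not 0.0 <= self.identity <= 1.0:
            raise AlignmentError(f"identity {self.identity} outside [0, 1]")
        prev_t, prev_h = 0, 0
        for t, h in self.mapping:
            if t <= prev_t or h <= prev_h:
                raise AlignmentError("mapping must be strictly increasing in both coordinates")
            prev_t, prev_h = t, h

    @property
    def target_positions(self) -> tuple[int, ...]:
        return tuple(t for t, _ in self.mapping)

    def hit_to_target(self) -> dict[int, int]:
        """Hit ungapped position -> target ungapped position."""
        return {h: t for t, h in self.mapping}

    def target_chars(self) -> dict[int, tuple[str, str]]:
        """Target position -> (target residue, hit residue) one-letter pair."""
        out: dict[int, tuple[str, str]] = {}
        t_de = self.target_row.replace("-", "")
        h_de = self.hit_row.replace("-", "")
        for t, h in self.mapping:
            out[t] = (t_de[t - 1], h_de[h - 1])
        return out
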