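"""Readers and writers for the formats the pipeline touches.

PDB handling covers the polymer-ATOM subset a search model needs (HETATM,
waters and hydrogens are discarded; alternate locations resolve to the
highest-occupancy conformer).  Ensemble files carry the per-member
r.m.s.d. annotations on ``REMARK PHASER ENSEMBLE MODEL i RMS r`` cards ahead
of the MODEL/ENDMDL blocks, which is how downstream MR programs pick up the
coordinate-error estimate.  FASTA and Stockholm parsing go through Biopython;
the tiny PIR pairwise dialect is written directly.

All writers are deterministic: the same input produces byte-identical output.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, TextIO

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import AnnotationError, FormatError, ParseError
from .seqdata import MultipleAlignment, SequenceRecord
from .structures import AtomRecord, Chain, Residue, StructureModel

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# ---------------------------------------------------------------------------
# PDB subset
# ---------------------------------------------------------------------------


def _as_text(source: str | TextIO) -> str:
    return source if isinstance(source, str) else source.read()


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> tuple[str, int, str, AtomRecord]:
    """Return (chain id, residue number, 'resname|icode', atom) for one ATOM line."""
    try:
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        res_num = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        b_field = line[60:66].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        b_factor = float(b_field) if b_field else 0.0
        element = line[76:78].strip().upper() or _guess_element(name)
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM record at line {lineno}: {exc}") from None
    atom = AtomRecord(name, element, (x, y, z), occupancy, b_factor, alt_loc)
    return chain_id, res_num, f"{res_name}|{icode}", atom


def _build_model(atom_rows: list[tuple[str, int, str, AtomRecord]],
                 model_id: str) -> StructureModel:
    """Group parsed ATOM rows into chains/residues with alt-loc resolution."""
    # residue key -> (chain id, number, name, icode, {atom name -> atom})
    order: list[tuple[str, int, str]] = []
    residues: dict[tuple[str, int, str], dict[str, AtomRecord]] = {}
    names: dict[tuple[str, int, str], str] = {}
    for chain_id, res_num, name_icode, atom in atom_rows:
        res_name, icode = name_icode.split("|")
        key = (chain_id, res_num, icode)
        if key not in residues:
            residues[key] = {}
            names[key] = res_name
            order.append(key)
        existing = residues[key].get(atom.name)
        if existing is None:
            residues[key][atom.name] = atom
        else:
            # alt-loc rule: highest occupancy wins, ties to alphabetical alt_loc
            if (atom.occupancy, -ord(atom.alt_loc or "~")) > \
                    (existing.occupancy, -ord(existing.alt_loc or "~")):
                residues[key][atom.name] = atom

    chains: list[Chain] = []
    by_chain: dict[str, Chain] = {}
    for key in order:
        chain_id, res_num, icode = key
        if chain_id not in by_chain:
            by_chain[chain_id] = Chain(chain_id)
            chains.append(by_chain[chain_id])
        atoms = list(residues[key].values())
        for a in atoms:
            a.alt_loc = ""
        by_chain[chain_id].residues.append(
            Residue(res_num, names[key], atoms, icode, source_number=res_num))
    for chain in chains:
        chain.residues.sort(key=lambda r: (r.number, r.insertion_code))
    return StructureModel(model_id, chains)


def read_pdb(source: str | TextIO, model_id: str = "model") -> StructureModel:
    """Parse the polymer ATOM records of a PDB stream into a model.

    HETATM records, waters and hydrogens are discarded.  Duplicated alternate
    locations keep the highest-occupancy conformer (ties: alphabetically
    first alt-loc).  Only the first MODEL of a multi-model file is read.
    Raises :class:`ParseError` on malformed fixed columns (naming the line)
    or when no ATOM record survives.
    """
    text = _as_text(source)
    rows: list[tuple[str, int, str, AtomRecord]] = []
    resolution: float | None = None
    r_value: float | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "ENDMDL":
            break
        if record == "REMARK":
            fields = line.split()
            if len(fields) >= 4 and fields[1] == "2" and fields[2] == "RESOLUTION.":
                try:
                    resolution = float(fields[3])
                except ValueError:
                    pass
            continue
        if record != "ATOM":
            continue
        chain_id, res_num, name_icode, atom = _parse_atom_line(line, lineno)
        res_name = name_icode.split("|")[0]
        if res_name in _WATER_NAMES or atom.element in ("H", "D"):
            continue
        rows.append((chain_id, res_num, name_icode, atom))
    if not rows:
        raise ParseError("no polymer ATOM records found (empty structure)")
    model = _build_model(rows, model_id)
    model.resolution = resolution
    model.r_value = r_value
    return model


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise FormatError(f"atom name {name!r} longer than 4 characters")
    # single-letter elements start in column 14; 4-char names fill 13-16
    if len(name) == 4 or len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def _atom_lines(model: StructureModel, serial_start: int = 1,
                ter: bool = True) -> tuple[list[str], int]:
    if not model.chains or all(not c.residues for c in model.chains):
        raise FormatError(f"model {model.id!r} has no residues to write")
    lines: list[str] = []
    serial = serial_start
    for chain in model.chains:
        last = None
        for res in chain.residues:
            for atom in res.atoms:
                name4 = _format_atom_name(atom.name, atom.element)
                lines.append(
                    f"ATOM  {serial:5d} {name4}{atom.alt_loc or ' '}{res.name:>3s} "
                    f"{chain.id[:1] or 'A'}{res.number:4d}{res.insertion_code or ' '}   "
                    f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
                    f"{atom.element:>2s}")
                serial += 1
            last = res
        if ter and last is not None:
            lines.append(f"TER   {serial:5d}      {last.name:>3s} "
                         f"{chain.id[:1] or 'A'}{last.number:4d}{last.insertion_code or ' '}")
            serial += 1
    return lines, serial


def write_pdb(model: StructureModel) -> str:
    """Serialize a model as fixed-column ATOM records with TER and END."""
    lines, _ = _atom_lines(model)
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_ensemble_pdb(ensemble) -> str:
    """Serialize an ensemble search model as an annotated multi-MODEL file.

    One ``REMARK PHASER ENSEMBLE MODEL <i> RMS <r.mmm>`` card per member is
    followed by MODEL/ENDMDL coordinate blocks in member order.  Every member
    must carry an r.m.s.d.-from-centroid annotation.
    """
    members = list(ensemble.members)
    rmsds = list(ensemble.member_rmsd)
    if not members:
        raise AnnotationError("ensemble has no members")
    if len(rmsds) != len(members) or any(r is None for r in rmsds):
        raise AnnotationError("every ensemble member needs an r.m.s.d. annotation")
    lines: list[str] = []
    for i, r in enumerate(rmsds, start=1):
        lines.append(f"REMARK PHASER ENSEMBLE MODEL {i} RMS {r:.3f}")
    for i, member in enumerate(members, start=1):
        lines.append(f"MODEL     {i:4d}")
        body, _ = _atom_lines(member)
        lines.extend(body)
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_ensemble_pdb(source: str | TextIO) -> tuple[list[StructureModel], list[float]]:
    """Parse back an annotated ensemble file: (members, per-member r.m.s.d.)."""
    text = _as_text(source)
    rmsds: list[float] = []
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        record = line[:6].strip()
        if line.startswith("REMARK PHASER ENSEMBLE MODEL"):
            try:
                rmsds.append(float(line.split()[-1]))
            except ValueError as exc:
                raise ParseError(f"bad ensemble REMARK: {line!r}") from exc
        elif record == "MODEL":
            current = []
        elif record == "ENDMDL":
            if current is not None:
                blocks.append(current)
            current = None
        elif current is not None:
            current.append(line)
    members = [read_pdb("\n".join(block) + "\n", model_id=f"member_{i}")
               for i, block in enumerate(blocks, start=1)]
    return members, rmsds


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _metadata_from_description(description: str) -> tuple[float | None, float | None]:
    resolution = r_value = None
    for token in description.split():
        if token.startswith("resolution="):
            try:
                resolution = float(token.split("=", 1)[1])
            except ValueError:
                pass
        elif token.startswith("rvalue="):
            try:
                r_value = float(token.split("=", 1)[1])
            except ValueError:
                pass
    return resolution, r_value


def read_fasta(source: str | TextIO) -> list[SequenceRecord]:
    """Read FASTA records (uppercased), with optional ``resolution=``/``rvalue=``
    tokens in the description parsed into entry metadata."""
    text = _as_text(source)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"FASTA record {rec.id!r} has an empty sequence body")
        resolution, r_value = _metadata_from_description(rec.description)
        records.append(SequenceRecord(rec.id, seq, resolution, r_value))
    if not records and text.strip():
        raise ParseError("no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord]) -> str:
    """Write FASTA wrapped at 60 columns, metadata as description tokens."""
    out: list[_BioSeqRecord] = []
    for rec in records:
        tokens = []
        if rec.resolution is not None:
            tokens.append(f"resolution={rec.resolution:g}")
        if rec.r_value is not None:
            tokens.append(f"rvalue={rec.r_value:g}")
        out.append(_BioSeqRecord(Seq(rec.sequence), id=rec.id,
                                 description=" ".join(tokens)))
    handle = _io.StringIO()
    SeqIO.write(out, handle, "fasta")
    return handle.getvalue()


# ---------------------------------------------------------------------------
# PIR pairwise alignment
# ---------------------------------------------------------------------------


def _wrap(seq: str, width: int = 60) -> list[str]:
    return [seq[i:i + width] for i in range(0, len(seq), width)] or [""]


def write_pir_pairwise(target_id: str, target_row: str,
                       hit_id: str, hit_row: str) -> str:
    """Write a two-entry PIR alignment (`>P1;` headers, `*`-terminated rows).

    The target entry is tagged ``sequence``, the hit ``structure``, following
    the convention of comparative-modelling alignment files.
    """
    from .errors import AlignmentError
    if len(target_row) != len(hit_row):
        raise AlignmentError(
            f"PIR rows differ in length: {len(target_row)} vs {len(hit_row)}")
    lines: list[str] = []
    for seq_id, kind, row in ((target_id, "sequence", target_row),
                              (hit_id, "structure", hit_row)):
        lines.append(f">P1;{seq_id}")
        lines.append(f"{kind}:{seq_id}::::::::")
        lines.extend(_wrap(row + "*"))
    return "\n".join(lines) + "\n"


def read_pir(source: str | TextIO) -> list[tuple[str, str]]:
    """Parse a PIR alignment back into (id, gapped row) pairs."""
    text = _as_text(source)
    entries: list[tuple[str, str]] = []
    seq_id: str | None = None
    body: list[str] = []
    skip_description = False

    def flush() -> None:
        nonlocal seq_id, body
        if seq_id is not None:
            seq = "".join(body)
            if not seq.endswith("*"):
                raise ParseError(f"PIR entry {seq_id!r} not terminated by '*'")
            entries.append((seq_id, seq[:-1]))
        seq_id, body = None, []

    for line in text.splitlines():
        if line.startswith(">P1;"):
            flush()
            seq_id = line[4:].strip()
            skip_description = True
        elif seq_id is not None and skip_description:
            skip_description = False  # free-text description line
        elif seq_id is not None and line.strip():
            body.append(line.strip())
    flush()
    return entries


# ---------------------------------------------------------------------------
# Stockholm
# ---------------------------------------------------------------------------


def read_stockholm(source: str | TextIO) -> MultipleAlignment:
    """Read a Stockholm 1.0 MSA (wrapped blocks concatenated per id).

    Both '.' and '-' are treated as gaps and normalized to '-'; sequences are
    uppercased.  Annotation (#=GC etc.) lines are ignored.
    """
    text = _as_text(source)
    if not text.lstrip().startswith("# STOCKHOLM"):
        raise ParseError("missing '# STOCKHOLM' header")
    if "//" not in text:
        raise ParseError("missing '//' terminator")
    try:
        alignment = AlignIO.read(_io.StringIO(text), "stockholm")
    except ValueError as exc:
        raise ParseError(f"bad Stockholm alignment: {exc}") from None
    rows = {rec.id: str(rec.seq).upper().replace(".", "-") for rec in alignment}
    return MultipleAlignment(rows)


# ---------------------------------------------------------------------------
# Hit-score table
# ---------------------------------------------------------------------------


def read_hit_table(source: str | TextIO):
    """Read a whitespace-delimited (hit id, score) table into SearchHits.

    Lines beginning with '#' and blank lines are skipped; file order is
    preserved.  Non-numeric scores raise :class:`ParseError`.
    """
    from .search_clustering import SearchHit

    text = _as_text(source)
    hits: list[SearchHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 2:
            raise ParseError(f"hit table line {lineno}: expected 'id score'")
        try:
            score = float(fields[1])
        except ValueError:
            raise ParseError(
                f"hit table line {lineno}: non-numeric score {fields[1]!r}") from None
        hits.append(SearchHit(fields[0], score))
    return hits


def write_hit_table(hits) -> str:
    """Write hits back out as the two-column table."""
    lines = ["# hit_id score"]
    lines += [f"{h.id}\t{h.score:g}" for h in hits]
    return "\n".join(lines) + "\n"
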