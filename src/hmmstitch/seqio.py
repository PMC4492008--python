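"""Core sequence containers and FASTA I/O.

The on-disk conventions follow the HMMER/a2m style referenced throughout the
method: '-' and '.' are both accepted as gap characters on read and normalised
to '-'; in *unmasked* output, residues sitting in insertion columns are written
in lowercase while backbone (match) columns are uppercase; *masked* output
simply drops every insertion column.  Because plain FASTA cannot carry the
column flags losslessly in every edge case, unmasked alignments are written
with a small sidecar text file (``<fasta>.cols``) holding one 'M'/'I' flag per
column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

from .alphabet import GAP, GAP_CHARS, Alphabet, get_alphabet
from .errors import AlignmentError, SequenceFormatError

MATCH, INSERTION = "M", "I"


@dataclass(frozen=True)
class SequenceRecord:
    """An identified, unaligned sequence over a declared alphabet."""

    id: str
    residues: str
    alphabet: Alphabet

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceFormatError(f"invalid sequence id {self.id!r}")
        if any(c in GAP_CHARS for c in self.residues):
            raise SequenceFormatError(
                f"sequence {self.id!r}: unaligned residues may not contain gaps"
            )
        self.alphabet.validate(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)


class SequenceSet:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records: Iterable[SequenceRecord]):
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise SequenceFormatError(f"duplicate sequence id {rec.id!r}")
            self._records[rec.id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._records

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._records[seq_id]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._records)

    @property
    def alphabet(self) -> Alphabet:
        return next(iter(self._records.values())).alphabet

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        wanted = set(ids)
        missing = wanted - set(self._records)
        if missing:
            raise SequenceFormatError(f"unknown sequence ids: {sorted(missing)}")
        return SequenceSet(r for r in self if r.id in wanted)


@dataclass
class Alignment:
    """A gapped row-per-sequence matrix with per-column MATCH/INSERTION flags.

    ``rows`` maps sequence id to its gapped string; every row has the same
    width ``W`` and ``column_flags`` is a length-``W`` string over {'M','I'}.
    A backbone-only alignment has all columns flagged MATCH.
    """

    rows: dict[str, str]
    alphabet: Alphabet
    column_flags: str = field(default="")

    def __post_init__(self):
        if not self.rows:
            raise AlignmentError("alignment must contain at least one row")
        widths = {len(r) for r in self.rows.values()}
        if len(widths) != 1:
            bad = next(
                i for i, r in self.rows.items() if len(r) != len(next(iter(self.rows.values())))
            )
            raise AlignmentError(f"ragged alignment: row {bad!r} has deviant length")
        if not self.column_flags:
            self.column_flags = MATCH * self.width
        if len(self.column_flags) != self.width:
            raise AlignmentError(
                f"column_flags length {len(self.column_flags)} != width {self.width}"
            )
        if set(self.column_flags) - {MATCH, INSERTION}:
            raise AlignmentError("column_flags must be a string over {'M','I'}")
        for sid, row in self.rows.items():
            self.alphabet.validate(row.replace(GAP, ""), sid)

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")

    def to_sequence_set(self) -> SequenceSet:
        return SequenceSet(
            SequenceRecord(i, self.ungapped(i), self.alphabet) for i in self.rows
        )

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows.values())

    def restrict(self, ids: Iterable[str], drop_empty_columns: bool = False) -> "Alignment":
        """Row restriction; optionally drop columns left all-gap."""
        wanted = [i for i in self.rows if i in set(ids)]
        missing = set(ids) - set(self.rows)
        if missing:
            raise AlignmentError(f"unknown row ids: {sorted(missing)}")
        rows = {i: self.rows[i] for i in wanted}
        flags = self.column_flags
        if drop_empty_columns:
            keep = [
                j for j in range(self.width) if any(r[j] != GAP for r in rows.values())
            ]
            rows = {i: "".join(r[j] for j in keep) for i, r in rows.items()}
            flags = "".join(flags[j] for j in keep)
        return Alignment(rows, self.alphabet, flags)

    def drop_insertion_columns(self) -> "Alignment":
        keep = [j for j, f in enumerate(self.column_flags) if f == MATCH]
        rows = {i: "".join(r[j] for j in keep) for i, r in self.rows.items()}
        return Alignment(rows, self.alphabet, MATCH * len(keep))


# ---------------------------------------------------------------------------
# FASTA


def _sidecar_path(path) -> str:
    return str(path) + ".cols"


def write_column_flags(path, flags: str) -> None:
    with open(_sidecar_path(path), "w") as fh:
        fh.write(f"# columns: {len(flags)}\n{flags}\n")


def read_column_flags(path) -> str | None:
    sc = _sidecar_path(path)
    if not os.path.exists(sc):
        return None
    with open(sc) as fh:
        header = fh.readline()
        flags = fh.readline().strip()
    if not header.startswith("# columns:"):
        raise AlignmentError(f"malformed sidecar flag file {sc!r}")
    want = int(header.split(":")[1])
    if want != len(flags):
        raise AlignmentError(
            f"sidecar {sc!r} declares {want} columns but carries {len(flags)} flags"
        )
    return flags


def read_fasta(path, aligned: bool = False, alphabet="dna"):
    """Read a FASTA file into a :class:`SequenceSet` or :class:`Alignment`.

    Gap characters '-' and '.' are both accepted and normalised to '-'.  For
    aligned input the column flags are taken from the ``.cols`` sidecar when
    present; otherwise any column containing a lowercase residue is treated as
    an INSERTION column (a2m-like convention).  Case is ignored for unaligned
    input.
    """
    ab = get_alphabet(alphabet)
    raw = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not raw:
        raise SequenceFormatError(f"no FASTA records found in {path}")
    if not aligned:
        return SequenceSet(
            SequenceRecord(
                sid, seq.upper().translate(str.maketrans("", "", "-.")), ab
            )
            for sid, seq in raw
        )
    width = len(raw[0][1])
    for sid, seq in raw:
        if len(seq) != width:
            raise AlignmentError(
                f"ragged aligned FASTA: row {sid!r} has length {len(seq)}, "
                f"expected {width}"
            )
    flags = read_column_flags(path)
    if flags is None:
        flags = "".join(
            INSERTION if any(seq[j].islower() for _, seq in raw) else MATCH
            for j in range(width)
        )
    norm = {}
    for sid, seq in raw:
        if sid in norm:
            raise SequenceFormatError(f"duplicate sequence id {sid!r}")
        norm[sid] = "".join(GAP if c in GAP_CHARS else c.upper() for c in seq)
    return Alignment(norm, ab, flags)


def write_fasta(seqs: SequenceSet, path) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def write_alignment(aln: Alignment, path, masked: bool = False) -> None:
    """Write an alignment to FASTA.

    ``masked=True`` drops all INSERTION columns.  ``masked=False`` writes
    insertion-column residues in lowercase, match-column residues in
    uppercase, and a ``.cols`` sidecar with the column flags.
    """
    if masked:
        out = aln.drop_insertion_columns()
        with open(path, "w") as fh:
            for sid, row in out.rows.items():
                fh.write(f">{sid}\n{row}\n")
        return
    with open(path, "w") as fh:
        for sid, row in aln.rows.items():
            cased = "".join(
                c.lower() if f == INSERTION else c
                for c, f in zip(row, aln.column_flags)
            )
            fh.write(f">{sid}\n{cased}\n")
    write_column_flags(path, aln.column_flags)
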