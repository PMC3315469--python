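"""Protein sequence and alignment I/O.

Defines the two core containers — :class:`ProteinSequence` (ungapped residues
with an identifier) and :class:`Msa` (a rectangular gapped alignment) — and
readers/writers for plain FASTA, aligned FASTA and Stockholm 1.0. Parsing of
the standard formats is delegated to Biopython; this module adds the package's
validation contract (unique ids, legal residue letters, rectangular
alignments) and gap normalization ('.' and '-' both accepted, stored as '-').
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

from Bio import AlignIO, SeqIO

from ._alphabet import LEGAL_LETTERS

Source = Union[str, IO[str]]


class SeqIoError(ValueError):
    """Raised on malformed sequence or alignment input."""


@dataclass(frozen=True)
class ProteinSequence:
    """An ungapped protein sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header; the
    remainder is kept as ``description``. Residues are stored uppercase and may
    contain the ambiguity letters X/B/Z/U/O but never gaps or whitespace.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIoError("sequence identifier must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise SeqIoError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in LEGAL_LETTERS:
                raise SeqIoError(
                    f"illegal residue {ch!r} in record {self.id!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Msa:
    """A rectangular multiple sequence alignment.

    Rows are (id, aligned string) pairs; gaps are normalized to '-'.
    ``column_annotations`` carries optional per-column metadata such as
    Stockholm ``#=GC`` lines; ``metadata`` carries free-form provenance
    (e.g. ids of rows that were all-gap after slicing).
    """

    ids: list[str]
    rows: list[str]
    column_annotations: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise SeqIoError("ids and rows must have equal length")
        if not self.rows:
            raise SeqIoError("alignment has no rows")
        seen: set[str] = set()
        for rid in self.ids:
            if rid in seen:
                raise SeqIoError(f"duplicate identifier {rid!r}")
            seen.add(rid)
        normalized = []
        n_cols = len(self.rows[0].replace(".", "-"))
        for rid, row in zip(self.ids, self.rows):
            row = row.upper().replace(".", "-")
            if len(row) != n_cols:
                raise SeqIoError(f"unequal alignment lengths: row {rid!r}")
            for ch in row:
                if ch != "-" and ch not in LEGAL_LETTERS:
                    raise SeqIoError(f"illegal residue {ch!r} in row {rid!r}")
            normalized.append(row)
        self.rows = normalized

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise SeqIoError(f"unknown reference {rid!r}") from None

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")

    def to_sequences(self) -> list[ProteinSequence]:
        """Strip gaps from every row; all-gap rows are rejected."""
        return [
            ProteinSequence(rid, row.replace("-", ""))
            for rid, row in zip(self.ids, self.rows)
        ]


def _as_handle(source: Source) -> IO[str]:
    if isinstance(source, str):
        if not source or "\n" in source or source.lstrip().startswith((">", "#")):
            return io.StringIO(source)
        return open(source, "rt")
    return source


def read_fasta(source: Source) -> list[ProteinSequence]:
    """Read a multi-record FASTA of ungapped protein sequences.

    The id is the first whitespace token of each header. Raises
    :class:`SeqIoError` on empty input, duplicate ids or illegal residues
    (gaps in particular are illegal in unaligned FASTA).
    """
    handle = _as_handle(source)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise SeqIoError(f"duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinSequence(rec.id, str(rec.seq), desc))
    if not records:
        raise SeqIoError("no records in FASTA input")
    return records


def read_msa(source: Source, dialect: str = "aligned-fasta") -> Msa:
    """Read an alignment in ``aligned-fasta`` or ``stockholm`` dialect.

    '.' gaps are normalized to '-'; Stockholm ``#=GC`` per-column annotation
    lines are preserved in ``column_annotations``.
    """
    if dialect not in ("aligned-fasta", "stockholm"):
        raise SeqIoError(f"unknown alignment dialect {dialect!r}")
    handle = _as_handle(source)
    fmt = "fasta" if dialect == "aligned-fasta" else "stockholm"
    if dialect == "stockholm":
        aln = AlignIO.read(handle, fmt)
        col_ann = dict(getattr(aln, "column_annotations", {}) or {})
        ids = [rec.id for rec in aln]
        rows = [str(rec.seq) for rec in aln]
    else:
        col_ann = {}
        ids, rows = [], []
        for rec in SeqIO.parse(handle, fmt):
            ids.append(rec.id)
            rows.append(str(rec.seq))
        if rows:
            lengths = {len(r) for r in rows}
            if len(lengths) > 1:
                longest = max(lengths)
                bad = ids[next(i for i, r in enumerate(rows) if len(r) != longest)]
                raise SeqIoError(f"unequal alignment lengths: row {bad!r}")
    if not rows:
        raise SeqIoError("no records in alignment input")
    return Msa(ids=ids, rows=rows, column_annotations=col_ann)


def write_fasta(records: Iterable[ProteinSequence], width: int = 60) -> str:
    """Render records as FASTA text; round-trips losslessly through
    :func:`read_fasta`. An empty record list yields the empty string."""
    if width < 1:
        raise ValueError("width must be >= 1")
    chunks = []
    for rec in records:
        header = f">{rec.id} {rec.description}".rstrip()
        body = "\n".join(
            rec.residues[i: i + width] for i in range(0, len(rec.residues), width)
        )
        chunks.append(f"{header}\n{body}\n")
    return "".join(chunks)


def write_stockholm(msa: Msa) -> str:
    """Render an Msa as minimal Stockholm 1.0 (rows plus #=GC annotations)."""
    tags = [f"#=GC {key}" for key in sorted(msa.column_annotations)]
    pad = max(len(i) for i in list(msa.ids) + tags) + 2
    lines = ["# STOCKHOLM 1.0"]
    for rid, row in zip(msa.ids, msa.rows):
        lines.append(f"{rid:<{pad}}{row}")
    for tag, (_, ann) in zip(tags, sorted(msa.column_annotations.items())):
        lines.append(f"{tag:<{pad}}{ann}")
    lines.append("//")
    return "\n".join(lines) + "\n"
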