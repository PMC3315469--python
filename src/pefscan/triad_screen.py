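"""Catalytic-triad integrity screening over a family alignment.

Calpain proteolysis requires an intact Cys/His/Asn triad in the catalytic
domain. Given a family alignment and a :class:`TriadSpec` (three 1-based
positions on an ungapped reference row plus the required letters), the screen
maps each position to its alignment column and reads the residue of every
row at those columns. A residue counts as present only when it equals the
required letter exactly; a gap, an ambiguity code or any substitution marks
the residue as missing, so a protein is never called catalytically intact on
uncertain evidence. Proteins missing at least one residue are the
"calpain-like inactive" candidates.

``filter_redundant`` implements the fragment/splice-variant filter applied
before such a screen: exact substrings of a longer sequence are removed as
fragments, and near-identical pairs (identity over the shorter sequence
above a threshold) keep only the longest member.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .seqio import Msa, ProteinSequence, SeqIoError

TRIAD_LABELS = ("C", "H", "N")
IDENTITY_THRESHOLD_DEFAULT = 0.97


@dataclass(frozen=True)
class TriadSpec:
    """Reference definition of the catalytic triad."""

    ref_id: str
    positions: tuple[int, int, int]  # 1-based ungapped reference positions
    required: tuple[str, str, str] = ("C", "H", "N")

    def __post_init__(self) -> None:
        if not (0 < self.positions[0] < self.positions[1] < self.positions[2]):
            raise ValueError("triad positions must be strictly increasing")
        if any(len(r) != 1 or not r.isalpha() for r in self.required):
            raise ValueError("required residues must be single letters")
        object.__setattr__(self, "required", tuple(r.upper() for r in self.required))


@dataclass(frozen=True)
class TriadReport:
    """Per-protein triad verdict."""

    id: str
    residues_at_triad: tuple[str, str, str]  # '-' where gapped
    missing: tuple[str, ...]  # subset of C/H/N labels
    intact: bool

    def __post_init__(self) -> None:
        if self.intact != (len(self.missing) == 0):
            raise ValueError("intact must mean no missing residues")


def map_reference_positions(aln: Msa, ref_id: str, positions: list[int]) -> list[int]:
    """0-based alignment column of each 1-based ungapped reference position."""
    row = aln.row(ref_id)
    cols = [i for i, ch in enumerate(row) if ch != "-"]
    out = []
    for pos in positions:
        if not (1 <= pos <= len(cols)):
            raise SeqIoError(
                f"coordinate beyond reference length: {pos} on {ref_id!r} "
                f"(ungapped length {len(cols)})"
            )
        out.append(cols[pos - 1])
    return out


def screen_triad(aln: Msa, spec: TriadSpec) -> list[TriadReport]:
    """Read the three triad columns for every row of the alignment.

    Strict matching: only the exact required letter counts as present.
    """
    columns = map_reference_positions(aln, spec.ref_id, list(spec.positions))
    reports = []
    for rid, row in zip(aln.ids, aln.rows):
        observed = tuple(row[c] for c in columns)
        missing = tuple(
            label
            for label, obs, req in zip(TRIAD_LABELS, observed, spec.required)
            if obs != req
        )
        reports.append(
            TriadReport(
                id=rid,
                residues_at_triad=observed,
                missing=missing,
                intact=not missing,
            )
        )
    return reports


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=0,
    extend_gap_score=0,
)


def _identity(a: str, b: str) -> float:
    """Maximum matches over an optimal alignment, divided by the shorter length."""
    if not a or not b:
        return 0.0
    matches = _aligner.score(a, b)
    return float(matches) / min(len(a), len(b))


def filter_redundant(
    seqs: list[ProteinSequence],
    identity_threshold: float = IDENTITY_THRESHOLD_DEFAULT,
    substring_rule: bool = True,
    msa: Msa | None = None,
) -> tuple[list[ProteinSequence], list[tuple[ProteinSequence, str]]]:
    """Remove protein fragments and near-identical splice variants.

    Sequences are considered longest-first (ties broken by lexicographic id,
    smaller id kept). A candidate is removed as ``fragment-of:<id>`` when it
    is an exact substring of an already-kept sequence, or as
    ``variant-of:<id>`` when its identity to a kept sequence over the shorter
    length reaches ``identity_threshold``. When an ``msa`` covering the ids
    is supplied, identity is computed on the aligned rows instead of by
    pairwise alignment. Idempotent: filtering the kept set again removes
    nothing.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    kept: list[ProteinSequence] = []
    removed: list[tuple[ProteinSequence, str]] = []
    aligned = {rid: row for rid, row in zip(msa.ids, msa.rows)} if msa else {}
    for cand in ordered:
        reason = None
        for ref in kept:
            if (
                substring_rule
                and len(cand.residues) < len(ref.residues)
                and cand.residues in ref.residues
            ):
                reason = f"fragment-of:{ref.id}"
                break
            if msa and cand.id in aligned and ref.id in aligned:
                pairs = [
                    (x, y)
                    for x, y in zip(aligned[cand.id], aligned[ref.id])
                    if x != "-" and y != "-"
                ]
                shorter = min(len(cand.residues), len(ref.residues))
                ident = (
                    sum(1 for x, y in pairs if x == y) / shorter if shorter else 0.0
                )
            else:
                ident = _identity(cand.residues, ref.residues)
            if ident >= identity_threshold:
                reason = f"variant-of:{ref.id}"
                break
        if reason is None:
            kept.append(cand)
        else:
            removed.append((cand, reason))
    original_order = {s.id: i for i, s in enumerate(seqs)}
    kept.sort(key=lambda s: original_order[s.id])
    removed.sort(key=lambda sr: original_order[sr[0].id])
    return kept, removed


def screen_summary(
    reports: list[TriadReport],
    taxon_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Counts of intact vs inactive proteins, optionally grouped by clade.

    Ids absent from ``taxon_map`` are grouped under ``unassigned`` rather
    than dropped; group rows always sum to the ungrouped totals.
    """
    if not reports:
        return pd.DataFrame(columns=["clade", "intact", "inactive", "total"])
    rows: dict[str, list[int]] = {}
    for rep in reports:
        clade = (
            taxon_map.get(rep.id, "unassigned") if taxon_map is not None else "all"
        )
        bucket = rows.setdefault(clade, [0, 0])
        bucket[0 if rep.intact else 1] += 1
    out = pd.DataFrame(
        [
            {"clade": clade, "intact": c[0], "inactive": c[1], "total": c[0] + c[1]}
            for clade, c in sorted(rows.items())
        ]
    )
    return out


def format_triad_report(reports: list[TriadReport]) -> str:
    """Deterministic TSV rendering of a triad screen."""
    buf = io.StringIO()
    buf.write("id\tres_C\tres_H\tres_N\tmissing\tintact\n")
    for rep in reports:
        buf.write(
            f"{rep.id}\t{rep.residues_at_triad[0]}\t{rep.residues_at_triad[1]}\t"
            f"{rep.residues_at_triad[2]}\t{','.join(rep.missing)}\t{rep.intact}\n"
        )
    return buf.getvalue()


def read_triad_spec(source) -> TriadSpec:
    """Read a TriadSpec TSV: ref_id, pos_C, pos_H, pos_N, req (e.g. 'CHN')."""
    if isinstance(source, str) and "\n" not in source and "\t" not in source:
        with open(source, "rt") as fh:
            return read_triad_spec(fh)
    text = source if isinstance(source, str) else source.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    values = dict(zip(header, lines[1].split("\t")))
    req = values.get("req", "CHN")
    return TriadSpec(
        ref_id=values["ref_id"],
        positions=(int(values["pos_C"]), int(values["pos_H"]), int(values["pos_N"])),
        required=(req[0], req[1], req[2]),
    )
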