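"""Profile-HMM construction from seed alignments.

Implements the classic match/insert/delete profile architecture (Krogh/Durbin
style, the core of HMMER's Plan7 without the flanking N/C/J states):

* ``slice_alignment`` cuts a motif sub-alignment out of a master alignment
  using 1-based residue coordinates on an ungapped reference row — the way
  per-motif seed alignments are carved out of a full-length family alignment.
* ``assign_match_columns`` applies the standard gap-fraction heuristic
  (a column is a match column when fewer than ``gap_threshold`` of its
  entries are gaps).
* ``build_profile`` turns a seed alignment into a :class:`ProfileHmm` by
  counting emissions/transitions along each row's implied state path and
  adding a single-parameter background-proportional pseudocount.
* ``sample_sequence`` runs the generative model, which the synthetic-fixture
  generators use to plant realistic motif instances.

Node indexing convention: match states are 1..L. Transition arrays are
indexed by source node 0..L, node 0 being Begin (B->M1 is ``t_mm[0]``,
B->I0 is ``t_mi[0]``, B->D1 is ``t_md[0]``); at node L the M->M / I->M /
D->M entries are the exits to End.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Union

import numpy as np

from ._alphabet import (
    AMBIG_INDEX,
    AMINO_ACIDS,
    N_AA,
    encode,
    uniform_background,
    validate_background,
)
from .seqio import Msa, ProteinSequence, SeqIoError

TRANSITION_KEYS = ("mm", "mi", "md", "im", "ii", "dm", "dd")

#: transition pseudocount shapes; "plan7" is the classic protein-family
#: Dirichlet (heavily biased toward match-to-match), "uniform" splits the
#: weight evenly over the legal moves of each state
TRANSITION_PRIORS = {
    "plan7": {
        "mm": 0.7939, "mi": 0.0278, "md": 0.0135,
        "im": 0.1551, "ii": 0.1331,
        "dm": 0.9002, "dd": 0.5630,
    },
    "uniform": {
        "mm": 1 / 3, "mi": 1 / 3, "md": 1 / 3,
        "im": 1 / 2, "ii": 1 / 2,
        "dm": 1 / 2, "dd": 1 / 2,
    },
}

_PROB_TOL = 1e-9


@dataclass
class ProfileHmm:
    """A profile hidden Markov model over the 20 amino acids.

    Attributes
    ----------
    name : str
        Model name (e.g. ``EF-1``).
    match_emissions : (L, 20) array
        Per-node match emission probabilities.
    insert_emissions : (L+1, 20) array
        Per-node insert emission probabilities (node 0 = I0 before M1).
    transitions : dict of (L+1,) arrays
        Keys ``mm, mi, md, im, ii, dm, dd``; see module docstring for the
        Begin/End conventions.
    background : (20,) array
        Null emission composition used for log-odds scoring.
    metadata : dict
        Provenance: seed alignment id, build parameters, etc.
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: dict[str, np.ndarray]
    background: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = validate_background(self.background)
        self.transitions = {
            k: np.asarray(v, dtype=float) for k, v in self.transitions.items()
        }
        self.validate()

    @property
    def length(self) -> int:
        """Number of match states L."""
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        """Assert all probabilistic invariants (raises ValueError)."""
        L = self.length
        if L < 1:
            raise ValueError("model must have at least one match state")
        if self.match_emissions.shape != (L, N_AA):
            raise ValueError("match_emissions must be (L, 20)")
        if self.insert_emissions.shape != (L + 1, N_AA):
            raise ValueError("insert_emissions must be (L+1, 20)")
        for key in TRANSITION_KEYS:
            if key not in self.transitions:
                raise ValueError(f"missing transition group {key!r}")
            if self.transitions[key].shape != (L + 1,):
                raise ValueError(f"transition group {key!r} must be (L+1,)")
        for arr, label in (
            (self.match_emissions, "match emission"),
            (self.insert_emissions, "insert emission"),
        ):
            if np.any(arr < -_PROB_TOL) or np.any(arr > 1 + _PROB_TOL):
                raise ValueError(f"{label} probabilities outside [0, 1]")
            sums = arr.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError(f"{label} rows must sum to 1")
        t = self.transitions
        m_out = t["mm"] + t["mi"] + t["md"]
        i_out = t["im"] + t["ii"]
        d_out = t["dm"] + t["dd"]
        if np.any(np.abs(m_out - 1.0) > 1e-9) or np.any(np.abs(i_out - 1.0) > 1e-9):
            raise ValueError("outgoing transition groups must sum to 1")
        # delete states exist only for nodes 1..L
        if np.any(np.abs(d_out[1:] - 1.0) > 1e-9):
            raise ValueError("outgoing transition groups must sum to 1")
        if abs(t["md"][self.length]) > 1e-12 or abs(t["dd"][self.length]) > 1e-12:
            raise ValueError("node L cannot transition to a node L+1 state")

    def consensus(self) -> str:
        """Most probable residue at each match state."""
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))


@dataclass(frozen=True)
class MotifAnnotation:
    """Ordered motif coordinates on an ungapped reference sequence.

    ``motifs`` holds (motif_index, start, end) with 1-based inclusive
    residue coordinates; intervals must be sorted and non-overlapping.
    """

    ref_id: str
    motifs: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for idx, start, end in self.motifs:
            if not (1 <= start <= end):
                raise ValueError(f"motif {idx}: invalid interval {start}..{end}")
            if start <= prev_end:
                raise ValueError(f"motif {idx}: overlaps previous motif")
            prev_end = end


def read_motif_annotation(source: Union[str, IO[str]]) -> MotifAnnotation:
    """Read a motif annotation TSV with columns ref_id, motif_index, start, end."""
    if isinstance(source, str) and "\t" not in source and "\n" not in source:
        with open(source, "rt") as fh:
            return read_motif_annotation(fh)
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()
    reader = csv.DictReader(lines, delimiter="\t")
    ref_ids = set()
    motifs = []
    for row in reader:
        ref_ids.add(row["ref_id"])
        motifs.append((int(row["motif_index"]), int(row["start"]), int(row["end"])))
    if len(ref_ids) != 1:
        raise ValueError("motif annotation must reference exactly one sequence")
    motifs.sort(key=lambda m: m[1])
    return MotifAnnotation(ref_id=ref_ids.pop(), motifs=tuple(motifs))


def _reference_columns(row: str, rid: str) -> np.ndarray:
    """Alignment column index (0-based) of each ungapped residue of a row."""
    cols = np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord("-"))
    if cols.size == 0:
        raise SeqIoError(f"reference row {rid!r} is all gaps")
    return cols


def slice_alignment(aln: Msa, ref_id: str, start: int, end: int) -> Msa:
    """Extract the alignment columns spanning reference residues start..end.

    Coordinates are 1-based inclusive on the ungapped reference row. Every
    alignment column between (and including) the columns holding the two
    boundary residues is kept, so insert columns internal to the motif are
    retained. All rows are kept; rows that are entirely gaps within the slice
    are listed in ``metadata['all_gap_ids']`` rather than dropped.
    """
    row = aln.row(ref_id)
    cols = _reference_columns(row, ref_id)
    if not (1 <= start <= end <= cols.size):
        raise SeqIoError(
            f"coordinate beyond reference length: {start}..{end} on "
            f"{ref_id!r} (ungapped length {cols.size})"
        )
    c0, c1 = int(cols[start - 1]), int(cols[end - 1])
    sliced = [r[c0: c1 + 1] for r in aln.rows]
    all_gap = [rid for rid, r in zip(aln.ids, sliced) if set(r) == {"-"}]
    col_ann = {k: v[c0: c1 + 1] for k, v in aln.column_annotations.items()}
    return Msa(
        ids=list(aln.ids),
        rows=sliced,
        column_annotations=col_ann,
        metadata={
            "sliced_from": ref_id,
            "ref_start": start,
            "ref_end": end,
            "all_gap_ids": all_gap,
        },
    )


def assign_match_columns(aln: Msa, gap_threshold: float = 0.5) -> list[bool]:
    """Mark each column as a match column iff its gap fraction < gap_threshold.

    Raises ValueError if no column qualifies.
    """
    if not (0.0 < gap_threshold <= 1.0):
        raise ValueError("gap_threshold must be in (0, 1]")
    n = aln.n_rows
    flags = []
    for j in range(aln.n_cols):
        gaps = sum(1 for r in aln.rows if r[j] == "-")
        flags.append(gaps / n < gap_threshold)
    if not any(flags):
        raise ValueError("no match columns at this gap threshold")
    return flags


def _row_state_path(row: str, match_columns: list[bool]) -> list[tuple[str, int, str]]:
    """Implied state path of one aligned row: list of (state, node, letter).

    Match-column residue -> ('M', k, aa); match-column gap -> ('D', k, '-');
    insert-column residue -> ('I', k, aa); insert-column gaps emit nothing.
    """
    path = []
    node = 0
    for ch, is_match in zip(row, match_columns):
        if is_match:
            node += 1
            path.append(("M" if ch != "-" else "D", node, ch))
        elif ch != "-":
            path.append(("I", node, ch))
    return path


def build_profile(
    aln: Msa,
    match_columns: list[bool] | None = None,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    name: str = "profile",
    gap_threshold: float = 0.5,
    transition_prior: str = "plan7",
) -> ProfileHmm:
    """Estimate a profile HMM from a seed alignment.

    Match emissions for node k are the observed residue counts in that match
    column plus ``pseudocount_weight`` times the background, normalized.
    Transition counts come from each row's implied state path (gap in a match
    column -> delete, residue in an insert column -> insert) and receive the
    same background-proportional pseudocount, uniform over the moves legal at
    each node. Insert emissions are fixed to the background. Ambiguity
    residues contribute to the path but not to emission counts.
    """
    if match_columns is None:
        match_columns = assign_match_columns(aln, gap_threshold)
    if len(match_columns) != aln.n_cols:
        raise ValueError("match_columns length must equal alignment width")
    L = sum(match_columns)
    if L < 1:
        raise ValueError("at least one match column is required")
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be >= 0")
    bg = uniform_background() if background is None else validate_background(background)

    m_counts = np.zeros((L, N_AA))
    t_counts = {k: np.zeros(L + 1) for k in TRANSITION_KEYS}

    for row in aln.rows:
        path = _row_state_path(row, match_columns)
        prev_state, prev_node = "M", 0  # Begin behaves like M0
        for state, node, letter in path:
            t_counts[prev_state.lower() + state.lower()][prev_node] += 1
            if state == "M":
                idx = encode(letter)[0]
                if idx != AMBIG_INDEX:
                    m_counts[node - 1, idx] += 1
            prev_state, prev_node = state, node
        # exit to End counts as *->M at node L
        t_counts[prev_state.lower() + "m"][prev_node if prev_state != "M" else L] += 1

    w = pseudocount_weight
    match_emissions = m_counts + w * bg
    row_sums = match_emissions.sum(axis=1, keepdims=True)
    # a zero row (w == 0 and a match column with no counted residues) -> background
    match_emissions = np.where(row_sums > 0, match_emissions / np.where(row_sums > 0, row_sums, 1.0), bg)
    insert_emissions = np.tile(bg, (L + 1, 1))

    t = {k: v.copy() for k, v in t_counts.items()}
    # transition pseudocounts: a Dirichlet prior strongly favouring M->M
    # (the Plan7 default shape for protein families; a uniform prior grossly
    # overestimates indel rates on small seed alignments), scaled by w
    prior = TRANSITION_PRIORS[transition_prior]
    for k in range(L + 1):
        for key in ("mm", "mi", "md"):
            if key == "md" and k == L:
                continue
            t[key][k] += w * prior[key]
        for key in ("im", "ii"):
            t[key][k] += w * prior[key]
        if k >= 1:
            t["dm"][k] += w * prior["dm"]
            if k < L:
                t["dd"][k] += w * prior["dd"]
    # normalize each outgoing group; empty groups fall back to the prior shape
    m_tot = t["mm"] + t["mi"] + t["md"]
    i_tot = t["im"] + t["ii"]
    d_tot = t["dm"] + t["dd"]
    with np.errstate(invalid="ignore", divide="ignore"):
        for key, tot in (
            ("mm", m_tot), ("mi", m_tot), ("md", m_tot),
            ("im", i_tot), ("ii", i_tot),
            ("dm", d_tot), ("dd", d_tot),
        ):
            t[key] = np.where(tot > 0, t[key] / np.where(tot > 0, tot, 1.0), 0.0)
    # zero-count fallbacks (possible only at w == 0): deterministic M->M / I->M / D->M
    for k in range(L + 1):
        if m_tot[k] == 0:
            t["mm"][k] = 1.0
        if i_tot[k] == 0:
            t["im"][k] = 1.0
        if k >= 1 and d_tot[k] == 0:
            t["dm"][k] = 1.0
    t["dm"][0] = 0.0
    t["dd"][0] = 0.0

    return ProfileHmm(
        name=name,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=t,
        background=bg,
        metadata={
            "n_seed_rows": aln.n_rows,
            "pseudocount_weight": w,
            "gap_threshold": gap_threshold,
            "match_columns": "".join("M" if f else "I" for f in match_columns),
        },
    )


def sample_sequence(
    hmm: ProfileHmm,
    seed: int | np.random.Generator,
    seq_id: str = "sample",
) -> tuple[ProteinSequence, list[tuple[str, int]]]:
    """Draw one sequence (and its state path) from the generative model.

    Deterministic for a given integer seed. The returned path is the list of
    (state, node) pairs visited between Begin and End, states in {M, I, D}.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = hmm.transitions
    L = hmm.length
    letters: list[str] = []
    path: list[tuple[str, int]] = []
    state, node = "M", 0  # Begin behaves like M0; a *->M move past node L is End
    while True:
        if state == "M":
            moves = [("M", node + 1), ("I", node), ("D", node + 1)]
            probs = [t["mm"][node], t["mi"][node], t["md"][node]]
        elif state == "I":
            moves = [("M", node + 1), ("I", node)]
            probs = [t["im"][node], t["ii"][node]]
        else:
            moves = [("M", node + 1), ("D", node + 1)]
            probs = [t["dm"][node], t["dd"][node]]
        probs = np.asarray(probs, dtype=float)
        state, node = moves[rng.choice(len(moves), p=probs / probs.sum())]
        if state in ("M", "D") and node > L:
            break  # reached End
        path.append((state, node))
        if state == "M":
            letters.append(AMINO_ACIDS[rng.choice(N_AA, p=hmm.match_emissions[node - 1])])
        elif state == "I":
            letters.append(AMINO_ACIDS[rng.choice(N_AA, p=hmm.insert_emissions[node])])
    # an all-delete path emits nothing; fall back to the node-1 consensus letter
    if not letters:
        letters = [AMINO_ACIDS[int(hmm.match_emissions[0].argmax())]]
        path = [("M", 1)]
    return ProteinSequence(seq_id, "".join(letters)), path
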