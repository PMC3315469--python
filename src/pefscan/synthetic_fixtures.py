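"""Seeded synthetic inputs with ground truth for every pipeline stage.

Real EF-hand panels are trained on curated calpain accessions; nothing in
this package requires those downloads. Instead, this module generates
labeled stand-ins:

* seed alignments for motif models (a conserved consensus with point
  substitutions, mimicking a ~10-protein family alignment sliced down to a
  single ~29-residue EF-hand motif);
* query sequences with motifs *planted* by sampling from the models
  themselves, separated by background spacers, with exact spans recorded;
* family alignments with triad knockouts planted at known rows;
* pure background (null) sequence sets.

All generators are pure functions of (parameters, seed): the same seed
reproduces byte-identical FASTA/Stockholm output and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._alphabet import AMINO_ACIDS, N_AA, uniform_background, validate_background
from .ef_counter import MotifPanel
from .hmm_core import ProfileHmm, build_profile, sample_sequence
from .search_stats import GumbelParams, calibrate
from .seqio import Msa, ProteinSequence
from .triad_screen import TriadSpec

EF_MOTIF_LENGTH = 29  # canonical EF-hand helix-loop-helix span
SEED_ROWS_DEFAULT = 10  # mirrors a ten-protein training family

#: the six calcium-coordinating loop positions of a canonical EF-hand
#: (loop residues 1, 3, 5, 7, 9, 12 of the 12-residue loop spanning
#: positions 10-21 of the 29-residue helix-loop-helix motif), 1-based
EF_ANCHOR_POSITIONS = (10, 12, 14, 16, 18, 21)
ANCHOR_CONSERVATION_DEFAULT = 0.92
COLUMN_ALPHA_DEFAULT = 0.25  # Dirichlet concentration for non-anchor columns


@dataclass
class FixtureTruth:
    """Ground truth for one generated sequence set."""

    records: list[dict] = field(default_factory=list)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _random_consensus(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, N_AA, size=length))


def _column_profiles(
    length: int,
    anchor_positions: tuple[int, ...],
    anchor_conservation: float,
    alpha: float,
    anchor_alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Position-specific emission profiles for a synthetic motif family.

    Anchor columns (e.g. the calcium-coordinating loop residues of an
    EF-hand) get one dominant letter at ``anchor_conservation`` with a
    Dirichlet spread over the rest; all other columns are full Dirichlet
    draws, so conservation varies column to column the way it does in real
    motif alignments.
    """
    profiles = np.empty((length, N_AA))
    for j in range(length):
        if (j + 1) in anchor_positions:
            p = rng.dirichlet(np.full(N_AA, anchor_alpha))
            consensus_idx = int(rng.integers(N_AA))
            p = (1.0 - anchor_conservation) * p
            p[consensus_idx] += anchor_conservation
        else:
            p = rng.dirichlet(np.full(N_AA, alpha))
        profiles[j] = p
    return profiles


def make_seed_alignment(
    length: int = EF_MOTIF_LENGTH,
    n_rows: int = SEED_ROWS_DEFAULT,
    seed: int = 0,
    name_prefix: str = "seed",
    anchor_positions: tuple[int, ...] | None = None,
    anchor_conservation: float = ANCHOR_CONSERVATION_DEFAULT,
    alpha: float = COLUMN_ALPHA_DEFAULT,
    anchor_alpha: float = 0.3,
) -> Msa:
    """An ungapped family alignment with position-specific residue profiles.

    By default the anchors sit at the six calcium-coordinating positions of
    a canonical EF-hand loop (for the default 29-column motif); other
    columns vary in conservation via Dirichlet-drawn profiles.
    """
    rng = np.random.default_rng(seed)
    if anchor_positions is None:
        anchor_positions = (
            EF_ANCHOR_POSITIONS if length == EF_MOTIF_LENGTH else ()
        )
    profiles = _column_profiles(
        length, anchor_positions, anchor_conservation, alpha, anchor_alpha, rng
    )
    rows, ids = [], []
    for r in range(n_rows):
        chars = [
            AMINO_ACIDS[rng.choice(N_AA, p=profiles[j])] for j in range(length)
        ]
        ids.append(f"{name_prefix}_{r + 1}")
        rows.append("".join(chars))
    msa = Msa(ids=ids, rows=rows)
    msa.metadata["consensus"] = "".join(
        AMINO_ACIDS[i] for i in profiles.argmax(axis=1)
    )
    return msa


def build_motif_panel(
    seed: int = 0,
    motif_length: int = EF_MOTIF_LENGTH,
    n_rows: int = SEED_ROWS_DEFAULT,
    evalue_cutoff: float = 0.01,
    n_calibration: int = 4000,
    null_length: int = 400,
) -> MotifPanel:
    """Build and calibrate a five-model EF-hand panel from seeded alignments."""
    models: list[ProfileHmm] = []
    calibs: list[GumbelParams] = []
    for i in range(5):
        aln = make_seed_alignment(
            length=motif_length,
            n_rows=n_rows,
            seed=seed * 17 + i,
            name_prefix=f"ef{i + 1}",
        )
        model = build_profile(aln, name=f"EF-{i + 1}")
        models.append(model)
        calibs.append(
            calibrate(
                model,
                n_samples=n_calibration,
                null_length=null_length,
                seed=seed * 31 + i,
            )
        )
    return MotifPanel(models=models, calibrations=calibs, evalue_cutoff=evalue_cutoff)


def _background_run(length: int, rng: np.random.Generator, bg: np.ndarray) -> str:
    if length <= 0:
        return ""
    return "".join(AMINO_ACIDS[i] for i in rng.choice(N_AA, size=length, p=bg))


def make_motif_fixture(
    panel: MotifPanel,
    n_sequences: int,
    count_law: dict[int, float] | int | None = None,
    spacer_law: tuple[int, int] = (10, 40),
    flank_law: tuple[int, int] = (50, 150),
    seed: int = 0,
    background: np.ndarray | None = None,
    id_prefix: str = "fix",
) -> tuple[list[ProteinSequence], FixtureTruth]:
    """Sequences with k motifs planted in model order (k drawn per sequence).

    ``count_law`` may be a dict {count: probability} over 0..5, a fixed
    integer, or None for uniform on 0..5. Motif instances are sampled from
    the corresponding panel model (realistic variability, not consensus
    planting); truth records the exact planted spans and motif indices.
    """
    rng = np.random.default_rng(seed)
    bg = uniform_background() if background is None else validate_background(background)
    if count_law is None:
        counts_domain, probs = list(range(6)), np.full(6, 1 / 6)
    elif isinstance(count_law, int):
        counts_domain, probs = [count_law], np.array([1.0])
    else:
        counts_domain = sorted(count_law)
        probs = np.array([count_law[c] for c in counts_domain], dtype=float)
        probs /= probs.sum()
    seqs: list[ProteinSequence] = []
    truth = FixtureTruth(
        seed=seed,
        params={
            "n_sequences": n_sequences,
            "spacer_law": spacer_law,
            "flank_law": flank_law,
        },
    )
    for s in range(n_sequences):
        k = int(np.asarray(counts_domain)[rng.choice(len(counts_domain), p=probs)])
        sid = f"{id_prefix}_{s + 1}"
        parts = [_background_run(rng.integers(*flank_law, endpoint=True), rng, bg)]
        spans = []
        pos = len(parts[0])
        for m in range(k):
            if m > 0:
                spacer = int(rng.integers(*spacer_law, endpoint=True))
                parts.append(_background_run(spacer, rng, bg))
                pos += spacer
            motif_seq, _ = sample_sequence(panel.models[m], rng)
            parts.append(motif_seq.residues)
            spans.append((m + 1, pos + 1, pos + len(motif_seq.residues)))
            pos += len(motif_seq.residues)
        parts.append(_background_run(rng.integers(*flank_law, endpoint=True), rng, bg))
        residues = "".join(parts)
        seqs.append(ProteinSequence(sid, residues))
        truth.records.append(
            {
                "id": sid,
                "planted_count": k,
                "length": len(residues),
                "spans": tuple(spans),
            }
        )
    return seqs, truth


def make_triad_fixture(
    consensus: str | None = None,
    n: int = 50,
    knockout_fraction: float = 0.14,
    spec: TriadSpec | None = None,
    seed: int = 0,
    substitution_rate: float = 0.05,
    gap_rate: float = 0.02,
    consensus_length: int = 120,
    triad_positions: tuple[int, int, int] = (30, 60, 90),
    knockout_residues: tuple[str, ...] | None = None,
) -> tuple[Msa, TriadSpec, FixtureTruth]:
    """A family alignment with triad knockouts planted at known rows.

    The first row is the (unmutated) reference carrying the required triad
    letters at ``spec.positions``. The remaining rows are mutated copies:
    substitutions away from triad columns at ``substitution_rate``, gaps at
    ``gap_rate``; a ``knockout_fraction`` subset additionally receives a
    disabling substitution at one to three triad columns. Truth lists the
    knockout ids and which triad labels were hit.
    """
    rng = np.random.default_rng(seed)
    if spec is None:
        spec = TriadSpec(ref_id="ref", positions=triad_positions)
    if consensus is None:
        chars = list(_random_consensus(consensus_length, rng))
        for pos, req in zip(spec.positions, spec.required):
            chars[pos - 1] = req
        consensus = "".join(chars)
    else:
        for pos, req in zip(spec.positions, spec.required):
            if consensus[pos - 1] != req:
                raise ValueError("consensus must carry the required triad letters")
    triad_cols = {p - 1 for p in spec.positions}
    n_knockout = int(round(knockout_fraction * (n - 1)))
    members = [f"fam_{i + 1}" for i in range(n - 1)]
    knockout_ids = set(rng.choice(members, size=n_knockout, replace=False).tolist())
    ids, rows = [spec.ref_id], [consensus]
    truth = FixtureTruth(seed=seed, params={"n": n, "knockout_fraction": knockout_fraction})
    truth.records.append({"id": spec.ref_id, "knocked_out": (), "is_knockout": False})
    for mid in members:
        chars = []
        for j, ch in enumerate(consensus):
            if j in triad_cols:
                chars.append(ch)  # knockouts handled below, explicitly
            elif rng.random() < gap_rate:
                chars.append("-")
            elif rng.random() < substitution_rate:
                chars.append(AMINO_ACIDS[rng.integers(0, N_AA)])
            else:
                chars.append(ch)
        hit_labels: tuple[str, ...] = ()
        if mid in knockout_ids:
            if knockout_residues is not None:
                which = sorted("CHN".index(r) for r in knockout_residues)
            else:
                n_hit = int(rng.integers(1, 4))
                which = sorted(rng.choice(3, size=n_hit, replace=False).tolist())
            hit_labels = tuple("CHN"[w] for w in which)
            for w in which:
                col = spec.positions[w] - 1
                req = spec.required[w]
                alternatives = [aa for aa in AMINO_ACIDS if aa != req]
                chars[col] = alternatives[rng.integers(0, len(alternatives))]
        ids.append(mid)
        rows.append("".join(chars))
        truth.records.append(
            {"id": mid, "knocked_out": hit_labels, "is_knockout": bool(hit_labels)}
        )
    return Msa(ids=ids, rows=rows), spec, truth


def make_null_set(
    background: np.ndarray | None = None,
    n: int = 100,
    length: int = 400,
    seed: int = 0,
    id_prefix: str = "null",
) -> list[ProteinSequence]:
    """i.i.d. background sequences (the true-negative set)."""
    bg = uniform_background() if background is None else validate_background(background)
    rng = np.random.default_rng(seed)
    return [
        ProteinSequence(f"{id_prefix}_{i + 1}", _background_run(length, rng, bg))
        for i in range(n)
    ]


def build_dii_fixture_model(
    seed: int = 0,
    length: int = 90,
    triad_nodes: tuple[int, int, int] = (25, 50, 75),
    n_rows: int = SEED_ROWS_DEFAULT,
) -> tuple[ProfileHmm, str, tuple[int, int, int]]:
    """A synthetic stand-in for a calpain catalytic-domain (DII) profile.

    Scaled down from the ~300-residue domain to keep scans fast. The triad
    nodes are built as perfectly conserved C/H/N columns (as they are in
    active calpains); other columns carry Dirichlet-drawn profiles. Returns
    (model, consensus, triad_nodes); the consensus carries the intact triad.
    """
    rng = np.random.default_rng(seed)
    profiles = _column_profiles(
        length, (), 1.0, COLUMN_ALPHA_DEFAULT, 0.3, rng
    )
    for node, req in zip(triad_nodes, ("C", "H", "N")):
        profiles[node - 1] = 0.0
        profiles[node - 1][AMINO_ACIDS.index(req)] = 1.0
    rows, ids = [], []
    for r in range(n_rows):
        ids.append(f"dii_{r + 1}")
        rows.append(
            "".join(AMINO_ACIDS[rng.choice(N_AA, p=profiles[j])] for j in range(length))
        )
    model = build_profile(Msa(ids=ids, rows=rows), name="DII")
    consensus = "".join(AMINO_ACIDS[i] for i in profiles.argmax(axis=1))
    return model, consensus, triad_nodes
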