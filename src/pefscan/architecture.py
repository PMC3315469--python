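"""Domain-architecture classification of calpain-like proteins.

Combines three axes of evidence into one label per query:

* **catalytic domain** — does a calibrated profile HMM of the calpain
  catalytic domain (DII) hit the query at the E-value cutoff?
* **triad integrity** — are the catalytic Cys/His/Asn present? Read from the
  query residues that the best DII hit's Viterbi path aligns to the three
  designated triad match nodes. If any triad node is deleted in the path or
  lies outside the matched node range, the status is *unknown* — absence of
  evidence is not evidence of loss.
* **PEF** — does the EF-hand panel call a penta-EF-hand domain?

Label table (pure function of the three axes):

==============  ============  =====  ======================
catalytic hit   triad         PEF    label
==============  ============  =====  ======================
no              any           any    not-calpain
yes             missing       any    calpain-like-inactive
yes             intact        yes    typical-calpain
yes             intact        no     atypical-calpain
yes             unknown       any    atypical-calpain (warning flag set)
==============  ============  =====  ======================

A protein whose triad is demonstrably broken is called inactive even when it
carries a PEF domain (the pseudo-enzyme case); an unknown triad is never
grounds for an inactive call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .ef_counter import MotifCountResult, MotifPanel, call_pef, count_ef_hands
from .hmm_core import ProfileHmm
from .search_stats import GumbelParams, Hit, scan
from .seqio import ProteinSequence

TriadStatus = Literal["intact", "missing", "unknown"]
Label = Literal[
    "typical-calpain", "atypical-calpain", "calpain-like-inactive", "not-calpain"
]


@dataclass(frozen=True)
class TriadNodes:
    """The three DII match-node indices carrying the catalytic triad."""

    nodes: tuple[int, int, int]
    required: tuple[str, str, str] = ("C", "H", "N")

    def __post_init__(self) -> None:
        if not (0 < self.nodes[0] < self.nodes[1] < self.nodes[2]):
            raise ValueError("triad nodes must be strictly increasing")


@dataclass
class ArchitectureCall:
    """Classification of one query protein."""

    query_id: str
    has_catalytic_domain: bool
    triad_status: TriadStatus
    triad_residues: tuple[str, str, str] | None
    pef: bool
    ef_count: int
    label: Label
    best_dii_evalue: float | None
    triad_warning: bool = False
    dii_hits: list[Hit] = field(default_factory=list)
    motif_result: Optional[MotifCountResult] = None

    def __post_init__(self) -> None:
        # the label invariants are structural; fail loudly if ever violated
        if (self.label == "not-calpain") != (not self.has_catalytic_domain):
            raise ValueError("not-calpain iff no catalytic-domain hit")
        if self.label == "typical-calpain" and not (self.pef and self.has_catalytic_domain):
            raise ValueError("typical-calpain requires a catalytic domain and a PEF")
        if self.label == "calpain-like-inactive" and not (
            self.has_catalytic_domain and self.triad_status == "missing"
        ):
            raise ValueError("calpain-like-inactive requires a broken triad")


def assign_label(
    has_catalytic_domain: bool, triad_status: TriadStatus, pef: bool
) -> tuple[Label, bool]:
    """The label table; returns (label, triad_warning)."""
    if not has_catalytic_domain:
        return "not-calpain", False
    if triad_status == "missing":
        return "calpain-like-inactive", False
    if triad_status == "unknown":
        return "atypical-calpain", True
    return ("typical-calpain" if pef else "atypical-calpain"), False


def read_triad_from_hit(hit: Hit, query: ProteinSequence, nodes: TriadNodes):
    """Query residues aligned to the triad match nodes of a DII hit.

    Returns (status, residues): status is ``unknown`` when any node is
    deleted in the path or outside the hit's matched node range, otherwise
    ``intact``/``missing`` by strict letter comparison.
    """
    node_to_residue: dict[int, str] = {}
    deleted: set[int] = set()
    qpos = hit.q_start
    for state, node in hit.path:
        if state == "M":
            node_to_residue[node] = query.residues[qpos - 1]
            qpos += 1
        elif state == "I":
            qpos += 1
        else:
            deleted.add(node)
    observed = []
    status: TriadStatus = "intact"
    for node, req in zip(nodes.nodes, nodes.required):
        if node in node_to_residue:
            observed.append(node_to_residue[node])
        else:
            observed.append("-")
            status = "unknown"
    if status == "unknown":
        return "unknown", tuple(observed)
    if any(obs != req for obs, req in zip(observed, nodes.required)):
        return "missing", tuple(observed)
    return "intact", tuple(observed)


def classify(
    query: ProteinSequence,
    dii_model: ProfileHmm,
    dii_calibration: GumbelParams,
    panel: MotifPanel,
    triad_nodes: TriadNodes,
    evalue_cutoff: float = 0.01,
    n_targets: int = 1,
    pef_window: int = 400,
    pef_require_order: bool = True,
    downstream_only: bool = False,
) -> ArchitectureCall:
    """Classify one protein as typical / atypical / inactive / not-calpain.

    The PEF search covers the whole sequence by default;
    ``downstream_only`` restricts it to the region after the DII hit
    (the penta-EF-hand domain is C-terminal in typical calpains, but
    truncated or rearranged queries may place it elsewhere).
    """
    dii_hits = scan(
        dii_model, query, dii_calibration,
        evalue_cutoff=evalue_cutoff, n_targets=n_targets,
    )
    has_dii = len(dii_hits) > 0
    triad_status: TriadStatus = "unknown"
    triad_residues = None
    best_evalue = None
    if has_dii:
        best = min(dii_hits, key=lambda h: h.evalue)
        best_evalue = best.evalue
        triad_status, triad_residues = read_triad_from_hit(best, query, triad_nodes)

    region = query
    offset = 0
    if downstream_only and has_dii:
        best = min(dii_hits, key=lambda h: h.evalue)
        offset = best.q_end
        if offset < len(query.residues):
            region = ProteinSequence(query.id, query.residues[offset:])
        else:
            region = None
    if region is not None:
        motif_result = call_pef(
            count_ef_hands(region, panel, n_targets=n_targets),
            panel,
            window=pef_window,
            require_order=pef_require_order,
        )
        pef = motif_result.pef_called
        ef_count = motif_result.ef_count
    else:
        motif_result, pef, ef_count = None, False, 0

    label, warning = assign_label(has_dii, triad_status, pef)
    return ArchitectureCall(
        query_id=query.id,
        has_catalytic_domain=has_dii,
        triad_status=triad_status,
        triad_residues=triad_residues,
        pef=pef,
        ef_count=ef_count,
        label=label,
        best_dii_evalue=best_evalue,
        triad_warning=warning,
        dii_hits=dii_hits,
        motif_result=motif_result,
    )
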