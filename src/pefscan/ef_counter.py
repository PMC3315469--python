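"""EF-hand motif counting and penta-EF-hand (PEF) domain calling.

A :class:`MotifPanel` bundles five calibrated profile HMMs, one per EF-hand
motif position within a PEF domain (EF-1 .. EF-5). Counting a query scans
each model independently and then reduces the union of passing hits to a
non-overlapping set, so a query region can satisfy at most one motif model —
single pooled EF-hand models tend to merge adjacent motifs and undercount,
which is exactly what the per-motif panel is designed to avoid.

A PEF domain is called when at least five accepted hits fall within a
400-residue window and (by default) their motif indices run in non-decreasing
order along the query, reflecting the conserved EF-1..EF-5 arrangement.
"""

from __future__ import annotations

import dataclasses
import io
import json
import os
from dataclasses import dataclass

import pandas as pd

from .hmm_core import ProfileHmm
from .search_stats import CalibrationError, GumbelParams, Hit, scan
from .seqio import ProteinSequence

PEF_WINDOW_DEFAULT = 400
EVALUE_CUTOFF_DEFAULT = 0.01


@dataclass
class MotifPanel:
    """Exactly five calibrated per-motif models, ordered EF-1..EF-5."""

    models: list[ProfileHmm]
    calibrations: list[GumbelParams]
    evalue_cutoff: float = EVALUE_CUTOFF_DEFAULT

    def __post_init__(self) -> None:
        if len(self.models) != 5:
            raise ValueError("a motif panel holds exactly five models")
        names = [m.name for m in self.models]
        if len(set(names)) != 5:
            raise ValueError("panel model names must be unique")
        if len(self.calibrations) != 5 or any(c is None for c in self.calibrations):
            raise CalibrationError("calibration required for all five panel models")

    def model_index(self, model_name: str) -> int:
        """1-based motif index of a model name."""
        for i, m in enumerate(self.models, start=1):
            if m.name == model_name:
                return i
        raise KeyError(model_name)


@dataclass
class MotifCountResult:
    """Per-query EF-hand tally and PEF verdict."""

    query_id: str
    per_model_hits: dict[str, list[Hit]]
    accepted: list[Hit]
    ef_count: int
    pef_called: bool = False
    pef_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.ef_count != len(self.accepted):
            raise ValueError("ef_count must equal the number of accepted hits")
        if self.pef_called and self.ef_count < 5:
            raise ValueError("a PEF call requires at least five accepted hits")


def _non_overlapping(hits: list[Hit]) -> list[Hit]:
    """Greedy selection on ascending E-value (ties: higher bits, then leftmost)."""
    chosen: list[Hit] = []
    for hit in sorted(hits, key=lambda h: (h.evalue, -h.score_bits, h.q_start)):
        if all(hit.q_end < c.q_start or hit.q_start > c.q_end for c in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: h.q_start)
    return chosen


def count_ef_hands(
    query: ProteinSequence,
    panel: MotifPanel,
    n_targets: int = 1,
    max_hits_per_model: int = 20,
) -> MotifCountResult:
    """Scan all five motif models and count accepted non-overlapping hits."""
    per_model: dict[str, list[Hit]] = {}
    pooled: list[Hit] = []
    for model, calib in zip(panel.models, panel.calibrations):
        hits = scan(
            model,
            query,
            calib,
            max_hits=max_hits_per_model,
            evalue_cutoff=panel.evalue_cutoff,
            n_targets=n_targets,
        )
        per_model[model.name] = hits
        pooled.extend(hits)
    accepted = _non_overlapping(pooled)
    return MotifCountResult(
        query_id=query.id,
        per_model_hits=per_model,
        accepted=accepted,
        ef_count=len(accepted),
    )


def call_pef(
    result: MotifCountResult,
    panel: MotifPanel,
    window: int = PEF_WINDOW_DEFAULT,
    require_order: bool = True,
) -> MotifCountResult:
    """Fill the PEF fields of a count result.

    pef_called is true iff some run of >= 5 consecutive accepted hits spans
    at most ``window`` residues and, when ``require_order`` is set, has
    non-decreasing motif indices along the query. ``pef_span`` is the
    envelope of the first qualifying run.
    """
    hits = result.accepted  # already sorted by q_start
    result.pef_called = False
    result.pef_span = None
    n = len(hits)
    for i in range(n):
        for j in range(i + 4, n):
            if hits[j].q_end - hits[i].q_start + 1 > window:
                break
            run = hits[i: j + 1]
            if require_order:
                idx = [panel.model_index(h.model_name) for h in run]
                if any(b < a for a, b in zip(idx, idx[1:])):
                    continue
            result.pef_called = True
            result.pef_span = (run[0].q_start, run[-1].q_end)
            return result
    return result


def count_table(
    queries: list[ProteinSequence],
    panel: MotifPanel,
    window: int = PEF_WINDOW_DEFAULT,
    require_order: bool = True,
    n_targets: int | None = None,
) -> pd.DataFrame:
    """One row per query: id, ef_count, pef_called, per-model best E-values.

    E-values use n_targets = number of queries unless overridden, the
    per-database convention for a fixed search set.
    """
    if n_targets is None:
        n_targets = max(len(queries), 1)
    rows = []
    for query in queries:
        res = call_pef(
            count_ef_hands(query, panel, n_targets=n_targets),
            panel,
            window=window,
            require_order=require_order,
        )
        row: dict = {
            "id": query.id,
            "ef_count": res.ef_count,
            "pef_called": res.pef_called,
        }
        for model in panel.models:
            hits = res.per_model_hits[model.name]
            row[f"best_evalue_{model.name}"] = (
                min(h.evalue for h in hits) if hits else float("nan")
            )
        rows.append(row)
    columns = ["id", "ef_count", "pef_called"] + [
        f"best_evalue_{m.name}" for m in panel.models
    ]
    return pd.DataFrame(rows, columns=columns)


def save_panel(panel: MotifPanel, directory: str) -> None:
    """Write the five models (native text dialect) plus panel.json."""
    from .model_io import write_hmm

    os.makedirs(directory, exist_ok=True)
    meta = {"order": [], "evalue_cutoff": panel.evalue_cutoff, "calibrations": {}}
    for model, calib in zip(panel.models, panel.calibrations):
        with open(os.path.join(directory, f"{model.name}.hmm"), "wt") as fh:
            fh.write(write_hmm(model))
        meta["order"].append(model.name)
        meta["calibrations"][model.name] = dataclasses.asdict(calib)
    with open(os.path.join(directory, "panel.json"), "wt") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_panel(directory: str) -> MotifPanel:
    """Load a panel directory written by :func:`save_panel`."""
    from .model_io import read_hmm

    with open(os.path.join(directory, "panel.json"), "rt") as fh:
        meta = json.load(fh)
    models, calibs = [], []
    for name in meta["order"]:
        models.append(read_hmm(os.path.join(directory, f"{name}.hmm")))
        calibs.append(GumbelParams(**meta["calibrations"][name]))
    return MotifPanel(
        models=models,
        calibrations=calibs,
        evalue_cutoff=meta.get("evalue_cutoff", EVALUE_CUTOFF_DEFAULT),
    )


def format_count_table(table: pd.DataFrame) -> str:
    """Deterministic TSV rendering (E-values with 6 significant digits)."""
    out = table.copy()
    for col in out.columns:
        if col.startswith("best_evalue_"):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
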