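"""Plain-text serialization of profile HMMs.

The native dialect mirrors the HMMER3 ASCII layout (header, background
composition, one block of emission/transition lines per node) but stores
probabilities as negative natural logs exactly like HMMER3 does, with ``*``
for probability zero. :func:`read_hmm` reads the native dialect and, on a
best-effort basis, HMMER3/f ASCII files (match/insert emissions and the seven
state transitions; Plan7 special states are ignored).
"""

from __future__ import annotations

from typing import IO, Union

import numpy as np

from ._alphabet import AMINO_ACIDS, N_AA, uniform_background
from .hmm_core import TRANSITION_KEYS, ProfileHmm

MAGIC = "PEFSCAN-HMM 1.0"


def _fmt(p: float) -> str:
    if p <= 0.0:
        return "*"
    return f"{-np.log(p):.5f}"


def _parse(tok: str) -> float:
    if tok == "*":
        return 0.0
    return float(np.exp(-float(tok)))


def write_hmm(hmm: ProfileHmm) -> str:
    """Serialize a model to the native text dialect."""
    L = hmm.length
    lines = [
        MAGIC,
        f"NAME  {hmm.name}",
        f"LENG  {L}",
        f"ALPH  amino {AMINO_ACIDS}",
        "BG    " + " ".join(_fmt(p) for p in hmm.background),
        "HMM",
    ]
    t = hmm.transitions
    for k in range(L + 1):
        if k > 0:
            lines.append(f"M{k:<5d}" + " ".join(_fmt(p) for p in hmm.match_emissions[k - 1]))
        lines.append(f"I{k:<5d}" + " ".join(_fmt(p) for p in hmm.insert_emissions[k]))
        lines.append(
            f"T{k:<5d}" + " ".join(_fmt(t[key][k]) for key in TRANSITION_KEYS)
        )
    lines.append("//")
    return "\n".join(lines) + "\n"


def _renormalize(match_em: np.ndarray, insert_em: np.ndarray, trans: dict) -> None:
    """Repair the small rounding error introduced by 5-digit text storage."""
    match_em /= match_em.sum(axis=1, keepdims=True)
    insert_em /= insert_em.sum(axis=1, keepdims=True)
    m = trans["mm"] + trans["mi"] + trans["md"]
    i = trans["im"] + trans["ii"]
    d = trans["dm"] + trans["dd"]
    for key in ("mm", "mi", "md"):
        trans[key] /= m
    for key in ("im", "ii"):
        trans[key] /= i
    ok = d > 0
    for key in ("dm", "dd"):
        trans[key] = np.where(ok, trans[key] / np.where(ok, d, 1.0), 0.0)


def _read_native(lines: list[str]) -> ProfileHmm:
    header: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].strip() != "HMM":
        key, _, value = lines[i].partition(" ")
        header[key.strip()] = value.strip()
        i += 1
    L = int(header["LENG"])
    bg = np.array([_parse(tok) for tok in header["BG"].split()])
    bg /= bg.sum()  # repair 5-digit text rounding
    name = header.get("NAME", "profile")
    match_em = np.zeros((L, N_AA))
    insert_em = np.zeros((L + 1, N_AA))
    trans = {key: np.zeros(L + 1) for key in TRANSITION_KEYS}
    for line in lines[i + 1:]:
        line = line.strip()
        if not line or line == "//":
            continue
        tag, *toks = line.split()
        kind, k = tag[0], int(tag[1:])
        vals = [_parse(tok) for tok in toks]
        if kind == "M":
            match_em[k - 1] = vals
        elif kind == "I":
            insert_em[k] = vals
        elif kind == "T":
            for key, v in zip(TRANSITION_KEYS, vals):
                trans[key][k] = v
    _renormalize(match_em, insert_em, trans)
    return ProfileHmm(
        name=name,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        background=bg,
        metadata={"source": "native"},
    )


def _read_hmmer3(lines: list[str]) -> ProfileHmm:
    """Best-effort reader for HMMER3/f ASCII (single amino model)."""
    name, L = "profile", None
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("NAME"):
            name = line.split(maxsplit=1)[1]
        elif line.startswith("LENG"):
            L = int(line.split()[1])
        elif line.startswith("ALPH"):
            if line.split()[1].lower() != "amino":
                raise ValueError("only amino-alphabet HMMER3 models are supported")
        elif line.startswith("HMM "):
            break
        i += 1
    if L is None:
        raise ValueError("HMMER3 input lacks a LENG line")
    i += 2  # skip the two HMM header lines (residue order / transition order)
    bg = uniform_background()
    match_em = np.zeros((L, N_AA))
    insert_em = np.zeros((L + 1, N_AA))
    trans = {key: np.zeros(L + 1) for key in TRANSITION_KEYS}
    body = [ln.strip() for ln in lines[i:] if ln.strip() and ln.strip() != "//"]
    j = 0
    if body and body[0].startswith("COMPO"):
        bg = np.array([_parse(tok) for tok in body[0].split()[1:21]])
        bg = bg / bg.sum()
        j = 1
    # node 0: insert emission line + transition line
    insert_em[0] = [_parse(tok) for tok in body[j].split()[:N_AA]]
    for key, tok in zip(TRANSITION_KEYS, body[j + 1].split()[:7]):
        trans[key][0] = _parse(tok)
    j += 2
    for k in range(1, L + 1):
        toks = body[j].split()
        if int(toks[0]) != k:
            raise ValueError(f"unexpected node index in HMMER3 body: {toks[0]}")
        match_em[k - 1] = [_parse(t) for t in toks[1: 1 + N_AA]]
        insert_em[k] = [_parse(t) for t in body[j + 1].split()[:N_AA]]
        for key, tok in zip(TRANSITION_KEYS, body[j + 2].split()[:7]):
            trans[key][k] = _parse(tok)
        j += 3
    # HMMER stores M->E implicitly at node L; renormalize each group
    for k in range(L + 1):
        m = trans["mm"][k] + trans["mi"][k] + trans["md"][k]
        if m > 0:
            for key in ("mm", "mi", "md"):
                trans[key][k] /= m
        isum = trans["im"][k] + trans["ii"][k]
        if isum > 0:
            trans["im"][k] /= isum
            trans["ii"][k] /= isum
        d = trans["dm"][k] + trans["dd"][k]
        if k >= 1 and d > 0:
            trans["dm"][k] /= d
            trans["dd"][k] /= d
    trans["md"][L] = 0.0
    trans["dd"][L] = 0.0
    _renormalize(match_em, insert_em, trans)
    return ProfileHmm(
        name=name,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        background=bg,
        metadata={"source": "hmmer3"},
    )


def read_hmm(source: Union[str, IO[str]]) -> ProfileHmm:
    """Read a profile HMM from text (native dialect or HMMER3/f ASCII)."""
    if isinstance(source, str) and "\n" not in source:
        with open(source, "rt") as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    lines = text.splitlines()
    if not lines:
        raise ValueError("empty model input")
    if lines[0].startswith(MAGIC.split()[0]):
        return _read_native(lines)
    if lines[0].startswith("HMMER3"):
        return _read_hmmer3(lines)
    raise ValueError("unrecognized model format")
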