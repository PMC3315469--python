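"""Independent brute-force oracles for profile-HMM scoring.

Path probabilities are enumerated explicitly (in linear odds space — models
and sequences are tiny), entirely independent of the dynamic-programming
implementation they are checked against.
"""

from __future__ import annotations

import numpy as np

from pefscan._alphabet import AMINO_ACIDS, N_AA
from pefscan.hmm_core import ProfileHmm


def _odds(hmm: ProfileHmm):
    me = hmm.match_emissions / hmm.background
    ie = hmm.insert_emissions / hmm.background
    return me, ie


def enumerate_global(hmm: ProfileHmm, x: list[int]) -> list[float]:
    """Odds-ratio of every Begin-to-End path emitting exactly ``x``."""
    L = hmm.length
    t = hmm.transitions
    me, ie = _odds(hmm)
    n = len(x)
    out: list[float] = []

    def go(state: str, node: int, pos: int, p: float) -> None:
        if p == 0.0:
            return
        if node == L:
            p_end = p * t[state.lower() + "m"][L]
            if pos == n and p_end > 0:
                out.append(p_end)
        if state == "M":
            moves = [
                ("M", node + 1, t["mm"][node]),
                ("I", node, t["mi"][node]),
                ("D", node + 1, t["md"][node]),
            ]
        elif state == "I":
            moves = [("M", node + 1, t["im"][node]), ("I", node, t["ii"][node])]
        else:
            moves = [("M", node + 1, t["dm"][node]), ("D", node + 1, t["dd"][node])]
        for s2, n2, tp in moves:
            if tp == 0.0 or n2 > L:
                continue
            if s2 == "M":
                if pos < n:
                    go(s2, n2, pos + 1, p * tp * me[n2 - 1, x[pos]])
            elif s2 == "I":
                if pos < n:
                    go(s2, n2, pos + 1, p * tp * ie[n2, x[pos]])
            else:
                go(s2, n2, pos, p * tp)

    go("M", 0, 0, 1.0)
    return out


def enumerate_local(hmm: ProfileHmm, x: list[int]) -> list[float]:
    """Odds-ratio of every local hit: entry 1/L into any match node, any
    start position, free exit from any match state; flanks contribute 1."""
    L = hmm.length
    t = hmm.transitions
    me, ie = _odds(hmm)
    n = len(x)
    out: list[float] = []

    def go(state: str, node: int, pos: int, p: float) -> None:
        if p == 0.0:
            return
        if state == "M":
            out.append(p)  # exit here, free
        if state == "M":
            moves = [
                ("M", node + 1, t["mm"][node]),
                ("I", node, t["mi"][node]),
                ("D", node + 1, t["md"][node]),
            ]
        elif state == "I":
            moves = [("M", node + 1, t["im"][node]), ("I", node, t["ii"][node])]
        else:
            moves = [("M", node + 1, t["dm"][node]), ("D", node + 1, t["dd"][node])]
        for s2, n2, tp in moves:
            if tp == 0.0 or n2 > L:
                continue
            if s2 == "M" or s2 == "I":
                if pos < n:
                    em = me[n2 - 1, x[pos]] if s2 == "M" else ie[n2, x[pos]]
                    go(s2, n2, pos + 1, p * tp * em)
            else:
                go(s2, n2, pos, p * tp)

    for i0 in range(n):
        for a in range(1, L + 1):
            go("M", a, i0 + 1, (1.0 / L) * me[a - 1, x[i0]])
    return out


def oracle_scores(hmm: ProfileHmm, residues: str, mode: str) -> tuple[float, float]:
    """(viterbi_bits, forward_bits) by exhaustive enumeration."""
    x = [AMINO_ACIDS.index(c) for c in residues]
    paths = enumerate_global(hmm, x) if mode == "global" else enumerate_local(hmm, x)
    if not paths:
        return -np.inf, -np.inf
    arr = np.array(paths)
    return float(np.log2(arr.max())), float(np.log2(arr.sum()))


def random_hmm(L: int, seed: int, alphabet_size: int = N_AA) -> ProfileHmm:
    """A random valid profile HMM (emissions concentrated on the first
    ``alphabet_size`` letters so that small-alphabet enumeration stays fast)."""
    rng = np.random.default_rng(seed)
    me = np.zeros((L, N_AA))
    me[:, :alphabet_size] = rng.dirichlet(np.ones(alphabet_size), size=L)
    ie = np.zeros((L + 1, N_AA))
    ie[:, :alphabet_size] = rng.dirichlet(np.ones(alphabet_size), size=L + 1)
    t = {}
    m = rng.dirichlet(np.ones(3), size=L + 1).T
    t["mm"], t["mi"], t["md"] = m[0].copy(), m[1].copy(), m[2].copy()
    i = rng.dirichlet(np.ones(2), size=L + 1).T
    t["im"], t["ii"] = i[0].copy(), i[1].copy()
    d = rng.dirichlet(np.ones(2), size=L + 1).T
    t["dm"], t["dd"] = d[0].copy(), d[1].copy()
    # node-L edge: no transitions into node L+1 delete/match-skip
    t["mm"][L] += t["md"][L]
    t["md"][L] = 0.0
    t["dm"][L] += t["dd"][L]
    t["dd"][L] = 0.0
    t["dm"][0], t["dd"][0] = 0.0, 0.0
    bg = np.full(N_AA, 1.0 / N_AA)
    return ProfileHmm(
        name=f"rand{L}_{seed}",
        match_emissions=me,
        insert_emissions=ie,
        transitions=t,
        background=bg,
    )
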