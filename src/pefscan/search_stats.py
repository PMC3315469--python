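"""Scoring, hit extraction and E-value calibration for profile HMMs.

Scores are log-odds — log of (path probability / background probability of
the emitted residues) — computed in natural-log space and reported in bits.
Two alignment modes are supported:

* ``global``: the whole query must be generated Begin-to-End.
* ``local``: a hit enters at any match state (uniform entry mass 1/L),
  exits after any match state at no cost, and the query residues outside
  the hit are scored as background (log-odds 0). This is the mode used for
  motif scanning.

Statistical significance follows the extreme-value convention used
throughout profile-HMM searching: local Viterbi scores of i.i.d. background
sequences are fitted with a Gumbel law, P(S > s) = 1 - exp(-exp(-lam*(s-mu))),
and E-value = n_targets * P. Ambiguity residues (X/B/Z/U/O) are scored as the
background distribution, i.e. log-odds zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from ._alphabet import encode, validate_background
from .hmm_core import ProfileHmm, sample_sequence
from .seqio import ProteinSequence

NEG_INF = -np.inf

Mode = Literal["global", "local"]

LN2 = float(np.log(2.0))


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GumbelParams:
    """Gumbel (type-I extreme value) fit of the null local-Viterbi scores.

    ``mu`` is the location and ``lam`` the scale (lambda) in bit units;
    P-value(S) = 1 - exp(-exp(-lam * (S - mu))).
    """

    mu: float
    lam: float
    n_calibration: int
    seed: int
    null_length: int = 400

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.n_calibration < 100:
            raise ValueError("calibration needs at least 100 samples")

    def pvalue(self, score_bits: float) -> float:
        # survival function of the Gumbel law, stable for extreme scores
        x = -self.lam * (score_bits - self.mu)
        return float(-np.expm1(-np.exp(np.clip(x, None, 700.0))))

    def evalue(self, score_bits: float, n_targets: int = 1) -> float:
        return n_targets * self.pvalue(score_bits)


@dataclass(frozen=True)
class Hit:
    """One local match of a model on a query."""

    model_name: str
    query_id: str
    q_start: int  # 1-based inclusive
    q_end: int
    m_start: int  # matched model node range
    m_end: int
    score_bits: float
    evalue: float
    path: tuple[tuple[str, int], ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.m_start > self.m_end:
            raise ValueError("hit coordinates must be non-decreasing")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    def path_rle(self) -> str:
        """Compact M/I/D run-length encoding of the state path."""
        out = []
        prev, run = None, 0
        for state, _ in self.path:
            if state == prev:
                run += 1
            else:
                if prev is not None:
                    out.append(f"{run}{prev}")
                prev, run = state, 1
        if prev is not None:
            out.append(f"{run}{prev}")
        return "".join(out)


def _log_scores(hmm: ProfileHmm):
    """Log-odds emission scores (L x 21 / (L+1) x 21) and log transitions."""
    with np.errstate(divide="ignore"):
        lbg = np.log(hmm.background)
        msc = np.log(hmm.match_emissions) - lbg  # (L, 20)
        isc = np.log(hmm.insert_emissions) - lbg  # (L+1, 20)
        lt = {k: np.log(v) for k, v in hmm.transitions.items()}
    # ambiguity column: score as background (log-odds 0)
    msc = np.concatenate([msc, np.zeros((msc.shape[0], 1))], axis=1)
    isc = np.concatenate([isc, np.zeros((isc.shape[0], 1))], axis=1)
    return msc, isc, lt


def _encode_masked(seq: ProteinSequence, mask: np.ndarray | None) -> np.ndarray:
    x = encode(seq.residues)
    if mask is not None:
        x = x.copy()
        x[np.asarray(mask, dtype=bool)] = -1  # sentinel: unmatchable
    return x


def _viterbi_global(hmm: ProfileHmm, x: np.ndarray):
    """Global Viterbi in nats with traceback; returns (score, path)."""
    msc, isc, lt = _log_scores(hmm)
    L, n = hmm.length, x.size
    VM = np.full((n + 1, L + 1), NEG_INF)
    VI = np.full((n + 1, L + 1), NEG_INF)
    VD = np.full((n + 1, L + 1), NEG_INF)
    # choice codes: 1 from M, 2 from I, 3 from D (0 = unreachable)
    CM = np.zeros((n + 1, L + 1), dtype=np.uint8)
    CI = np.zeros((n + 1, L + 1), dtype=np.uint8)
    CD = np.zeros((n + 1, L + 1), dtype=np.uint8)
    VM[0, 0] = 0.0  # Begin
    for k in range(1, L + 1):
        cand = (VM[0, k - 1] + lt["md"][k - 1], VD[0, k - 1] + lt["dd"][k - 1])
        best = int(np.argmax((cand[0], cand[1])))
        VD[0, k] = cand[best]
        CD[0, k] = (1, 3)[best]
    for i in range(1, n + 1):
        xi = x[i - 1]
        e_m = msc[:, xi] if xi >= 0 else np.full(L, NEG_INF)
        e_i = isc[:, xi] if xi >= 0 else np.full(L + 1, NEG_INF)
        for k in range(0, L + 1):
            if k >= 1:
                cand = (
                    VM[i - 1, k - 1] + lt["mm"][k - 1],
                    VI[i - 1, k - 1] + lt["im"][k - 1],
                    VD[i - 1, k - 1] + lt["dm"][k - 1],
                )
                best = int(np.argmax(cand))
                # tie-break: prefer M, then D, then I
                if cand[2] == cand[best] and best == 1:
                    best = 2
                if cand[0] == cand[best]:
                    best = 0
                VM[i, k] = e_m[k - 1] + cand[best]
                CM[i, k] = best + 1
            cand_i = (VM[i - 1, k] + lt["mi"][k], VI[i - 1, k] + lt["ii"][k])
            bi = 0 if cand_i[0] >= cand_i[1] else 1
            VI[i, k] = e_i[k] + cand_i[bi]
            CI[i, k] = (1, 2)[bi]
            if k >= 1:
                cand_d = (VM[i, k - 1] + lt["md"][k - 1], VD[i, k - 1] + lt["dd"][k - 1])
                bd = 0 if cand_d[0] >= cand_d[1] else 1
                VD[i, k] = cand_d[bd]
                CD[i, k] = (1, 3)[bd]
    ends = (
        VM[n, L] + lt["mm"][L],
        VI[n, L] + lt["im"][L],
        VD[n, L] + lt["dm"][L],
    )
    order = (0, 2, 1)  # prefer M, then D, then I on ties
    best_state = max(order, key=lambda s: (ends[s], -order.index(s)))
    score = ends[best_state]
    if not np.isfinite(score):
        return NEG_INF, []
    # traceback
    path: list[tuple[str, int]] = []
    state = "MID"[best_state]
    i, k = n, L
    while not (state == "M" and k == 0):
        path.append((state, k))
        if state == "M":
            code = CM[i, k]
            i, k = i - 1, k - 1
        elif state == "I":
            code = CI[i, k]
            i = i - 1
        else:
            code = CD[i, k]
            k = k - 1
        state = {1: "M", 2: "I", 3: "D"}[int(code)]
    path.reverse()
    return float(score), path


def _forward_global(hmm: ProfileHmm, x: np.ndarray) -> float:
    msc, isc, lt = _log_scores(hmm)
    L, n = hmm.length, x.size
    FM = np.full((n + 1, L + 1), NEG_INF)
    FI = np.full((n + 1, L + 1), NEG_INF)
    FD = np.full((n + 1, L + 1), NEG_INF)
    FM[0, 0] = 0.0
    for k in range(1, L + 1):
        FD[0, k] = np.logaddexp(FM[0, k - 1] + lt["md"][k - 1], FD[0, k - 1] + lt["dd"][k - 1])
    for i in range(1, n + 1):
        xi = x[i - 1]
        e_m = msc[:, xi] if xi >= 0 else np.full(L, NEG_INF)
        e_i = isc[:, xi] if xi >= 0 else np.full(L + 1, NEG_INF)
        for k in range(0, L + 1):
            if k >= 1:
                FM[i, k] = e_m[k - 1] + np.logaddexp.reduce(
                    [
                        FM[i - 1, k - 1] + lt["mm"][k - 1],
                        FI[i - 1, k - 1] + lt["im"][k - 1],
                        FD[i - 1, k - 1] + lt["dm"][k - 1],
                    ]
                )
            FI[i, k] = e_i[k] + np.logaddexp(
                FM[i - 1, k] + lt["mi"][k], FI[i - 1, k] + lt["ii"][k]
            )
            if k >= 1:
                FD[i, k] = np.logaddexp(
                    FM[i, k - 1] + lt["md"][k - 1], FD[i, k - 1] + lt["dd"][k - 1]
                )
    return float(
        np.logaddexp.reduce(
            [FM[n, L] + lt["mm"][L], FI[n, L] + lt["im"][L], FD[n, L] + lt["dm"][L]]
        )
    )


def _local_dp(hmm: ProfileHmm, x: np.ndarray, viterbi: bool):
    """Shared local DP. Returns (VM, VI, VD[, choice arrays]) in nats.

    Entry: fresh start into any match node with mass 1/L; exit from any
    match cell at no cost. Row i corresponds to query position i (1-based).
    """
    msc, isc, lt = _log_scores(hmm)
    L, n = hmm.length, x.size
    entry = -np.log(L)
    VM = np.full((n + 1, L + 1), NEG_INF)
    VI = np.full((n + 1, L + 1), NEG_INF)
    VD = np.full((n + 1, L + 1), NEG_INF)
    if viterbi:
        CM = np.zeros((n + 1, L + 1), dtype=np.uint8)  # 0 fresh, 1 M, 2 I, 3 D
        CI = np.zeros((n + 1, L + 1), dtype=np.uint8)
        CD = np.zeros((n + 1, L + 1), dtype=np.uint8)
    t_mm, t_mi, t_md = lt["mm"], lt["mi"], lt["md"]
    t_im, t_ii = lt["im"], lt["ii"]
    t_dm, t_dd = lt["dm"], lt["dd"]
    ks = np.arange(1, L + 1)
    for i in range(1, n + 1):
        xi = x[i - 1]
        if xi < 0:  # masked position: no state may emit it
            continue
        e_m = msc[:, xi]
        e_i = isc[:, xi]
        # M states (vectorized over k)
        from_m = VM[i - 1, :-1] + t_mm[:-1]
        from_i = VI[i - 1, :-1] + t_im[:-1]
        from_d = VD[i - 1, :-1] + t_dm[:-1]
        if viterbi:
            stacked = np.stack([np.full(L, entry), from_m, from_i, from_d])
            # prefer fresh < ... ties: M over D over I -> evaluate in order M,D,I
            order = np.array([1, 3, 0, 2])  # M, D, fresh, I by descending preference
            vals = stacked[order]
            am = np.argmax(vals, axis=0)  # first max wins -> preference order
            VM[i, 1:] = e_m + vals[am, np.arange(L)]
            CM[i, 1:] = order[am]
        else:
            VM[i, 1:] = e_m + np.logaddexp.reduce(
                np.stack([np.full(L, entry), from_m, from_i, from_d]), axis=0
            )
        # I states (vectorized over k); I cannot start or end a hit
        fi_m = VM[i - 1, :] + t_mi
        fi_i = VI[i - 1, :] + t_ii
        if viterbi:
            take_m = fi_m >= fi_i
            VI[i, :] = e_i + np.where(take_m, fi_m, fi_i)
            CI[i, :] = np.where(take_m, 1, 2)
        else:
            VI[i, :] = e_i + np.logaddexp(fi_m, fi_i)
        # D states (sequential in k within row i)
        for k in ks:
            cd_m = VM[i, k - 1] + t_md[k - 1]
            cd_d = VD[i, k - 1] + t_dd[k - 1]
            if viterbi:
                if cd_m >= cd_d:
                    VD[i, k] = cd_m
                    CD[i, k] = 1
                else:
                    VD[i, k] = cd_d
                    CD[i, k] = 3
            else:
                VD[i, k] = np.logaddexp(cd_m, cd_d)
    if viterbi:
        return VM, VI, VD, CM, CI, CD
    return VM, VI, VD


def _viterbi_local(hmm: ProfileHmm, x: np.ndarray):
    """Full local Viterbi: (score_nats, path, q_start, q_end)."""
    VM, VI, VD, CM, CI, CD = _local_dp(hmm, x, viterbi=True)
    best = np.unravel_index(np.argmax(VM), VM.shape)
    score = VM[best]
    if not np.isfinite(score):
        return NEG_INF, [], 0, 0
    i, k = int(best[0]), int(best[1])
    q_end = i
    path: list[tuple[str, int]] = []
    state = "M"
    while True:
        path.append((state, k))
        if state == "M":
            code = CM[i, k]
            i, k = i - 1, k - 1
        elif state == "I":
            code = CI[i, k]
            i -= 1
        else:
            code = CD[i, k]
            k -= 1
        if state == "M" and code == 0:
            break
        state = {1: "M", 2: "I", 3: "D"}[int(code)]
    path.reverse()
    q_start = i + 1
    return float(score), path, q_start, q_end


def viterbi(
    hmm: ProfileHmm,
    seq: ProteinSequence,
    mode: Mode = "local",
    mask: np.ndarray | None = None,
) -> tuple[float, list[tuple[str, int]]]:
    """Best-path log-odds score in bits and the corresponding state path.

    In local mode the path covers only the matched query span; the returned
    path is a list of (state, node) pairs. Re-scoring the path with
    :func:`score_path` reproduces the score.
    """
    x = _encode_masked(seq, mask)
    if mode == "global":
        score, path = _viterbi_global(hmm, x)
        return score / LN2, path
    score, path, _, _ = _viterbi_local(hmm, x)
    return score / LN2, path


def forward(
    hmm: ProfileHmm,
    seq: ProteinSequence,
    mode: Mode = "local",
    mask: np.ndarray | None = None,
) -> float:
    """All-paths log-odds score in bits (log-sum-exp over paths)."""
    x = _encode_masked(seq, mask)
    if mode == "global":
        return _forward_global(hmm, x) / LN2
    FM, _, _ = _local_dp(hmm, x, viterbi=False)
    total = float(np.logaddexp.reduce(FM[1:, 1:], axis=None))
    return total / LN2


def score_path(
    hmm: ProfileHmm,
    seq: ProteinSequence,
    path: list[tuple[str, int]],
    mode: Mode = "local",
    q_start: int = 1,
) -> float:
    """Log-odds score in bits of an explicit state path (self-consistency check).

    For local mode, ``q_start`` is the 1-based query position of the first
    emitted residue and the path must start and end on match states; the
    1/L entry mass is included, exit is free.
    """
    msc, isc, lt = _log_scores(hmm)
    x = encode(seq.residues)
    total = 0.0
    pos = q_start - 1
    if mode == "local":
        if not path or path[0][0] != "M" or path[-1][0] != "M":
            raise ValueError("a local path must start and end on match states")
        total += -np.log(hmm.length)
        prev = None
    else:
        prev = ("M", 0)  # Begin
    for state, node in path:
        if prev is not None:
            total += lt[prev[0].lower() + state.lower()][prev[1]]
        if state == "M":
            total += msc[node - 1, x[pos]]
            pos += 1
        elif state == "I":
            total += isc[node, x[pos]]
            pos += 1
        prev = (state, node)
    if mode == "global":
        total += lt[prev[0].lower() + "m"][prev[1]]
    return float(total) / LN2


def local_viterbi_scores_batch(hmm: ProfileHmm, X: np.ndarray) -> np.ndarray:
    """Local Viterbi bit scores for a batch of equal-length encoded sequences.

    ``X`` is (n_seqs, seq_len) of residue indices (ambiguity = 20). Used for
    calibration, where thousands of null sequences share one length.
    """
    msc, isc, lt = _log_scores(hmm)
    N, n = X.shape
    L = hmm.length
    entry = -np.log(L)
    VM = np.full((N, L + 1), NEG_INF)
    VI = np.full((N, L + 1), NEG_INF)
    VD = np.full((N, L + 1), NEG_INF)
    best = np.full(N, NEG_INF)
    t_mm, t_md = lt["mm"][:-1], lt["md"]
    t_im, t_dm = lt["im"][:-1], lt["dm"][:-1]
    t_mi, t_ii = lt["mi"], lt["ii"]
    t_dd = lt["dd"]
    for i in range(n):
        xi = X[:, i]
        e_m = msc[:, xi].T  # (N, L)
        e_i = isc[:, xi].T  # (N, L+1)
        newM = np.empty((N, L + 1))
        newM[:, 0] = NEG_INF
        cand = np.maximum(VM[:, :-1] + t_mm, VI[:, :-1] + t_im)
        cand = np.maximum(cand, VD[:, :-1] + t_dm)
        cand = np.maximum(cand, entry)
        newM[:, 1:] = e_m + cand
        newI = e_i + np.maximum(VM + t_mi, VI + t_ii)
        newD = np.full((N, L + 1), NEG_INF)
        for k in range(1, L + 1):
            newD[:, k] = np.maximum(
                newM[:, k - 1] + t_md[k - 1], newD[:, k - 1] + t_dd[k - 1]
            )
        VM, VI, VD = newM, newI, newD
        best = np.maximum(best, VM[:, 1:].max(axis=1))
    return best / LN2


def calibrate(
    hmm: ProfileHmm,
    background: np.ndarray | None = None,
    n_samples: int = 4000,
    null_length: int = 400,
    seed: int = 0,
) -> GumbelParams:
    """Fit a Gumbel law to local Viterbi scores of i.i.d. null sequences.

    Null sequences of fixed length are drawn from ``background`` (defaults
    to the model's own background); the maximum-likelihood Gumbel fit gives
    the (mu, lam) pair used for P-values and E-values. The default sample
    count keeps the fitted-parameter error (which scales as 1/sqrt(n)) well
    below the extreme-value approximation error itself.
    """
    if n_samples < 100:
        raise CalibrationError("calibration needs at least 100 samples")
    bg = hmm.background if background is None else validate_background(background)
    rng = np.random.default_rng(seed)
    X = rng.choice(20, size=(n_samples, null_length), p=bg)
    scores = local_viterbi_scores_batch(hmm, X)
    if np.ptp(scores) < 1e-12 or not np.all(np.isfinite(scores)):
        raise CalibrationError("calibration failed: degenerate null scores")
    loc, scale = stats.gumbel_r.fit(scores)
    return GumbelParams(
        mu=float(loc),
        lam=float(1.0 / scale),
        n_calibration=n_samples,
        seed=seed,
        null_length=null_length,
    )


def scan(
    hmm: ProfileHmm,
    seq: ProteinSequence,
    calib: GumbelParams | None,
    max_hits: int = 20,
    evalue_cutoff: float = 0.01,
    n_targets: int = 1,
) -> list[Hit]:
    """Iterative best-hit extraction with query masking.

    Finds the best local Viterbi hit; if its E-value passes the cutoff the
    hit is recorded and its query span masked (those residues become
    unmatchable), and the search repeats. Returned hits are non-overlapping
    and sorted by query start.
    """
    if calib is None:
        raise CalibrationError("calibration required before scanning")
    mask = np.zeros(len(seq.residues), dtype=bool)
    hits: list[Hit] = []
    while len(hits) < max_hits:
        x = _encode_masked(seq, mask)
        score_nats, path, q_start, q_end = _viterbi_local(hmm, x)
        if not path or not np.isfinite(score_nats):
            break
        score = score_nats / LN2
        evalue = calib.evalue(score, n_targets=n_targets)
        if evalue > evalue_cutoff:
            break
        hits.append(
            Hit(
                model_name=hmm.name,
                query_id=seq.id,
                q_start=q_start,
                q_end=q_end,
                m_start=path[0][1],
                m_end=path[-1][1],
                score_bits=score,
                evalue=evalue,
                path=tuple(path),
            )
        )
        mask[q_start - 1: q_end] = True
    hits.sort(key=lambda h: h.q_start)
    return hits
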