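import itertools

import numpy as np
import pytest
from oracle import oracle_scores, random_hmm

from pefscan._alphabet import AMINO_ACIDS, uniform_background
from pefscan.hmm_core import ProfileHmm, build_profile, sample_sequence
from pefscan.search_stats import (
    CalibrationError,
    GumbelParams,
    calibrate,
    forward,
    scan,
    score_path,
    viterbi,
)
from pefscan.seqio import ProteinSequence
from pefscan.synthetic_fixtures import make_seed_alignment


def _single_path_model():
    """L=1 model that can only emit one 'C' through B->M1->E."""
    me = np.zeros((1, 20))
    me[0, AMINO_ACIDS.index("C")] = 1.0
    t = {
        "mm": np.ones(2), "mi": np.zeros(2), "md": np.zeros(2),
        "im": np.ones(2), "ii": np.zeros(2),
        "dm": np.array([0.0, 1.0]), "dd": np.zeros(2),
    }
    return ProfileHmm(
        name="one",
        match_emissions=me,
        insert_emissions=np.tile(uniform_background(), (2, 1)),
        transitions=t,
        background=uniform_background(),
    )


class TestViterbiForward:
    def test_single_path_model_scores_log_odds_of_c(self):
        hmm = _single_path_model()
        seq = ProteinSequence("q", "C")
        score, path = viterbi(hmm, seq, "global")
        assert path == [("M", 1)]
        assert score == pytest.approx(np.log2(1.0 / 0.05))
        assert forward(hmm, seq, "global") == pytest.approx(score)

    @pytest.mark.parametrize("mode", ["global", "local"])
    @pytest.mark.parametrize("seed", range(6))
    def test_dp_agrees_with_exhaustive_enumeration(self, mode, seed):
        hmm = random_hmm(1 + seed % 3, seed, alphabet_size=3)
        for n in (1, 2, 3):
            for tup in itertools.product("ACD", repeat=n):
                seq = ProteinSequence("q", "".join(tup))
                ov, of = oracle_scores(hmm, seq.residues, mode)
                dv, _ = viterbi(hmm, seq, mode)
                df = forward(hmm, seq, mode)
                assert dv == pytest.approx(ov, rel=1e-9, abs=1e-9)
                assert df == pytest.approx(of, rel=1e-9, abs=1e-9)

    def test_forward_never_below_viterbi(self):
        rng = np.random.default_rng(12)
        for trial in range(100):
            hmm = random_hmm(1 + trial % 5, 1000 + trial)
            n = int(rng.integers(1, 30))
            seq = ProteinSequence(
                "q", "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))
            )
            for mode in ("global", "local"):
                v, _ = viterbi(hmm, seq, mode)
                f = forward(hmm, seq, mode)
                assert f >= v - 1e-9

    def test_returned_path_rescores_to_the_same_bits(self):
        rng = np.random.default_rng(5)
        hmm = build_profile(make_seed_alignment(seed=13))
        for _ in range(10):
            seq, _ = sample_sequence(hmm, rng)
            v, path = viterbi(hmm, seq, "local")
            # local path of the full-motif sample starts at the argmax cell
            from pefscan.search_stats import _encode_masked, _viterbi_local

            s_nats, p2, q_start, _ = _viterbi_local(hmm, _encode_masked(seq, None))
            assert p2 == path
            assert score_path(hmm, seq, path, "local", q_start=q_start) == pytest.approx(
                v, abs=1e-9
            )
            vg, pg = viterbi(hmm, seq, "global")
            assert score_path(hmm, seq, pg, "global") == pytest.approx(vg, abs=1e-9)

    def test_ambiguity_residues_score_as_background(self):
        hmm = _single_path_model()
        seq = ProteinSequence("q", "X")
        score, _ = viterbi(hmm, seq, "global")
        # transition chain is free; emission log-odds of X is zero
        assert score == pytest.approx(0.0, abs=1e-9)


class TestGumbel:
    def test_pvalue_at_mu_is_one_minus_exp_minus_one(self):
        g = GumbelParams(mu=5.0, lam=0.7, n_calibration=1000, seed=0)
        assert g.pvalue(5.0) == pytest.approx(1 - np.exp(-1))

    def test_evalue_monotone_decreasing_in_score(self):
        g = GumbelParams(mu=5.0, lam=0.7, n_calibration=1000, seed=0)
        # stay away from the saturated P ~= 1 regime where float precision
        # makes successive P-values exactly equal
        scores = np.linspace(2, 45, 200)
        evs = [g.evalue(s, n_targets=100) for s in scores]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_calibration_requires_enough_samples(self):
        hmm = build_profile(make_seed_alignment(seed=1))
        with pytest.raises(CalibrationError):
            calibrate(hmm, n_samples=50, seed=0)

    def test_calibration_is_deterministic(self):
        hmm = build_profile(make_seed_alignment(seed=1))
        c1 = calibrate(hmm, n_samples=200, seed=4)
        c2 = calibrate(hmm, n_samples=200, seed=4)
        assert c1 == c2
        assert c1.lam > 0


@pytest.fixture(scope="module")
def motif_model():
    hmm = build_profile(make_seed_alignment(seed=21), name="EF-t")
    calib = calibrate(hmm, n_samples=1000, seed=22)
    return hmm, calib


class TestScan:
    def test_scan_requires_calibration(self, motif_model):
        hmm, _ = motif_model
        with pytest.raises(CalibrationError, match="calibration required"):
            scan(hmm, ProteinSequence("q", "ACDEF"), None)

    def test_planted_motif_is_recovered_once(self, motif_model):
        hmm, calib = motif_model
        rng = np.random.default_rng(31)
        found = 0
        for _ in range(40):
            motif, _ = sample_sequence(hmm, rng)
            left = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 100))
            right = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 100))
            seq = ProteinSequence("q", left + motif.residues + right)
            hits = scan(hmm, seq, calib, evalue_cutoff=0.01)
            span = (101, 100 + len(motif.residues))
            if len(hits) == 1 and hits[0].q_start <= span[1] and hits[0].q_end >= span[0]:
                found += 1
        assert found >= 36  # >= 90% of planted trials

    def test_two_planted_copies_give_two_nonoverlapping_hits(self, motif_model):
        hmm, calib = motif_model
        rng = np.random.default_rng(17)
        m1, _ = sample_sequence(hmm, rng)
        m2, _ = sample_sequence(hmm, rng)
        spacer = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 50))
        seq = ProteinSequence("q", m1.residues + spacer + m2.residues)
        hits = scan(hmm, seq, calib, evalue_cutoff=0.01)
        assert len(hits) == 2
        assert hits[0].q_end < hits[1].q_start

    def test_hits_never_overlap(self, motif_model):
        hmm, calib = motif_model
        rng = np.random.default_rng(77)
        for _ in range(10):
            seq = ProteinSequence(
                "q", "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 300))
            )
            hits = scan(hmm, seq, calib, evalue_cutoff=0.5, n_targets=1)
            for a, b in zip(hits, hits[1:]):
                assert a.q_end < b.q_start

    def test_null_hit_rate_matches_cutoff(self, motif_model):
        hmm, calib = motif_model
        rng = np.random.default_rng(55)
        n_null = 300
        n_hit = 0
        from pefscan.search_stats import local_viterbi_scores_batch

        X = rng.integers(0, 20, size=(n_null, 200))
        scores = local_viterbi_scores_batch(hmm, X)
        for s in scores:
            if calib.evalue(float(s)) <= 0.05:
                n_hit += 1
        # expected per-sequence rate ~ 0.05 for these null lengths
        assert n_hit / n_null < 0.15

    def test_sampled_sequences_outscore_background(self, motif_model):
        hmm, _ = motif_model
        rng = np.random.default_rng(9)
        sampled, null = [], []
        for _ in range(200):
            seq, _ = sample_sequence(hmm, rng)
            sampled.append(viterbi(hmm, seq, "local")[0])
            bgseq = ProteinSequence(
                "b", "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, len(seq.residues)))
            )
            null.append(viterbi(hmm, bgseq, "local")[0])
        assert np.mean(sampled) > np.mean(null)
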