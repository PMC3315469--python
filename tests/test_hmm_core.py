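import io

import numpy as np
import pytest

from pefscan._alphabet import AMINO_ACIDS, uniform_background
from pefscan.hmm_core import (
    ProfileHmm,
    assign_match_columns,
    build_profile,
    read_motif_annotation,
    sample_sequence,
    slice_alignment,
)
from pefscan.model_io import read_hmm, write_hmm
from pefscan.seqio import Msa, SeqIoError
from pefscan.synthetic_fixtures import make_seed_alignment


class TestSliceAlignment:
    def test_columns_follow_reference_residues(self):
        aln = Msa(ids=["ref", "other"], rows=["A-CD", "AEC-"])
        sub = slice_alignment(aln, "ref", 2, 3)  # ref residues C, D
        assert sub.rows == ["CD", "C-"]
        assert sub.ids == ["ref", "other"]

    def test_full_span_is_identity_for_ungapped_reference(self):
        aln = Msa(ids=["ref", "o"], rows=["ACDE", "AC-E"])
        sub = slice_alignment(aln, "ref", 1, 4)
        assert sub.rows == aln.rows

    def test_internal_insert_columns_are_kept(self):
        aln = Msa(ids=["ref", "o"], rows=["AC--DE", "ACXYDE"])
        sub = slice_alignment(aln, "ref", 2, 3)  # C..D spans the insert columns
        assert sub.rows[0] == "C--D" and sub.rows[1] == "CXYD"

    def test_unknown_reference(self):
        aln = Msa(ids=["a"], rows=["ACD"])
        with pytest.raises(SeqIoError, match="unknown reference"):
            slice_alignment(aln, "zz", 1, 2)

    def test_coordinates_beyond_reference(self):
        aln = Msa(ids=["a", "b"], rows=["AC-D", "ACED"])
        with pytest.raises(SeqIoError, match="coordinate beyond reference length"):
            slice_alignment(aln, "a", 2, 9)

    def test_all_gap_rows_are_flagged_not_dropped(self):
        aln = Msa(ids=["ref", "gappy"], rows=["ACD", "A--"])
        sub = slice_alignment(aln, "ref", 2, 3)
        assert sub.ids == ["ref", "gappy"]
        assert sub.metadata["all_gap_ids"] == ["gappy"]

    def test_five_motif_slices_from_annotation(self):
        aln = make_seed_alignment(length=180, seed=5, anchor_positions=())
        tsv = "ref_id\tmotif_index\tstart\tend\n" + "".join(
            f"seed_1\t{i + 1}\t{1 + 30 * i}\t{29 + 30 * i}\n" for i in range(5)
        )
        annot = read_motif_annotation(io.StringIO(tsv))
        subs = [
            slice_alignment(aln, annot.ref_id, start, end)
            for _, start, end in annot.motifs
        ]
        assert len(subs) == 5
        assert all(s.n_cols == 29 for s in subs)


class TestAssignMatchColumns:
    def test_gap_free_alignment_is_all_match(self):
        aln = Msa(ids=["a", "b"], rows=["ACD", "ACD"])
        assert assign_match_columns(aln) == [True, True, True]

    def test_threshold_is_strict(self):
        # gap fractions 0.0, 0.6, 0.4 against threshold 0.5
        aln = Msa(
            ids=list("abcde"),
            rows=["A-C", "A-C", "A--", "AC-", "ACC"],
        )
        assert assign_match_columns(aln, 0.5) == [True, False, True]

    def test_all_gap_column_is_never_match(self):
        aln = Msa(ids=["a", "b"], rows=["A-C", "A-C"])
        assert assign_match_columns(aln) == [True, False, True]

    def test_no_match_columns_is_an_error(self):
        aln = Msa(ids=["a", "b"], rows=["A-", "-A"])
        with pytest.raises(ValueError, match="no match columns"):
            assign_match_columns(aln, gap_threshold=0.4)


class TestBuildProfile:
    def test_zero_pseudocount_recovers_column_frequencies(self):
        aln = Msa(ids=["a", "b", "c"], rows=["ACD"] * 3)
        hmm = build_profile(aln, pseudocount_weight=0.0)
        assert hmm.length == 3
        assert hmm.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(1.0)
        assert hmm.match_emissions[1, AMINO_ACIDS.index("C")] == pytest.approx(1.0)

    def test_background_pseudocount_arithmetic(self):
        # counts 3 on 'A' plus weight*bg: (3 + 0.05) / (3 + 1)
        aln = Msa(ids=["a", "b", "c"], rows=["ACD"] * 3)
        hmm = build_profile(
            aln, pseudocount_weight=1.0, background=uniform_background()
        )
        assert hmm.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(0.7625)

    def test_mixed_column_frequencies_at_zero_pseudocount(self):
        aln = Msa(ids=list("abcd"), rows=["AC", "AC", "AD", "CD"])
        hmm = build_profile(aln, pseudocount_weight=0.0)
        a, c, d = (AMINO_ACIDS.index(x) for x in "ACD")
        assert hmm.match_emissions[0, a] == pytest.approx(0.75)
        assert hmm.match_emissions[0, c] == pytest.approx(0.25)
        assert hmm.match_emissions[1, c] == pytest.approx(0.5)
        assert hmm.match_emissions[1, d] == pytest.approx(0.5)

    def test_gaps_become_delete_transitions(self):
        aln = Msa(ids=["a", "b", "c"], rows=["ACD", "ACD", "A-D"])
        hmm = build_profile(aln, pseudocount_weight=0.0)
        # row c passes M1 -> D2 -> M3
        assert hmm.transitions["md"][1] == pytest.approx(1 / 3)
        assert hmm.transitions["dm"][2] == pytest.approx(1.0)

    def test_insert_column_residues_become_inserts(self):
        aln = Msa(ids=["a", "b", "c"], rows=["A-D", "A-D", "AXD"])
        match = [True, False, True]
        hmm = build_profile(aln, match_columns=match, pseudocount_weight=0.0)
        assert hmm.length == 2
        assert hmm.transitions["mi"][1] == pytest.approx(1 / 3)

    def test_row_order_does_not_matter(self):
        aln = make_seed_alignment(seed=11)
        perm = Msa(ids=list(reversed(aln.ids)), rows=list(reversed(aln.rows)))
        h1, h2 = build_profile(aln), build_profile(perm)
        np.testing.assert_allclose(h1.match_emissions, h2.match_emissions)
        for key in h1.transitions:
            np.testing.assert_allclose(h1.transitions[key], h2.transitions[key])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_built_models_always_satisfy_invariants(self, seed):
        aln = make_seed_alignment(seed=seed)
        hmm = build_profile(aln)
        hmm.validate()  # raises on violation
        assert np.all(hmm.match_emissions >= 0)


class TestSampleSequence:
    def _deterministic_model(self):
        L = 4
        me = np.zeros((L, 20))
        for k, aa in enumerate("ACDE"):
            me[k, AMINO_ACIDS.index(aa)] = 1.0
        t = {
            "mm": np.ones(L + 1), "mi": np.zeros(L + 1), "md": np.zeros(L + 1),
            "im": np.ones(L + 1), "ii": np.zeros(L + 1),
            "dm": np.concatenate([[0.0], np.ones(L)]), "dd": np.zeros(L + 1),
        }
        return ProfileHmm(
            name="det",
            match_emissions=me,
            insert_emissions=np.tile(uniform_background(), (L + 1, 1)),
            transitions=t,
            background=uniform_background(),
        )

    def test_deterministic_model_emits_consensus(self):
        seq, path = sample_sequence(self._deterministic_model(), seed=0)
        assert seq.residues == "ACDE"
        assert path == [("M", 1), ("M", 2), ("M", 3), ("M", 4)]

    def test_same_seed_same_output(self):
        hmm = build_profile(make_seed_alignment(seed=2))
        s1, p1 = sample_sequence(hmm, seed=99)
        s2, p2 = sample_sequence(hmm, seed=99)
        assert s1.residues == s2.residues and p1 == p2

    def test_lengths_grow_only_through_inserts(self):
        hmm = build_profile(make_seed_alignment(seed=4))
        # forbid deletions entirely
        t = {k: v.copy() for k, v in hmm.transitions.items()}
        t["mm"] = t["mm"] + t["md"]
        t["md"] = np.zeros_like(t["md"])
        nodel = ProfileHmm(
            name="nodel",
            match_emissions=hmm.match_emissions,
            insert_emissions=hmm.insert_emissions,
            transitions=t,
            background=hmm.background,
        )
        rng = np.random.default_rng(8)
        lengths = [len(sample_sequence(nodel, rng)[0].residues) for _ in range(3000)]
        assert min(lengths) >= nodel.length
        assert np.mean(lengths) >= nodel.length

    def test_paths_are_valid_state_sequences(self):
        hmm = build_profile(make_seed_alignment(seed=6))
        rng = np.random.default_rng(3)
        for _ in range(50):
            _, path = sample_sequence(hmm, rng)
            nodes = [n for s, n in path if s in ("M", "D")]
            assert nodes == sorted(nodes)
            # M/D nodes run 1..L; insert states may also sit at node 0 (I0)
            assert all(1 <= n <= hmm.length for s, n in path if s in ("M", "D"))
            assert all(0 <= n <= hmm.length for s, n in path if s == "I")


class TestModelSerialization:
    def test_native_roundtrip(self):
        hmm = build_profile(make_seed_alignment(seed=9), name="EF-x")
        back = read_hmm(write_hmm(hmm))
        assert back.name == "EF-x" and back.length == hmm.length
        np.testing.assert_allclose(
            back.match_emissions, hmm.match_emissions, atol=2e-5
        )
        for key in hmm.transitions:
            np.testing.assert_allclose(
                back.transitions[key], hmm.transitions[key], atol=2e-5
            )

    def test_hmmer3_ascii_is_readable(self, tmp_path):
        # a minimal HMMER3/f file with one node
        text = "\n".join(
            [
                "HMMER3/f [3.4 | Aug 2023]",
                "NAME  mini",
                "LENG  1",
                "ALPH  amino",
                "HMM          A        C        D        E        F        G        H        I        K        L        M        N        P        Q        R        S        T        V        W        Y",
                "            m->m     m->i     m->d     i->m     i->i     d->m     d->d",
                "  COMPO   " + "  ".join(["2.99573"] * 20),
                "          " + "  ".join(["2.99573"] * 20),
                "          0.01005  5.00000  5.00000  0.69315  0.69315  0.00000        *",
                "      1   " + "  ".join(["0.10536"] + ["4.60517"] * 19) + "      1 A - - -",
                "          " + "  ".join(["2.99573"] * 20),
                "          0.01005  5.00000        *  0.69315  0.69315  0.00000        *",
                "//",
            ]
        )
        hmm = read_hmm(text)
        assert hmm.name == "mini" and hmm.length == 1
        assert hmm.match_emissions[0].argmax() == 0  # 'A'
        hmm.validate()
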