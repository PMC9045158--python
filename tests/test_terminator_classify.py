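"""Feature extraction, the Type I-IV cascade, tail logos and mutations."""

import math

import numpy as np
import pytest

from termstoich import (
    TerminatorFeatures,
    call_terminator,
    classify_type,
    extract_features,
    min_hairpin,
    mutate_delete_5arm,
    mutate_pair_unpaired,
    mutate_stem,
    tail_logo_counts,
)
from termstoich.rna_fold import structure_from_pairs
from termstoich.synthetic_data import TYPE_DG_MEAN, gen_terminator
from termstoich.terminator_classify import parse_dot_bracket


def _features(**kw) -> TerminatorFeatures:
    base = dict(
        polyU_run=0, tail_U_count=0, urich_window="", tail_paired=False,
        stem_bp=8, has_unpaired_region=False, unpaired_size=0,
        distal_arm_bp=0, dG=-20.0,
    )
    base.update(kw)
    return TerminatorFeatures(**base)


def _hairpin_with_tail(tail: str):
    seq = "GGGGC" + "AAAA" + "GCCCC" + tail
    st = min_hairpin(seq)
    assert st is not None and st.stem_bp == 5
    return st


class TestExtractFeatures:
    def test_unpaired_poly_u_tail(self):
        st = _hairpin_with_tail("UUUUUUAG")
        f = extract_features(st)
        assert f.polyU_run == 6
        assert f.tail_U_count == 6
        assert f.tail_paired is False
        assert f.urich_window == "UUUUUUAG"

    def test_all_gc_tail_has_no_u(self):
        st = _hairpin_with_tail("GCGCGCG")
        f = extract_features(st)
        assert f.polyU_run == 0 and f.tail_U_count == 0

    def test_window_downstream_of_unpaired_region_is_paired(self):
        """With a 1-nt internal loop the window starts on the 3' arm distal
        to it, so its first bases are paired stem bases (counted by hand)."""
        #     distal(3) gap inner(5)  loop  inner  gap distal  tail
        seq = "GAA" + "A" + "GCGCC" + "AACA" + "GGCGC" + "C" + "UUC" + "UACAG"
        st = min_hairpin(seq)
        f = extract_features(st)
        assert f.has_unpaired_region and f.unpaired_size == 1
        assert f.distal_arm_bp == 3
        assert f.tail_paired is True
        # window = 3' distal strand ("UUC") then tail start: UUCUACAG -> 3 U in first 7
        assert f.urich_window == "UUCUACAG"
        assert f.tail_U_count == 3
        assert f.polyU_run == 2


class TestClassifyCascade:
    @pytest.mark.parametrize(
        "features, expected",
        [
            (_features(polyU_run=8, tail_U_count=7), "I"),
            (_features(polyU_run=5, tail_U_count=5), "I"),   # >=5 consecutive U
            (_features(polyU_run=3, tail_U_count=3), "II"),
            (_features(polyU_run=4, tail_U_count=2), "II"),
            (_features(polyU_run=1, tail_U_count=1), "unclassified"),
            (
                _features(polyU_run=2, tail_U_count=3, has_unpaired_region=True,
                          unpaired_size=1, tail_paired=True, distal_arm_bp=3),
                "III",
            ),
            (
                _features(polyU_run=1, tail_U_count=1, has_unpaired_region=True,
                          unpaired_size=1, tail_paired=True, distal_arm_bp=7),
                "IV",
            ),
            (
                _features(polyU_run=1, tail_U_count=0, has_unpaired_region=True,
                          unpaired_size=2, tail_paired=False, distal_arm_bp=2),
                "IV",  # low U content qualifies even with a short distal arm
            ),
            (
                _features(polyU_run=2, tail_U_count=3, has_unpaired_region=True,
                          unpaired_size=4, tail_paired=True, distal_arm_bp=3),
                "unclassified",  # defect too large for the III/IV rules
            ),
        ],
    )
    def test_cascade(self, features, expected):
        assert classify_type(features) == expected

    def test_classification_is_total(self, rng):
        for _ in range(200):
            f = _features(
                polyU_run=int(rng.integers(0, 9)),
                tail_U_count=int(rng.integers(0, 8)),
                has_unpaired_region=bool(rng.integers(0, 2)),
                unpaired_size=int(rng.integers(0, 4)),
                tail_paired=bool(rng.integers(0, 2)),
                distal_arm_bp=int(rng.integers(0, 9)),
            )
            assert classify_type(f) in {"I", "II", "III", "IV", "unclassified"}


class TestGeneratorRecovery:
    @pytest.mark.parametrize("term_type", ["I", "II", "III", "IV"])
    def test_refolded_generator_terminators_classify_correctly(self, term_type, rng):
        hits = 0
        n = 25
        for _ in range(n):
            tgt = float(np.clip(rng.normal(TYPE_DG_MEAN[term_type], 3.0), -35, -12))
            seq, truth = gen_terminator(term_type, tgt, rng)
            st = min_hairpin(seq)
            assert abs(st.dG - truth["dG"]) < 1e-9
            assert abs(st.dG - tgt) <= 2.0
            hits += call_terminator("x", st).type_label == term_type
        assert hits >= math.ceil(0.95 * n)


class TestTailLogo:
    def test_uniform_u_tails_give_two_bits(self):
        calls = [call_terminator("x", _hairpin_with_tail("UUUUUUU")) for _ in range(5)]
        counts, info = tail_logo_counts(calls)
        assert counts[:, 3].tolist() == [5] * 7  # all U at every position
        assert np.allclose(info, 2.0)

    def test_column_sums_equal_reachable_tails(self):
        calls = [
            call_terminator("a", _hairpin_with_tail("UUAUUAU")),
            call_terminator("b", _hairpin_with_tail("UUA")),  # short window
        ]
        counts, _ = tail_logo_counts(calls)
        assert counts.sum(axis=1).tolist() == [2, 2, 2, 1, 1, 1, 1]

    def test_hand_counted_matrix(self):
        calls = [call_terminator(str(i), _hairpin_with_tail(t))
                 for i, t in enumerate(["UAAAAAA", "UUAAAAA", "AUAAAAA", "CGAAAAA"])]
        counts, info = tail_logo_counts(calls)
        # position 1: U,U,A,C ; position 2: A,U,U,G
        assert counts[0].tolist() == [1, 1, 0, 2]  # A,C,G,U
        assert counts[1].tolist() == [1, 0, 1, 2]
        assert info[2] == pytest.approx(2.0)  # all A at position 3

    def test_random_tails_carry_little_information(self, rng):
        # fixed stem with the tail forced unpaired, so the window is the tail
        stem_pairs = [(0, 13), (1, 12), (2, 11), (3, 10), (4, 9)]
        calls = []
        for _ in range(300):
            tail = "".join(rng.choice(list("ACGU"), size=7))
            st = structure_from_pairs("GGGGCAAAAGCCCC" + tail, stem_pairs, dG=-8.0)
            calls.append(call_terminator("x", st))
        _, info = tail_logo_counts(calls)
        assert np.all(info < 0.15)  # approaches 0 with n


class TestMutations:
    def test_delete_zero_is_identity(self):
        st = _hairpin_with_tail("UUUUUU")
        assert mutate_delete_5arm(st, 0) == st.sequence

    def test_delete_shortens_by_n(self):
        st = _hairpin_with_tail("UUUUUU")
        assert len(mutate_delete_5arm(st, 5)) == len(st.sequence) - 5

    def test_deleting_5arm_of_type_ii_unpairs_tail(self, rng):
        """Removing the 5' bases paired with the 3' U-rich tract abolishes
        the long paired stem on refolding."""
        seq, _ = gen_terminator("II", -20, rng)
        st = min_hairpin(seq)
        mut = min_hairpin(mutate_delete_5arm(st, 5))
        assert mut is None or mut.stem_bp < st.stem_bp

    def test_stem_identity_and_extension(self, rng):
        seq, _ = gen_terminator("II", -18, rng)
        st = min_hairpin(seq)
        assert mutate_stem(st, 0) == st.sequence
        longer = min_hairpin(mutate_stem(st, +2))
        assert longer.dG < st.dG  # two added G-C stacks
        shorter = min_hairpin(mutate_stem(st, -4))
        assert shorter is None or shorter.stem_bp <= st.stem_bp - 2

    @pytest.mark.parametrize("term_type", ["III", "IV"])
    def test_pairing_unpaired_region_lowers_dG(self, term_type, rng):
        for _ in range(5):
            seq, _ = gen_terminator(term_type, -25, rng)
            st = min_hairpin(seq)
            mut = min_hairpin(mutate_pair_unpaired(st))
            assert mut.dG < st.dG
            assert not extract_features(mut).has_unpaired_region

    def test_a_opposite_gap_becomes_au_pair(self):
        """The base opposite an unpaired A is substituted to U."""
        seq = "GAA" + "A" + "GCGCC" + "AACA" + "GGCGC" + "C" + "UUC" + "UACAG"
        st = min_hairpin(seq)
        mut = mutate_pair_unpaired(st)
        # the 1x1 internal loop was A (5' side) opposite C (3' side): C -> U
        i = seq.index("GGCGC") + 5
        assert seq[i] == "C" and mut[i] == "U"
        assert len(mut) == len(seq)

    def test_no_unpaired_region_warns_and_returns_identity(self):
        st = _hairpin_with_tail("UUUUUU")
        with pytest.warns(UserWarning, match="unpaired"):
            assert mutate_pair_unpaired(st) == st.sequence


def test_dot_bracket_round_trip():
    seq = "GGGGCAAAAGCCCCUUUUUU"
    st = min_hairpin(seq)
    assert parse_dot_bracket(st.dot_bracket()) == sorted(st.pairs)
    with pytest.raises(ValueError):
        parse_dot_bracket("(()")
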