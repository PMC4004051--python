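"""Motif parsing, information content, trimming and threshold calibration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimerscan.motifs import (
    Motif,
    MotifParseError,
    calibrate_threshold,
    information_content,
    parse_motifs,
    trim_motif,
    write_transfac,
)

from conftest import prob_motif

TRANSFAC_TEXT = """\
AC M00001
XX
NA testfactor
XX
P0 A C G T
01 60 10 20 10
02 10 70 10 10
03 5 5 85 5
04 25 25 25 25
XX
//
"""

JASPAR_BRACKETED = """\
>MA0001.1 AGL3
A  [ 0  3 79 40 ]
C  [94 75  4  3 ]
G  [ 1  0  3  4 ]
T  [ 2 19 11 50 ]
"""

JASPAR_PLAIN = """\
>MA0002 plainmat
0 3 79 40
94 75 4 3
1 0 3 4
2 19 11 50
"""

MEME_TEXT = """\
MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF m1 FIRST
letter-probability matrix: alength= 4 w= 2 nsites= 20 E= 1e-5
 0.10 0.20 0.30 0.40
 0.70 0.10 0.10 0.10

MOTIF m2
letter-probability matrix: alength= 4 w= 3 nsites= 10 E= 1e-3
 0.25 0.25 0.25 0.25
 1.00 0.00 0.00 0.00
 0.00 0.50 0.50 0.00

MOTIF m3 THIRD
letter-probability matrix: alength= 4 w= 1 nsites= 40 E= 0.5
 0.40 0.30 0.20 0.10
"""

SWISSREGULON_TEXT = """\
//
NA FOXA2.p2
P0 A C G T
1 5 3 2 10
2 0 0 0 20
3 20 0 0 0
//
"""


class TestParsers:
    def test_transfac_counts_preserved(self, tmp_path):
        p = tmp_path / "m.transfac"
        p.write_text(TRANSFAC_TEXT)
        motifs = parse_motifs(str(p), "TRANSFAC")
        assert len(motifs) == 1
        m = motifs[0]
        assert m.id == "M00001" and m.name == "testfactor"
        assert m.length == 4
        np.testing.assert_array_equal(m.counts[:, 0], [60, 10, 20, 10])
        np.testing.assert_array_equal(m.counts[:, 3], [25, 25, 25, 25])

    @pytest.mark.parametrize("text,mid", [(JASPAR_BRACKETED, "MA0001.1"),
                                          (JASPAR_PLAIN, "MA0002")])
    def test_jaspar_identity_parse(self, tmp_path, text, mid):
        p = tmp_path / "m.jaspar"
        p.write_text(text)
        (m,) = parse_motifs(str(p), "JASPAR")
        assert m.id == mid
        expected = np.array([[0, 3, 79, 40], [94, 75, 4, 3],
                             [1, 0, 3, 4], [2, 19, 11, 50]], float)
        np.testing.assert_array_equal(m.counts, expected)

    def test_meme_three_blocks_hand_parse(self, tmp_path):
        # expected probabilities transcribed by hand from the fixture text
        p = tmp_path / "m.meme"
        p.write_text(MEME_TEXT)
        motifs = parse_motifs(str(p), "MEME")
        assert [m.id for m in motifs] == ["m1", "m2", "m3"]
        assert [m.length for m in motifs] == [2, 3, 1]
        m1 = motifs[0]
        # counts = probs * nsites, with pseudocount-free recovery of probs
        np.testing.assert_allclose(m1.counts[:, 0], [2.0, 4.0, 6.0, 8.0])
        m2 = motifs[1]
        np.testing.assert_allclose(m2.counts[:, 1], [10.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(motifs[2].counts[:, 0], [16.0, 12.0, 8.0, 4.0])

    def test_swissregulon_as_count_blocks(self, tmp_path):
        p = tmp_path / "m.swiss"
        p.write_text(SWISSREGULON_TEXT)
        (m,) = parse_motifs(str(p), "SwissRegulon")
        assert m.name == "FOXA2.p2" and m.length == 3
        np.testing.assert_array_equal(m.counts[:, 1], [0, 0, 0, 20])

    def test_malformed_row_names_record(self, tmp_path):
        p = tmp_path / "bad.transfac"
        p.write_text("AC BADREC\nP0 A C G T\n01 1 2 3\n//\n")
        with pytest.raises(MotifParseError, match="BADREC"):
            parse_motifs(str(p), "TRANSFAC")

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        p = tmp_path / "empty.transfac"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert parse_motifs(str(p), "TRANSFAC") == []
        assert any("empty" in r.message for r in caplog.records)

    def test_transfac_round_trip(self, tmp_path, rng):
        motifs = [Motif(f"M{i}", rng.integers(0, 50, size=(4, 5)).astype(float))
                  for i in range(3)]
        out = tmp_path / "rt.transfac"
        write_transfac(motifs, str(out))
        back = parse_motifs(str(out), "TRANSFAC")
        assert [m.id for m in back] == [m.id for m in motifs]
        for a, b in zip(motifs, back):
            np.testing.assert_array_equal(a.counts, b.counts)


class TestInformationContent:
    @pytest.mark.parametrize("col,expected", [
        ((0.25, 0.25, 0.25, 0.25), 0.0),
        ((1.0, 0.0, 0.0, 0.0), 2.0),
        ((0.5, 0.5, 0.0, 0.0), 1.0),
    ])
    def test_closed_forms(self, col, expected):
        m = prob_motif("m", [col], pseudocount=0.0)
        col_ic, total = information_content(m)
        assert col_ic[0] == pytest.approx(expected, abs=1e-12)
        assert total == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_reverse_complement(self, rng):
        m = Motif("m", rng.integers(0, 100, size=(4, 7)).astype(float))
        _, total = information_content(m)
        _, total_rc = information_content(m.reverse_complement())
        assert total == pytest.approx(total_rc, rel=1e-12)

    def test_bounded(self, rng):
        m = Motif("m", rng.integers(0, 100, size=(4, 12)).astype(float))
        col_ic, _ = information_content(m)
        assert np.all(col_ic >= 0) and np.all(col_ic <= 2)


class TestReverseComplement:
    def test_involution(self, rng):
        m = Motif("m", rng.integers(0, 100, size=(4, 9)).astype(float))
        np.testing.assert_array_equal(m.reverse_complement().reverse_complement().counts,
                                      m.counts)

    def test_base_mapping(self):
        m = prob_motif("m", [(1, 0, 0, 0), (0, 1, 0, 0)], pseudocount=0.0)
        rc = m.reverse_complement()
        # AC -> GT read back: first column G, second column T
        np.testing.assert_array_equal(np.argmax(rc.counts, axis=0), [2, 3])


def _column_ic_oracle(probs_col):
    h = -sum(p * math.log2(p) for p in probs_col if p > 0)
    return 2.0 - h


class TestTrimming:
    def test_flank_trim_against_per_column_oracle(self, rng):
        # ten random motifs: trim must drop exactly the flanking columns
        # whose IC (independent closed-form computation) is <= 0.25 bit
        for i in range(10):
            counts = rng.integers(0, 30, size=(4, 8)).astype(float)
            # force uninformative flanks on some motifs
            if i % 2 == 0:
                counts[:, 0] = 10
                counts[:, -1] = 10
            m = Motif(f"m{i}", counts)
            ics = [_column_ic_oracle(m.probs[:, j]) for j in range(m.length)]
            left = 0
            while left < m.length and ics[left] <= 0.25:
                left += 1
            right = 0
            while right < m.length - left and ics[m.length - 1 - right] <= 0.25:
                right += 1
            tv = trim_motif(m)
            if left + right == m.length:
                assert tv.trimmed_length == 0
            else:
                assert (tv.left_offset, tv.right_offset) == (left, right)
                assert tv.trimmed_length == m.length - left - right

    def test_all_uniform_trims_to_zero(self, caplog):
        m = prob_motif("u", [(0.25,) * 4] * 3, pseudocount=0.0)
        with caplog.at_level("WARNING"):
            tv = trim_motif(m)
        assert tv.trimmed_length == 0

    def test_nothing_removable(self):
        m = prob_motif("s", [(1, 0, 0, 0), (0, 1, 0, 0)], pseudocount=0.0)
        tv = trim_motif(m)
        assert (tv.left_offset, tv.right_offset, tv.trimmed_length) == (0, 0, 2)

    def test_interior_low_ic_retained(self):
        m = prob_motif("i", [(1, 0, 0, 0), (0.25,) * 4, (0, 0, 1, 0)],
                       pseudocount=0.0)
        tv = trim_motif(m)
        assert tv.trimmed_length == 3

    def test_idempotent(self, rng):
        counts = rng.integers(0, 30, size=(4, 8)).astype(float)
        counts[:, 0] = 10
        m = Motif("m", counts)
        tv = trim_motif(m)
        if tv.trimmed_length > 0:
            inner = Motif("inner", counts[:, tv.left_offset: m.length - tv.right_offset])
            tv2 = trim_motif(inner)
            assert (tv2.left_offset, tv2.right_offset) == (0, 0)


class TestThresholdCalibration:
    def test_full_sensitivity_gives_minimum_score(self):
        m = prob_motif("m", [(0.7, 0.1, 0.1, 0.1), (0.1, 0.8, 0.05, 0.05)],
                       pseudocount=0.0)
        thr = calibrate_threshold(m, sensitivity=1.0).threshold
        lom = m.log_odds()
        min_score = lom.min(axis=0).sum()
        assert thr <= min_score + 1e-9
        assert thr == pytest.approx(min_score, abs=0.05)

    def test_single_deterministic_column(self):
        m = prob_motif("m", [(1, 0, 0, 0)], pseudocount=0.0)
        thr = calibrate_threshold(m, sensitivity=0.8).threshold
        assert thr == pytest.approx(2.0, abs=0.02)

    def test_tail_mass_against_enumeration_and_sampling(self, rng):
        # exact enumeration over all 4^3 sequences is the oracle; Monte-Carlo
        # confirms it within 0.01
        m = Motif("m", rng.integers(1, 60, size=(4, 3)).astype(float))
        st_obj = calibrate_threshold(m, sensitivity=0.8)
        probs, lom = m.probs, m.log_odds()
        tail = 0.0
        for seq in itertools.product(range(4), repeat=3):
            p = math.prod(probs[b, j] for j, b in enumerate(seq))
            s = sum(lom[b, j] for j, b in enumerate(seq))
            if s >= st_obj.threshold:
                tail += p
        assert tail >= 0.8
        draws = rng.random((100_000, 3))
        cum = probs.cumsum(axis=0)
        scores = np.zeros(100_000)
        for j in range(3):
            idx = np.searchsorted(cum[:, j], draws[:, j], side="right").clip(0, 3)
            scores += lom[idx, j]
        assert abs((scores >= st_obj.threshold).mean() - tail) < 0.01

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_threshold_monotone_in_sensitivity(self, seed):
        r = np.random.default_rng(seed)
        m = Motif("m", r.integers(0, 50, size=(4, 5)).astype(float))
        thrs = [calibrate_threshold(m, s).threshold for s in (0.5, 0.8, 0.95)]
        assert thrs[0] >= thrs[1] >= thrs[2]
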