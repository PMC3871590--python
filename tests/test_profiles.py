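"""Hallmark-pattern mining, k-mer hit source, and profile assembly."""

from fractions import Fraction

import numpy as np
import pytest

from shapestring import (
    HallmarkPattern,
    TabularHitSource,
    alphabetize_profile,
    build_profile,
    kmer_hits,
    mine_patterns,
)
from shapestring.profiles import (
    background_frequencies,
    binomial_tail,
    read_pattern_library,
    write_pattern_library,
)
from oracles import (
    brute_force_kmer_hits,
    brute_force_substrings,
    exact_binomial_tail,
)


def random_corpus(rng, n=10, length=30, alphabet="ACDG"):
    corpus = []
    for _ in range(n):
        seq = "".join(rng.choice(list(alphabet), size=length))
        shape = "".join(rng.choice(list("SRUVKATG"), size=length))
        corpus.append((seq, shape))
    return corpus


class TestMinePatterns:
    def test_support_counts_include_overlaps_and_repeats(self):
        corpus = [("ABAB".replace("B", "C"), "SSSS"), ("ACXY".replace("X", "D").replace("Y", "E"), "SSSS")]
        # "AC" occurs twice in ACAC and once in ACDE -> support 3
        patterns = mine_patterns(corpus, min_support=2, max_p=1.0)
        by_pat = {p.pattern: p for p in patterns}
        assert by_pat["AC"].support == 3

    def test_exact_binomial_tail_value(self):
        # support 10, modal letter seen 9 times, background 0.3
        from math import comb

        expected = sum(
            Fraction(comb(10, k)) * Fraction(3, 10) ** k * Fraction(7, 10) ** (10 - k)
            for k in range(9, 11)
        )
        assert binomial_tail(9, 10, 0.3) == pytest.approx(float(expected), abs=1e-15)

    def test_min_support_one_returns_every_substring(self):
        corpus = [("ACDEF", "SSSAA")]
        patterns = mine_patterns(corpus, min_support=1, max_p=1.0)
        expected = {
            "ACDEF"[i:i + w] for w in (2, 3, 4) for i in range(5 - w + 1)
        }
        assert {p.pattern for p in patterns} == expected

    def test_min_support_above_corpus_size_gives_empty_result(self):
        assert mine_patterns([("ACD", "SSS")], min_support=100) == []

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        corpus = random_corpus(rng, n=12, length=40)
        min_support, max_p = 4, 0.05
        patterns = mine_patterns(corpus, min_support=min_support, max_p=max_p)
        oracle = brute_force_substrings(corpus)
        bg = background_frequencies(corpus)
        expected = {}
        for pat, windows in oracle.items():
            n = len(windows)
            if n < min_support:
                continue
            keep = False
            for j in range(len(pat)):
                col = [w[j] for w in windows if w[j] != "X"]
                if not col:
                    continue
                counts = {c: col.count(c) for c in set(col)}
                modal, k = max(
                    counts.items(), key=lambda kv: (kv[1], -"SRUVKATG".index(kv[0]))
                )
                p = exact_binomial_tail(k, n, Fraction(bg[modal]).limit_denominator(10**12))
                if float(p) <= max_p:
                    keep = True
            if keep:
                expected[pat] = n
        assert {p.pattern: p.support for p in patterns} == expected

    def test_pvalues_match_exact_rational_tails(self):
        rng = np.random.default_rng(7)
        corpus = random_corpus(rng, n=8, length=35)
        bg = background_frequencies(corpus)
        for pat in mine_patterns(corpus, min_support=3, max_p=1.0)[:40]:
            windows = brute_force_substrings(corpus)[pat.pattern]
            for j, (letter, p) in enumerate(zip(pat.letters, pat.p_values)):
                if letter is None:
                    continue
                k = sum(1 for w in windows if w[j] == letter)
                exact = exact_binomial_tail(
                    k, pat.support, Fraction(bg[letter]).limit_denominator(10**12)
                )
                assert p == pytest.approx(float(exact), abs=1e-12)

    def test_pvalues_monotone_decreasing_in_k(self):
        values = [binomial_tail(k, 20, 0.3) for k in range(1, 21)]
        assert all(0 < v <= 1 for v in values)
        assert all(a > b for a, b in zip(values, values[1:]))


class TestKmerHits:
    def test_query_identical_to_corpus_entry_full_length_kmer(self):
        corpus = [("ACDEFG", "SRUVKA")]
        hits = kmer_hits("ACDEFG", corpus, k=6)
        assert len(hits) == 6
        got = {(h.query_pos, h.shape_letter) for h in hits}
        assert got == {(i, "SRUVKA"[i]) for i in range(6)}

    def test_disjoint_query_gives_no_hits(self):
        corpus = [("AAAA", "SSSS")]
        assert kmer_hits("GGGG", corpus, k=2) == []

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        corpus = random_corpus(rng, n=6, length=25, alphabet="ACD")
        query = "".join(rng.choice(list("ACD"), size=30))
        for k in (2, 3, 4):
            got = sorted((h.query_pos, h.shape_letter, h.subject)
                         for h in kmer_hits(query, corpus, k=k))
            assert got == sorted(brute_force_kmer_hits(query, corpus, k))

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            kmer_hits("AC", [("AC", "SS")], k=1)


class TestBuildProfile:
    def test_counting_into_boxes(self):
        hits = [(0, "A", s) for s in range(7)] + [(0, "T", s) for s in range(7, 10)]
        boxes = build_profile("M", TabularHitSource(hits).hits("M"), top_n=10)
        # box order S R U V K A T G
        assert boxes.tolist() == [[0, 0, 0, 0, 0, 7, 3, 0]]

    def test_position_without_evidence_is_all_zero(self):
        boxes = build_profile("MA", TabularHitSource([(0, "A", 0)]).hits("MA"))
        assert boxes[1].tolist() == [0] * 8

    def test_box_mass_conserved_against_hit_list(self):
        rng = np.random.default_rng(9)
        corpus = random_corpus(rng, n=5, length=30, alphabet="ACD")
        query = corpus[0][0]
        hits = kmer_hits(query, corpus, k=3)
        boxes = build_profile(query, hits, top_n=len(corpus))
        assert boxes.sum() == len(hits)

    def test_top_n_limits_contributing_subjects(self):
        hits = [(0, "A", 0), (0, "A", 0), (0, "T", 1)]
        boxes = build_profile("M", TabularHitSource(hits).hits("M"), top_n=1)
        # subject 0 covers more positions, so only its hits remain
        assert boxes.tolist() == [[0, 0, 0, 0, 0, 2, 0, 0]]

    def test_patterns_rescue_uncovered_positions_only(self):
        pat = HallmarkPattern(
            pattern="MA",
            letters=("A", "T"),
            p_values=(1e-4, 0.5),
            conserved=(True, False),
            support=10,
        )
        hits = TabularHitSource([(1, "S", 0)]).hits("MA")
        boxes = build_profile("MA", hits, patterns=[pat])
        assert boxes[0].tolist() == [0, 0, 0, 0, 0, 1, 0, 0]  # conserved letter
        assert boxes[1].tolist() == [1, 0, 0, 0, 0, 0, 0, 0]  # primary hit kept


class TestAlphabetizeProfile:
    def test_concentrated_box_gets_top_and_bottom_bins(self):
        letters = alphabetize_profile(np.array([[0, 0, 0, 0, 0, 10, 0, 0]]))
        assert letters == ["LLLLLGLL"]

    def test_all_zero_position_emits_vacancies(self):
        assert alphabetize_profile(np.zeros((1, 8))) == ["NNNNNNNN"]

    def test_fractions_sum_to_one_when_any_hit(self):
        rng = np.random.default_rng(1)
        boxes = rng.integers(0, 5, size=(20, 8))
        boxes[3] = 0
        fracs = boxes / np.maximum(boxes.sum(axis=1, keepdims=True), 1)
        letters = alphabetize_profile(boxes)
        for i, row in enumerate(letters):
            if boxes[i].sum() > 0:
                assert fracs[i].sum() == pytest.approx(1.0)
                assert "N" not in row


class TestPatternLibraryTsv:
    def test_round_trip_preserves_conserved_positions(self, tmp_path):
        rng = np.random.default_rng(21)
        corpus = random_corpus(rng, n=10, length=30)
        patterns = mine_patterns(corpus, min_support=3, max_p=0.2)
        assert patterns, "fixture should mine at least one pattern"
        path = tmp_path / "lib.tsv"
        write_pattern_library(patterns, path)
        back = read_pattern_library(path)
        orig = {p.pattern: p.conserved_letters() for p in patterns}
        assert {p.pattern: p.conserved_letters() for p in back} == orig


class TestTabularHitSource:
    def test_tsv_loader_round_trip(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "query_pos\tshape_letter\tsubject\n0\tA\t0\n1\tT\t2\n"
        )
        from shapestring import TabularHitSource

        hits = TabularHitSource.from_tsv(path).hits("MA")
        assert [(h.query_pos, h.shape_letter, h.subject) for h in hits] == [
            (0, "A", 0), (1, "T", 2),
        ]

    def test_bad_letter_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("query_pos\tshape_letter\tsubject\n0\tZ\t0\n")
        from shapestring import TabularHitSource

        with pytest.raises(ValueError):
            TabularHitSource.from_tsv(path)
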