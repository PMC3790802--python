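"""Suffix table construction, theta estimation, the two suffix predictors
and known-word smoothing — checked against hand counts, the worked
suffix-grid example, and independent brute-force scans."""

import math
import random

import pytest

import oracles
from suffixtag import (
    InterpolationParams,
    LexiconTable,
    build_lexicon,
    build_suffix_table,
    estimate_theta,
    interpolate_tag_given_suffix,
    invert_to_word_given_tag,
    mark_suffix_grid,
    msl_word_given_tag,
    smooth_known_word_unseen_tags,
    suffix_mle,
)
from suffixtag.corpus_io import TaggedSentence
from conftest import GRID_TAGS

COUNTINGS = ("freq_1", "freq_n")


def lexicon_from_items(items):
    lex = LexiconTable()
    for word, tag, count in items:
        lex.add(word, tag, count)
    return lex


class TestBuildSuffixTable:
    def test_three_word_fixture_counts(self, three_word_table):
        # running/VVG x3, ring/NN, sing/VVB x2
        assert three_word_table.freq("ing", "VVG", "freq_1") == 1
        assert three_word_table.freq("ing", "VVG", "freq_n") == 3
        assert three_word_table.freq("ing", "NN", "freq_n") == 1
        assert three_word_table.suffix_total("ing", "freq_1") == 3
        assert three_word_table.suffix_total("ing", "freq_n") == 6
        # proper endings only: "ring" (length 4) contributes lengths 1..3
        assert not three_word_table.has_row("ring", "NN")
        assert three_word_table.has_row("nning", "VVG")

    def test_freq1_equals_freqn_when_all_frequencies_one(self):
        lex = lexicon_from_items(
            [("walking", "VVG", 1), ("talked", "VVN", 1), ("quickly", "RR", 1)]
        )
        table = build_suffix_table(lex)
        for suffix, cells in table.rows.items():
            for tag, (f1, fn) in cells.items():
                assert f1 == fn

    def test_non_alphabetic_and_pattern_words_excluded(self):
        lex = lexicon_from_items(
            [("IL-2", "NN", 5), ("10-20", "MC", 2), ("3rd", "MC", 1), ("dog", "NN", 1)]
        )
        table = build_suffix_table(lex)
        assert set(table.rows) == {"g", "og"}

    def test_cumulativity_on_synthetic_lexicon(self, default_bundle):
        """freq(tail, tag) >= freq(suffix, tag) for every stored row."""
        lex = build_lexicon(default_bundle.train)
        table = build_suffix_table(lex)
        for suffix, cells in table.rows.items():
            if len(suffix) < 2:
                continue
            for tag, (f1, fn) in cells.items():
                assert table.freq(suffix[1:], tag, "freq_1") >= f1
                assert table.freq(suffix[1:], tag, "freq_n") >= fn

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            build_suffix_table(LexiconTable())


class TestSuffixMle:
    def test_fixture_values(self, three_word_table):
        assert suffix_mle(three_word_table, "VVG", "ing", "freq_1") == pytest.approx(1 / 3)
        assert suffix_mle(three_word_table, "VVG", "ing", "freq_n") == pytest.approx(0.5)

    def test_unknown_suffix_is_zero(self, three_word_table):
        assert suffix_mle(three_word_table, "VVG", "xyz") == 0.0

    @pytest.mark.parametrize("counting", COUNTINGS)
    def test_normalization_every_suffix(self, default_bundle, counting):
        lex = build_lexicon(default_bundle.train)
        table = build_suffix_table(lex)
        for suffix in table.rows:
            s = sum(suffix_mle(table, t, suffix, counting) for t in table.tags)
            assert abs(s - 1.0) < 1e-9


class TestEstimateTheta:
    def test_equiprobable_gives_zero(self):
        lex = lexicon_from_items([("aab", "T1", 1), ("bbc", "T2", 1)])
        params = estimate_theta(build_suffix_table(lex))
        assert params.theta == pytest.approx(0.0)
        assert params.lambda1 == 1.0 and params.lambda2 == 0.0

    def test_two_tags_all_mass_on_one(self):
        # p = (1, 0), k = 2, mean 1/2: sqrt(2 * 0.25 / 1) = 0.7071...
        lex = lexicon_from_items([("aab", "T1", 1), ("abb", "T1", 1)])
        table = build_suffix_table(lex)
        params = estimate_theta(table, tags=("T1", "T2"))
        assert params.theta == pytest.approx(math.sqrt(0.5))

    def test_lambda_identity(self, default_bundle):
        lex = build_lexicon(default_bundle.train)
        table = build_suffix_table(lex)
        for counting in COUNTINGS:
            p = estimate_theta(table, counting=counting)
            assert p.theta >= 0.0
            assert p.lambda1 + p.lambda2 == pytest.approx(1.0)
            assert p.lambda1 == pytest.approx(1 / (1 + p.theta))

    def test_single_tag_theta_zero(self):
        lex = lexicon_from_items([("abc", "T1", 1)])
        assert estimate_theta(build_suffix_table(lex)).theta == 0.0


class TestSuffixGrid:
    def test_worked_example_maximal_lengths(self, grid_table):
        grid = mark_suffix_grid(grid_table, "tubulointerstitial")
        expected = {"JJ": 4, "NN": 4, "VVI": 2, "RR": 2, "VVB": 2}
        for tag in ("DB", "CS", "VM", "NNP", "PND", "DD", "II"):
            expected[tag] = 1
        for tag, length in expected.items():
            assert grid.max_length(tag) == length, tag
        assert grid.max_any == 4  # no tag reaches length 5 ("itial" empty)

    def test_unmatched_word_all_unmarked(self, grid_table):
        grid = mark_suffix_grid(grid_table, "xyzzyx")
        assert grid.max_any == 0
        assert all(grid.max_length(t) == 0 for t in GRID_TAGS)

    def test_downward_closure_from_construction(self, small_bundle):
        lex = build_lexicon(small_bundle.train)
        table = build_suffix_table(lex)
        rng = random.Random(5)
        words = rng.sample(sorted(lex.words), 50)
        for word in words:
            grid = mark_suffix_grid(table, word)
            for tag in table.tags:
                m = grid.max_length(tag)
                for i in range(1, m + 1):
                    assert grid.marked(i, tag)


class TestInterpolation:
    def test_theta_zero_collapses_to_deepest_mle(self, three_word_table):
        params = InterpolationParams(theta=0.0, counting="freq_1", depth_method=1)
        got = interpolate_tag_given_suffix(three_word_table, "bling", "VVG", params)
        # deepest level with any entry for "bling" is "ling" (from "sing"?) no:
        # word suffixes g/ng/ing/ling; "ling" has no row, deepest is "ing"
        assert got == pytest.approx(suffix_mle(three_word_table, "VVG", "ing", "freq_1"))

    def test_method3_depth_zero_returns_prior(self, grid_table):
        params = InterpolationParams(theta=0.3, counting="freq_1", depth_method=3)
        got = interpolate_tag_given_suffix(grid_table, "xyzzyx", "JJ", params)
        assert got == pytest.approx(grid_table.p_tag("JJ", "freq_1"))

    def test_method3_uses_two_levels_for_vvi(self, grid_table):
        """The worked example: the VVI column is interpolated for 2 levels."""
        grid = mark_suffix_grid(grid_table, "tubulointerstitial")
        assert grid.max_length("VVI") == 2
        theta = 0.25
        params = InterpolationParams(theta=theta, counting="freq_1", depth_method=3)
        got = interpolate_tag_given_suffix(grid_table, "tubulointerstitial", "VVI", params)
        # explicit two-level recursion from the prior
        p = grid_table.p_tag("VVI", "freq_1")
        for s in ("l", "al"):
            p = (suffix_mle(grid_table, "VVI", s, "freq_1") + theta * p) / (1 + theta)
        assert got == pytest.approx(p)

    @pytest.mark.parametrize("counting", COUNTINGS)
    def test_method2_yields_proper_distribution(self, default_bundle, counting):
        lex = build_lexicon(default_bundle.train)
        table = build_suffix_table(lex)
        params = estimate_theta(table, counting=counting, depth_method=2)
        rng = random.Random(11)
        words = rng.sample(sorted(default_bundle.unknown_words), 40)
        for word in words:
            s = sum(
                interpolate_tag_given_suffix(table, word, t, params)
                for t in table.tags
            )
            assert abs(s - 1.0) < 1e-9, word


class TestInversion:
    def test_zero_in_zero_out(self, three_word_table):
        assert invert_to_word_given_tag(0.0, three_word_table, "VVG") == 0.0

    def test_symmetric_tags_get_equal_outputs(self):
        lex = lexicon_from_items([("aring", "T1", 2), ("bring", "T2", 2)])
        table = build_suffix_table(lex)
        a = invert_to_word_given_tag(0.4, table, "T1")
        b = invert_to_word_given_tag(0.4, table, "T2")
        assert a == pytest.approx(b)

    def test_two_row_fixture_direct_arithmetic(self):
        lex = lexicon_from_items([("ab", "T1", 3), ("cd", "T2", 5)])
        table = build_suffix_table(lex)  # rows: (b,T1), (d,T2), all length 1
        # freq_n: grand total 8, T1 total 3, length-1 mass 8
        got = invert_to_word_given_tag(1.0, table, "T1", "freq_n")
        assert got == pytest.approx(1.0 * (8 / 8) / (3 / 8))

    def test_zero_tag_total_returns_zero(self, three_word_table):
        assert invert_to_word_given_tag(0.5, three_word_table, "ZZZ") == 0.0


class TestMsl:
    def test_uses_longest_matching_suffix_per_tag(self, grid_table):
        """The worked example: for JJ the suffix used is 'tial'."""
        got = msl_word_given_tag(grid_table, "tubulointerstitial", "JJ", "freq_1")
        want = grid_table.freq("tial", "JJ", "freq_1") / grid_table.suffix_total(
            "tial", "freq_1"
        )
        assert got == pytest.approx(want)
        # for VVI the longest match is "al"
        got_vvi = msl_word_given_tag(grid_table, "tubulointerstitial", "VVI", "freq_1")
        want_vvi = grid_table.freq("al", "VVI", "freq_1") / grid_table.suffix_total(
            "al", "freq_1"
        )
        assert got_vvi == pytest.approx(want_vvi)

    def test_no_matching_suffix_gives_zero(self, grid_table):
        assert msl_word_given_tag(grid_table, "xyzzyx", "JJ") == 0.0

    def test_three_word_fixture(self, three_word_table):
        # longest VVG match for "bling" is "ing": 1 of 3 ing-words are VVG
        assert msl_word_given_tag(three_word_table, "bling", "VVG", "freq_1") == (
            pytest.approx(1 / 3)
        )
        assert msl_word_given_tag(three_word_table, "bling", "VVG", "freq_n") == (
            pytest.approx(0.5)
        )

    def test_counting_methods_agree_when_frequencies_one(self):
        lex = lexicon_from_items(
            [("walking", "VVG", 1), ("talking", "VVG", 1), ("ring", "NN", 1)]
        )
        table = build_suffix_table(lex)
        for word in ("bling", "sping", "zing"):
            for tag in ("VVG", "NN"):
                assert msl_word_given_tag(table, word, tag, "freq_1") == (
                    msl_word_given_tag(table, word, tag, "freq_n")
                )

    def test_monotone_support(self, default_bundle):
        """If word A's tag-t maximal suffix extends word B's, A's chosen
        suffix is at least as long as B's."""
        lex = build_lexicon(default_bundle.train)
        table = build_suffix_table(lex)
        a, b = "refactoring", "zzzzg"  # 'ing' extends 'g'
        ga = mark_suffix_grid(table, a).max_length("VVG")
        gb = mark_suffix_grid(table, b).max_length("VVG")
        assert ga >= gb


class TestSmoothing:
    @pytest.fixture()
    def smoothing_setup(self):
        corpus = [
            TaggedSentence(
                tuple(
                    (w, t)
                    for w, t in [
                        ("serious", "JJ"), ("famous", "JJ"), ("porous", "JJ"),
                        ("virus", "NN"), ("fungus", "NN"), ("callous", "NN"),
                    ]
                )
            )
        ]
        lex = build_lexicon(corpus)
        table = build_suffix_table(lex)
        params = estimate_theta(table)
        return lex, table, params

    def test_unseen_supported_tag_becomes_positive(self, smoothing_setup):
        lex, table, params = smoothing_setup
        smooth_known_word_unseen_tags(lex, table, params, beta=0.1)
        # "callous" was seen only as NN; its '-ous' suffix supports JJ
        assert lex.entries["callous"].get("JJ") is None
        assert lex.smoothed["callous"]["JJ"] > 0.0
        assert lex.smoothed["callous"]["NN"] == pytest.approx(lex.mle("callous", "NN"))

    def test_word_without_new_tags_unchanged(self, smoothing_setup):
        lex, table, params = smoothing_setup
        smooth_known_word_unseen_tags(lex, table, params, beta=0.1)
        # "virus" suffixes ('s', 'us', 'rus', 'irus') support NN and JJ only
        assert set(lex.smoothed["virus"]) <= {"NN", "JJ"}

    def test_beta_zero_is_identity_on_probabilities(self, smoothing_setup):
        lex, table, params = smoothing_setup
        smooth_known_word_unseen_tags(lex, table, params, beta=0.0)
        for word in lex.words:
            for tag in ("NN", "JJ"):
                assert lex.smoothed_prob(word, tag) == pytest.approx(lex.mle(word, tag))


class TestBruteForceOracle:
    """Every suffix-model probability on small random lexicons equals an
    independent scan over the flat word list."""

    def _random_items(self, rng, n_words):
        tags = ["NN", "JJ", "VVG", "RR"]
        endings = ["tion", "ing", "ly", "ous", "e", "s", ""]
        items = []
        seen = set()
        while len(items) < n_words:
            stem = "".join(rng.choice("abcdefgt") for _ in range(rng.randint(1, 4)))
            word = stem + rng.choice(endings)
            tag = rng.choice(tags)
            if not word or (word, tag) in seen:
                continue
            seen.add((word, tag))
            items.append((word, tag, rng.randint(1, 5)))
        return tags, items

    @pytest.mark.parametrize("trial", range(8))
    def test_oracle_equivalence(self, trial):
        rng = random.Random(100 + trial)
        tags, items = self._random_items(rng, rng.randint(3, 20))
        lex = lexicon_from_items(items)
        table = build_suffix_table(lex, tagset=None)
        probe_words = [w for w, _, _ in items[:6]] + ["bding", "tously", "xe"]
        all_suffixes = {s for w, _, _ in items for s in oracles.word_suffixes(w)}
        for counting in COUNTINGS:
            for s in all_suffixes:
                for t in tags:
                    assert suffix_mle(table, t, s, counting) == pytest.approx(
                        oracles.suffix_mle(items, t, s, counting)
                    )
            th = oracles.theta(items, tuple(table.tags), counting)
            params = estimate_theta(table, counting=counting)
            assert params.theta == pytest.approx(th)
            for word in probe_words:
                for t in tags:
                    if t not in table.tags:
                        continue
                    assert msl_word_given_tag(table, word, t, counting) == (
                        pytest.approx(oracles.msl(items, word, t, counting))
                    )
                    for method in (1, 2, 3):
                        p = InterpolationParams(
                            theta=th, counting=counting, depth_method=method
                        )
                        mine = interpolate_tag_given_suffix(table, word, t, p)
                        ref = oracles.interpolate(
                            items, word, t, tuple(table.tags), th, method, counting
                        )
                        assert mine == pytest.approx(ref), (word, t, method)
                        assert invert_to_word_given_tag(
                            mine, table, t, counting
                        ) == pytest.approx(oracles.invert(items, ref, t, counting))
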