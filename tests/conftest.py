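import pytest

from suffixtag import (
    LexiconTable,
    SuffixTable,
    TaggedSentence,
    TaggerModel,
    build_suffix_table,
    default_spec,
    generate_corpus,
)

# The worked suffix-grid example: rows marked for the word
# "tubulointerstitial" over 12 tags, suffix lengths 1..5 ("itial" empty).
# Frequencies are synthetic but respect cumulativity.
GRID_TAGS = ("DB", "VVI", "II", "CS", "VM", "NN", "RR", "NNP", "PND", "JJ", "VVB", "DD")
GRID_ROWS = {
    "l": GRID_TAGS,
    "al": ("VVI", "NN", "RR", "JJ", "VVB"),
    "ial": ("NN", "JJ"),
    "tial": ("NN", "JJ"),
}
_GRID_FREQ_BY_LEN = {1: 10, 2: 6, 3: 4, 4: 2}


@pytest.fixture(scope="session")
def grid_table() -> SuffixTable:
    table = SuffixTable(L_max=5, tags=GRID_TAGS)
    for suffix, tags in GRID_ROWS.items():
        f = _GRID_FREQ_BY_LEN[len(suffix)]
        for tag in tags:
            table.add(suffix, tag, f, f)
    return table


@pytest.fixture(scope="session")
def three_word_lexicon() -> LexiconTable:
    # running/VVG x3, ring/NN x1, sing/VVB x2
    lex = LexiconTable()
    for _ in range(3):
        lex.add("running", "VVG")
    lex.add("ring", "NN")
    for _ in range(2):
        lex.add("sing", "VVB")
    return lex


@pytest.fixture(scope="session")
def three_word_table(three_word_lexicon) -> SuffixTable:
    return build_suffix_table(three_word_lexicon, L_max=5)


@pytest.fixture(scope="session")
def small_bundle():
    """A quick synthetic study for unit tests."""
    return generate_corpus(
        default_spec(seed=7, n_sentences=400, n_test_sentences=60, vocab_size=800)
    )


@pytest.fixture(scope="session")
def small_model(small_bundle) -> TaggerModel:
    return TaggerModel.train(small_bundle.train, tagset=small_bundle.tagset)


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study (skewed tag prevalences, unknown words)."""
    return generate_corpus(default_spec(seed=0))


@pytest.fixture(scope="session")
def balanced_bundle():
    """Balanced-prevalence study with no unknown words, for parameter
    recovery and known-word tagging checks."""
    return generate_corpus(default_spec(seed=0, tag_prevalence={}, unknown_rate=0.0))


@pytest.fixture(scope="session")
def balanced_model(balanced_bundle) -> TaggerModel:
    return TaggerModel.train(balanced_bundle.train, tagset=balanced_bundle.tagset)


def corpus_from_tuples(*sentences) -> list:
    return [TaggedSentence(tuple(items)) for items in sentences]
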