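"""Synthetic tagged corpora and the 8-parameter-set suffix comparison.

The generator emulates the statistical structure that makes suffix-based
tag prediction work on real biomedical text: each open-class tag owns a
characteristic inventory of word endings (nouns in -tion/-ment/-ness,
adjectives in -ous/-ive/-ial, gerunds in -ing, ...), closed-class tags own
small fixed vocabularies, and tags follow a Markov chain.  Held-out
sentences inject a configurable fraction of words absent from training
(built from fresh stems but the same endings), so suffix prediction is
learnable by construction.

The tag chain is first-order with Dirichlet-distributed successor rows,
presented to the tagger through the trigram interface
(P(t3 | t1, t2) = B(t3 | t2)).  At the default corpus size this makes the
chain's parameters recoverable from counts to well within stochastic
tolerance, which a freely varying per-context trigram tensor would not be.

The comparison harness mirrors the suffix-analysis experiment design:
train once, select the held-out unknown all-lowercase words, tag each
through the suffix pathway alone under all 8 parameter sets (MSL x two
counting methods; interpolation x two counting methods x three depth
methods), log discordant words and score every set against gold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus_io import TaggedSentence, TagSet, build_lexicon
from .suffix_model import (
    build_suffix_table,
    estimate_theta,
    interpolate_tag_given_suffix,
    invert_to_word_given_tag,
    msl_word_given_tag,
)
from .tokenizer import classify_pattern

__all__ = [
    "SyntheticSpec",
    "SyntheticCorpus",
    "ParamSet",
    "DiscordanceReport",
    "DEFAULT_GRID",
    "default_spec",
    "generate_corpus",
    "run_parameter_grid",
    "accuracy",
]

# Open-class tags with their characteristic endings, closed-class
# vocabularies, and relative tag prevalences.  The inventories overlap the
# way English derivational morphology does: -ing words are mostly gerunds
# but sometimes participial adjectives (VVGJ), -ed words split between
# past participles and adjectives, and endings collide in their final
# characters (-ity/-ly, -ness/-ous), so short suffixes are ambiguous and
# the depth of suffix analysis matters.  Prevalences are skewed as in real
# tag distributions: a few dominant classes and a long tail of rare ones.
_DEFAULT_OPEN: Dict[str, Tuple[str, ...]] = {
    "NN": ("tion", "sion", "ment", "ness", "ity"),
    "JJ": ("ous", "ive", "ial", "ic", "ed"),
    "VVG": ("ing",),
    "VVN": ("ed", "en"),
    "RR": ("ly",),
    "VVGJ": ("ing",),
}
_DEFAULT_CLOSED: Dict[str, Tuple[str, ...]] = {
    "II": ("in", "of", "on", "with", "by", "for", "from", "at"),
    "DD": ("the", "a", "this", "that", "each", "these"),
}
_DEFAULT_PREVALENCE: Dict[str, float] = {
    "NN": 1.0, "JJ": 0.7, "VVG": 0.35, "VVN": 0.4, "RR": 0.5,
    "VVGJ": 0.1, "II": 0.9, "DD": 0.8,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic tagging study.

    ``transition_concentration`` is the Dirichlet concentration of each
    tag's successor row (smaller = sparser, more predictable sequences);
    ``suffix_fraction`` is the fraction of each open tag's training
    vocabulary built from the tag's characteristic endings — the rest are
    bare stems with diverse endings, as in a real lexicon;
    ``unknown_rate`` is the probability that an open-class token in a
    held-out sentence is drawn from the unknown-only vocabulary partition
    (all of whose words are suffix-bearing, since those are the words the
    suffix pathway exists for).
    """

    open_tags: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_OPEN)
    )
    closed_tags: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CLOSED)
    )
    tag_prevalence: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    transition_concentration: float = 1.5
    suffix_fraction: float = 0.5
    vocab_size: int = 5000
    n_sentences: int = 5000
    n_test_sentences: int = 500
    sentence_length: Tuple[int, int] = (8, 22)
    unknown_rate: float = 0.3
    zipf_exponent: float = 1.1
    seed: int = 0

    @property
    def tags(self) -> Tuple[str, ...]:
        return tuple(self.open_tags) + tuple(self.closed_tags)

    def validate(self) -> None:
        for tag, inv in self.open_tags.items():
            if not inv:
                raise ValueError(f"open tag {tag!r} has an empty suffix inventory")
        for tag, words in self.closed_tags.items():
            if not words:
                raise ValueError(f"closed tag {tag!r} has an empty vocabulary")
        if not (0.0 <= self.unknown_rate <= 1.0):
            raise ValueError("unknown_rate must be in [0, 1]")
        if self.sentence_length[0] < 1 or self.sentence_length[0] > self.sentence_length[1]:
            raise ValueError("invalid sentence length range")


def default_spec(seed: int = 0, **changes) -> SyntheticSpec:
    return replace(SyntheticSpec(seed=seed), **changes)


@dataclass
class SyntheticCorpus:
    """A generated study: training corpus, held-out gold sentences and the
    generator's ground truth."""

    spec: SyntheticSpec
    tagset: TagSet
    train: List[TaggedSentence]
    test: List[TaggedSentence]
    transition_matrix: np.ndarray  # B[i, j] = P(tag_j | tag_i), spec.tags order
    unknown_words: frozenset


_STEM_LETTERS = "abcdefghijklmnopqrstuvwxyz"
# letter weights loosely matching English letter frequency
_STEM_WEIGHTS = np.array(
    [8.2, 1.5, 2.8, 4.3, 12.7, 2.2, 2.0, 6.1, 7.0, 0.2, 0.8, 4.0, 2.4,
     6.7, 7.5, 1.9, 0.1, 6.0, 6.3, 9.1, 2.8, 1.0, 2.4, 0.2, 2.0, 0.1]
)


def _make_words(rng, inventory, n: int, taken: set) -> List[str]:
    """n distinct words: random stem + an ending from the inventory.

    An empty inventory yields bare stems (slightly longer, so they look
    like ordinary words rather than truncations).
    """
    probs = _STEM_WEIGHTS / _STEM_WEIGHTS.sum()
    words: List[str] = []
    while len(words) < n:
        stem_len = int(rng.integers(3, 8)) + (2 if not inventory else 0)
        stem = "".join(
            _STEM_LETTERS[i] for i in rng.choice(26, size=stem_len, p=probs)
        )
        word = stem + (inventory[int(rng.integers(len(inventory)))] if inventory else "")
        if word in taken:
            continue
        taken.add(word)
        words.append(word)
    return words


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Sample a training corpus and a held-out test set; reproducible
    byte-for-byte under the spec's seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tags = spec.tags
    K = len(tags)
    prev = np.array([spec.tag_prevalence.get(t, 1.0) for t in tags], dtype=float)

    # successor rows ~ Dirichlet with mean proportional to tag prevalence;
    # transition_concentration controls how sparse/predictable rows are
    alpha = spec.transition_concentration * K * prev / prev.sum()
    B = rng.dirichlet(alpha, size=K)
    start = rng.dirichlet(alpha)

    # vocabulary partition: per open tag, a training pool (a suffix_fraction
    # of it suffix-bearing, the rest bare stems) and a disjoint unknown-only
    # pool of suffix-bearing words used for held-out injection
    open_prev_sum = sum(spec.tag_prevalence.get(t, 1.0) for t in spec.open_tags)
    taken: set = set(w for ws in spec.closed_tags.values() for w in ws)
    train_vocab: Dict[str, List[str]] = {}
    unk_vocab: Dict[str, List[str]] = {}
    weights: Dict[str, np.ndarray] = {}
    for tag, inv in spec.open_tags.items():
        share = spec.tag_prevalence.get(tag, 1.0) / open_prev_sum
        per_tag = max(20, int(round(spec.vocab_size * share)))
        n_suffixed = int(round(spec.suffix_fraction * per_tag))
        vocab = _make_words(rng, inv, n_suffixed, taken) + _make_words(
            rng, (), per_tag - n_suffixed, taken
        )
        order = rng.permutation(per_tag)
        train_vocab[tag] = [vocab[i] for i in order]
        unk_vocab[tag] = _make_words(rng, inv, max(1, per_tag // 4), taken)
        w = 1.0 / np.arange(1, per_tag + 1) ** spec.zipf_exponent
        weights[tag] = w / w.sum()

    def sample_word(tag: str, heldout: bool, seen_pools) -> str:
        if tag in spec.closed_tags:
            words = spec.closed_tags[tag]
            return words[int(rng.integers(len(words)))]
        if heldout and rng.random() < spec.unknown_rate:
            pool = unk_vocab[tag]
            return pool[int(rng.integers(len(pool)))]
        if heldout:
            # known held-out words come from words actually seen in
            # training, so rate 0 means every held-out word is known
            pool, w = seen_pools[tag]
            return pool[int(rng.choice(len(pool), p=w))]
        pool = train_vocab[tag]
        return pool[int(rng.choice(len(pool), p=weights[tag]))]

    def sample_sentences(n: int, heldout: bool, seen_pools=None) -> List[TaggedSentence]:
        out = []
        for _ in range(n):
            length = int(rng.integers(spec.sentence_length[0], spec.sentence_length[1] + 1))
            t = int(rng.choice(K, p=start))
            seq = [t]
            for _ in range(length - 1):
                t = int(rng.choice(K, p=B[t]))
                seq.append(t)
            items = tuple(
                (sample_word(tags[i], heldout, seen_pools), tags[i]) for i in seq
            )
            out.append(TaggedSentence(items))
        return out

    train = sample_sentences(spec.n_sentences, heldout=False)
    seen = {w for s in train for w in s.words}
    seen_pools = {}
    for tag, pool in train_vocab.items():
        mask = [i for i, w in enumerate(pool) if w in seen]
        if not mask:
            mask = list(range(len(pool)))
        w = weights[tag][mask]
        seen_pools[tag] = ([pool[i] for i in mask], w / w.sum())
    test = sample_sentences(spec.n_test_sentences, heldout=True, seen_pools=seen_pools)
    return SyntheticCorpus(
        spec=spec,
        tagset=TagSet(tags),
        train=train,
        test=test,
        transition_matrix=B,
        unknown_words=frozenset(w for ws in unk_vocab.values() for w in ws),
    )


# --------------------------------------------------------------------- grid

@dataclass(frozen=True)
class ParamSet:
    """One cell of the comparison grid."""

    main_method: str             # "msl" | "interpolation"
    counting_method: str         # "freq_1" | "freq_n"
    interpolation_method: Optional[int] = None  # 1|2|3 for interpolation

    @property
    def name(self) -> str:
        if self.main_method == "msl":
            return f"msl_{self.counting_method}"
        return f"interp_{self.counting_method}_m{self.interpolation_method}"


DEFAULT_GRID: Tuple[ParamSet, ...] = (
    ParamSet("msl", "freq_1"),
    ParamSet("msl", "freq_n"),
    ParamSet("interpolation", "freq_1", 1),
    ParamSet("interpolation", "freq_1", 2),
    ParamSet("interpolation", "freq_1", 3),
    ParamSet("interpolation", "freq_n", 1),
    ParamSet("interpolation", "freq_n", 2),
    ParamSet("interpolation", "freq_n", 3),
)


@dataclass
class DiscordanceReport:
    """Per-word predictions of every parameter set over the unknown words,
    with per-set token-level scores against gold."""

    grid: Tuple[ParamSet, ...]
    predictions: Dict[str, Dict[str, str]]       # word -> set name -> tag
    concordant: Dict[str, bool]
    word_counts: Dict[str, int]                  # unknown token occurrences
    correct: Dict[str, int]                      # set name -> correct tokens
    total: int                                   # unknown token total
    correct_discordant: Dict[str, int]
    total_discordant: int

    @property
    def discordant_words(self) -> List[str]:
        return [w for w, ok in self.concordant.items() if not ok]

    def accuracy(self, set_name: str) -> float:
        return self.correct[set_name] / self.total if self.total else 0.0

    def discordant_accuracy(self, set_name: str) -> float:
        if not self.total_discordant:
            return 0.0
        return self.correct_discordant[set_name] / self.total_discordant

    def to_rows(self) -> List[dict]:
        rows = []
        for ps in self.grid:
            rows.append(
                {
                    "main_method": ps.main_method,
                    "counting_method": ps.counting_method,
                    "interpolation_method": ps.interpolation_method or "N.A.",
                    "correct": self.correct[ps.name],
                    "total": self.total,
                    "accuracy": self.accuracy(ps.name),
                }
            )
        return rows


def run_parameter_grid(
    train: Sequence[TaggedSentence],
    test: Sequence[TaggedSentence],
    grid: Sequence[ParamSet] = DEFAULT_GRID,
    tagset: Optional[TagSet] = None,
    L_max: int = 5,
) -> DiscordanceReport:
    """Train once; tag held-out unknown words through the suffix pathway
    under every parameter set; log discordance and score against gold.

    Unknown words are held-out tokens absent from the lexicon
    (case-independently), with no known surface pattern, and all
    lowercase — the selection rule of the suffix experiment.
    """
    if tagset is None:
        seen: List[str] = []
        for sent in train:
            for _, t in sent:
                if t not in seen:
                    seen.append(t)
        tagset = TagSet(sorted(seen))
    lexicon = build_lexicon(train)
    table = build_suffix_table(lexicon, L_max=L_max, tagset=tagset)
    params_by = {
        (c, m): estimate_theta(table, counting=c, depth_method=m, tags=tagset.tags)
        for c in ("freq_1", "freq_n")
        for m in (1, 2, 3)
    }

    # collect unknown tokens with their gold tags
    occurrences: Dict[str, List[str]] = {}
    for sent in test:
        for word, gold in sent:
            if lexicon.lookup_case_independent(word) is not None:
                continue
            if classify_pattern(word) != "none":
                continue
            if not (word.isalpha() and word == word.lower()):
                continue
            occurrences.setdefault(word, []).append(gold)

    def predict(word: str, ps: ParamSet) -> str:
        if ps.main_method == "msl":
            scores = [
                msl_word_given_tag(table, word, t, ps.counting_method)
                for t in tagset.tags
            ]
        else:
            p = params_by[(ps.counting_method, ps.interpolation_method)]
            scores = [
                invert_to_word_given_tag(
                    interpolate_tag_given_suffix(table, word, t, p),
                    table,
                    t,
                    ps.counting_method,
                )
                for t in tagset.tags
            ]
        best = max(range(len(scores)), key=lambda i: (scores[i], -i))
        return tagset.tags[best]

    predictions: Dict[str, Dict[str, str]] = {}
    concordant: Dict[str, bool] = {}
    correct = {ps.name: 0 for ps in grid}
    correct_disc = {ps.name: 0 for ps in grid}
    total = 0
    total_disc = 0
    word_counts: Dict[str, int] = {}
    for word, golds in occurrences.items():
        preds = {ps.name: predict(word, ps) for ps in grid}
        predictions[word] = preds
        is_conc = len(set(preds.values())) == 1
        concordant[word] = is_conc
        word_counts[word] = len(golds)
        total += len(golds)
        if not is_conc:
            total_disc += len(golds)
        for ps in grid:
            n_right = sum(1 for g in golds if preds[ps.name] == g)
            correct[ps.name] += n_right
            if not is_conc:
                correct_disc[ps.name] += n_right

    return DiscordanceReport(
        grid=tuple(grid),
        predictions=predictions,
        concordant=concordant,
        word_counts=word_counts,
        correct=correct,
        total=total,
        correct_discordant=correct_disc,
        total_discordant=total_disc,
    )


def accuracy(pred, gold) -> float:
    """Fraction of matching positions; accepts flat sequences or sequences
    of sequences (scored position-wise)."""
    if len(pred) != len(gold):
        raise ValueError("prediction and gold lengths differ")
    if pred and not isinstance(pred[0], str):
        match = 0
        total = 0
        for p_seq, g_seq in zip(pred, gold):
            if len(p_seq) != len(g_seq):
                raise ValueError("prediction and gold sequence lengths differ")
            match += sum(1 for p, g in zip(p_seq, g_seq) if p == g)
            total += len(g_seq)
        return match / total if total else 0.0
    if not pred:
        return 0.0
    return sum(1 for p, g in zip(pred, gold) if p == g) / len(pred)
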