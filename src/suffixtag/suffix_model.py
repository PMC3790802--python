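"""Suffix frequency table and the two unknown-word suffix predictors.

An unknown all-lowercase word is tagged from its word endings.  The table
stores, for every (suffix, tag) pair with suffix length 1..L_max, two
counts:

* ``freq_1`` — the number of distinct lexicon (word, tag) rows ending in
  the suffix (counting by word type);
* ``freq_n`` — the same count weighted by each word's corpus frequency
  (counting by token).

Because every word ending in a suffix of length i also ends in its length
i-1 tail, counts are cumulative in decreasing suffix length.

Two predictors are built on the table:

1. *Probability interpolation* (the TnT recursion).  With
   ``P_0 = p(tag)`` and

       P_i = (p_mle(tag | s_i) + theta * P_{i-1}) / (1 + theta)

   iterated over suffixes s_1..s_d of increasing length, where theta is
   the sample standard deviation of the unconditional tag distribution.
   The interpolation depth d is chosen by one of three methods: (1) the
   longest suffix of the word with any table entry, (2) always
   min(L_max, len(word)-1), (3) per tag, the longest suffix with an entry
   for that tag.  The result P(tag | suffix) is converted to the emission
   score P(word | tag) by Bayesian inversion.

2. *Maximum Suffix Length (MSL)*.  Per tag, only the longest suffix s_t
   of the word with an entry for that tag is used; its score is the tag's
   share of that suffix's mass, freq(s_t, tag) / sum_t' freq(s_t, t'),
   taken directly as the emission score without an inversion step.

The same machinery smooths known words: a lexicon word seen only under
some tags receives a discounted MSL probability for every unseen tag its
suffixes support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

from .corpus_io import LexiconTable, TagSet
from .tokenizer import classify_pattern

__all__ = [
    "COUNTING_METHODS",
    "SuffixTable",
    "InterpolationParams",
    "SuffixGrid",
    "build_suffix_table",
    "suffix_mle",
    "estimate_theta",
    "mark_suffix_grid",
    "interpolate_tag_given_suffix",
    "invert_to_word_given_tag",
    "msl_word_given_tag",
    "smooth_known_word_unseen_tags",
]

COUNTING_METHODS = ("freq_1", "freq_n")
_CIDX = {"freq_1": 0, "freq_n": 1}


def suffix_eligible(word: str) -> bool:
    """Words feeding the suffix table: alphabetic, no known pattern."""
    return word.isalpha() and classify_pattern(word) == "none"


@dataclass
class SuffixTable:
    """(suffix, tag) -> (freq_1, freq_n) counts, suffix lengths 1..L_max."""

    L_max: int = 5
    tags: Tuple[str, ...] = ()
    rows: Dict[str, Dict[str, list]] = field(default_factory=dict)

    def add(self, suffix: str, tag: str, freq_1: int, freq_n: int) -> None:
        cell = self.rows.setdefault(suffix, {}).setdefault(tag, [0, 0])
        cell[0] += freq_1
        cell[1] += freq_n
        if tag not in self.tags:
            self.tags = self.tags + (tag,)
        self.__dict__.pop("_totals", None)

    def has_row(self, suffix: str, tag: str) -> bool:
        return tag in self.rows.get(suffix, ())

    def freq(self, suffix: str, tag: str, counting: str = "freq_1") -> int:
        return self.rows.get(suffix, {}).get(tag, (0, 0))[_CIDX[counting]]

    def suffix_total(self, suffix: str, counting: str = "freq_1") -> int:
        i = _CIDX[counting]
        return sum(cell[i] for cell in self.rows.get(suffix, {}).values())

    @property
    def _cached_totals(self):
        # aggregate masses are consulted per (word, tag) query; computed once
        if "_totals" not in self.__dict__:
            tag_tot = {}
            tag_len1 = {}
            len1 = [0, 0]
            grand = [0, 0]
            for suffix, cells in self.rows.items():
                is1 = len(suffix) == 1
                for tag, cell in cells.items():
                    tt = tag_tot.setdefault(tag, [0, 0])
                    tt[0] += cell[0]
                    tt[1] += cell[1]
                    grand[0] += cell[0]
                    grand[1] += cell[1]
                    if is1:
                        tl = tag_len1.setdefault(tag, [0, 0])
                        tl[0] += cell[0]
                        tl[1] += cell[1]
                        len1[0] += cell[0]
                        len1[1] += cell[1]
            self.__dict__["_totals"] = (tag_tot, tag_len1, len1, grand)
        return self.__dict__["_totals"]

    def tag_total(self, tag: str, counting: str = "freq_1") -> int:
        """Sum of the tag's frequencies over all rows (all suffix lengths)."""
        return self._cached_totals[0].get(tag, (0, 0))[_CIDX[counting]]

    def tag_length1_total(self, tag: str, counting: str = "freq_1") -> int:
        """N(tag): the tag's length-1 suffix mass (its full word mass)."""
        return self._cached_totals[1].get(tag, (0, 0))[_CIDX[counting]]

    def length1_total(self, counting: str = "freq_1") -> int:
        return self._cached_totals[2][_CIDX[counting]]

    def grand_total(self, counting: str = "freq_1") -> int:
        return self._cached_totals[3][_CIDX[counting]]

    def p_tag(self, tag: str, counting: str = "freq_1") -> float:
        """Unconditional tag probability from the length-1 rows."""
        total = self.length1_total(counting)
        if total == 0:
            return 0.0
        return self.tag_length1_total(tag, counting) / total

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("suffix\ttag\tfreq_1\tfreq_n\n")
            for suffix in sorted(self.rows):
                for tag in sorted(self.rows[suffix]):
                    f1, fn = self.rows[suffix][tag]
                    fh.write(f"{suffix}\t{tag}\t{f1}\t{fn}\n")

    def to_dict(self) -> dict:
        return {
            "L_max": self.L_max,
            "tags": list(self.tags),
            "rows": {s: {t: list(c) for t, c in cells.items()} for s, cells in self.rows.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SuffixTable":
        return cls(
            L_max=payload["L_max"],
            tags=tuple(payload["tags"]),
            rows={
                s: {t: list(c) for t, c in cells.items()}
                for s, cells in payload["rows"].items()
            },
        )


def build_suffix_table(
    lex: LexiconTable, L_max: int = 5, tagset: Optional[TagSet] = None
) -> SuffixTable:
    """Count word endings over all eligible lexicon words.

    For each (word, tag) lexicon row and each suffix length
    i = 1..min(L_max, len(word)-1) of the lowercased word, ``freq_1`` is
    incremented by 1 and ``freq_n`` by the row's lexicon frequency.  Words
    with non-alphabetic characters or a known surface pattern are handled
    by the character-feature and pattern pathways instead and are skipped
    here.
    """
    if not lex.entries:
        raise ValueError("cannot build a suffix table from an empty lexicon")
    table = SuffixTable(L_max=L_max, tags=tuple(tagset.tags) if tagset else ())
    for word, tags in lex.entries.items():
        if not suffix_eligible(word):
            continue
        w = word.lower()
        for tag, count in tags.items():
            for i in range(1, min(L_max, len(w) - 1) + 1):
                table.add(w[-i:], tag, 1, count)
    return table


def suffix_mle(table: SuffixTable, tag: str, suffix: str, counting: str = "freq_1") -> float:
    """P_mle(tag | suffix): the proportion of the suffix's mass on the tag."""
    total = table.suffix_total(suffix, counting)
    if total == 0:
        return 0.0
    return table.freq(suffix, tag, counting) / total


@dataclass(frozen=True)
class InterpolationParams:
    """theta and the derived lambda weights of the TnT recursion.

    lambda1 = 1/(1+theta) weights the current level's MLE and
    lambda2 = theta/(1+theta) the accumulated estimate; theta is fixed for
    all suffixes and tags.
    """

    theta: float
    counting: str = "freq_1"
    depth_method: int = 1
    L_max: int = 5

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.counting not in COUNTING_METHODS:
            raise ValueError(f"unknown counting method: {self.counting}")
        if self.depth_method not in (1, 2, 3):
            raise ValueError(f"unknown depth method: {self.depth_method}")

    @property
    def lambda1(self) -> float:
        return 1.0 / (1.0 + self.theta)

    @property
    def lambda2(self) -> float:
        return self.theta / (1.0 + self.theta)


def estimate_theta(
    table: SuffixTable,
    counting: str = "freq_1",
    depth_method: int = 1,
    tags: Optional[Iterable[str]] = None,
) -> InterpolationParams:
    """theta = sample std. deviation of the unconditional tag distribution.

    Over the k tags, with mean fixed at 1/k and divisor k-1:

        theta^2 = 1/(k-1) * sum_t (p(t) - 1/k)^2

    where p(t) comes from the table's length-1 rows.  k = 1 gives theta = 0
    by convention.
    """
    tag_list = tuple(tags) if tags is not None else table.tags
    if not tag_list:
        raise ValueError("suffix table has no tags")
    k = len(tag_list)
    if k == 1:
        theta = 0.0
    else:
        mean = 1.0 / k
        var = sum((table.p_tag(t, counting) - mean) ** 2 for t in tag_list) / (k - 1)
        theta = math.sqrt(var)
    return InterpolationParams(
        theta=theta, counting=counting, depth_method=depth_method, L_max=table.L_max
    )


@dataclass(frozen=True)
class SuffixGrid:
    """Suffix-length x tag existence grid for one word (cf. the table of
    marked (suffix, tag) cells used to choose interpolation depths)."""

    word: str
    max_candidate: int                      # min(L_max, len(word)-1)
    max_len_by_tag: Dict[str, int]          # 0 when no suffix of the word has a row

    def marked(self, length: int, tag: str) -> bool:
        return 1 <= length <= self.max_len_by_tag.get(tag, 0)

    def max_length(self, tag: str) -> int:
        return self.max_len_by_tag.get(tag, 0)

    @property
    def max_any(self) -> int:
        """Longest suffix length with an entry for any tag."""
        return max(self.max_len_by_tag.values(), default=0)


def mark_suffix_grid(table: SuffixTable, word: str) -> SuffixGrid:
    """Mark, per tag, which word suffix lengths have a table row.

    Markers are downward-closed per tag for any table built by
    :func:`build_suffix_table` (cumulativity), so only the per-tag maximal
    marked length is stored.
    """
    if not word:
        raise ValueError("word must be non-empty")
    w = word.lower()
    max_candidate = min(table.L_max, len(w) - 1)
    max_len: Dict[str, int] = {}
    for tag in table.tags:
        best = 0
        for i in range(1, max_candidate + 1):
            if table.has_row(w[-i:], tag):
                best = i
        max_len[tag] = best
    return SuffixGrid(word=w, max_candidate=max_candidate, max_len_by_tag=max_len)


def _interpolation_depth(grid: SuffixGrid, tag: str, method: int) -> int:
    if method == 1:
        return grid.max_any
    if method == 2:
        return grid.max_candidate
    return grid.max_length(tag)


def interpolate_tag_given_suffix(
    table: SuffixTable, word: str, tag: str, params: InterpolationParams
) -> float:
    """P(tag | suffix) by the recursive interpolation from P_0 = p(tag).

    Depth method 2 can reach suffix lengths for which the table has no row
    under any tag; such a level carries no evidence for any tag and is
    skipped (the estimate is carried forward), which keeps the per-word
    distribution over tags normalized.  A level whose suffix has rows for
    other tags only contributes p_mle = 0 for this tag.
    """
    if not word:
        raise ValueError("word must be non-empty")
    w = word.lower()
    grid = mark_suffix_grid(table, w)
    depth = _interpolation_depth(grid, tag, params.depth_method)
    theta = params.theta
    p = table.p_tag(tag, params.counting)
    for i in range(1, depth + 1):
        suffix = w[-i:]
        if table.suffix_total(suffix, params.counting) == 0:
            continue
        p = (suffix_mle(table, tag, suffix, params.counting) + theta * p) / (1.0 + theta)
    return p


def invert_to_word_given_tag(
    p_tag_given_suffix: float,
    table: SuffixTable,
    tag: str,
    counting: str = "freq_1",
) -> float:
    """Bayesian inversion P(suffix | tag) = P(tag | suffix) P(suffix) / P(tag).

    P(tag) is the tag's share of the whole table's mass; P(suffix) is the
    length-1 row mass over the whole table — a per-word constant, so only
    the relative value across tags matters in the decoder's argmax.
    """
    if p_tag_given_suffix == 0.0:
        return 0.0
    tag_total = table.tag_total(tag, counting)
    if tag_total == 0:
        return 0.0
    grand = table.grand_total(counting)
    p_tag = tag_total / grand
    p_suffix = table.length1_total(counting) / grand
    return p_tag_given_suffix * p_suffix / p_tag


def msl_word_given_tag(
    table: SuffixTable, word: str, tag: str, counting: str = "freq_1"
) -> float:
    """Maximum Suffix Length emission score for (word, tag).

    Per tag, only the longest suffix s_t of the word with an entry for
    that tag is consulted; the score is the tag's share of that suffix's
    mass,

        freq(s_t, tag) / sum_t' freq(s_t, t'),

    used directly as the emission score (no Bayesian inversion step).  A
    long specific match ("tial" for an adjective) therefore outweighs a
    short generic one ("l" for a determiner), and a tag none of whose
    rows match any suffix of the word scores zero.
    """
    if not word:
        raise ValueError("word must be non-empty")
    w = word.lower()
    for i in range(min(table.L_max, len(w) - 1), 0, -1):
        suffix = w[-i:]
        if table.has_row(suffix, tag):
            return table.freq(suffix, tag, counting) / table.suffix_total(
                suffix, counting
            )
    return 0.0


def smooth_known_word_unseen_tags(
    lex: LexiconTable,
    table: SuffixTable,
    params: InterpolationParams,
    beta: float = 0.1,
) -> LexiconTable:
    """Fill smoothed word-given-tag probabilities for the whole lexicon.

    Seen tags keep their MLE c(w,t)/c(t).  A tag unseen for the word but
    supported by one of its suffixes receives the suffix evidence carried
    to the same word-given-tag scale through the Bayes identity
    p(w|t) = p(t|w) c(w)/c(t), with the MSL score standing in for p(t|w),
    discounted by ``beta`` because the pairing was never observed:

        smoothed(w, t) = beta * msl(w, t) * c(w) / c(t).

    With a small training corpus this is the common case of a word
    observed under only a subset of its true tags.  Original counts are
    untouched; ``beta = 0`` reproduces the raw MLE exactly.
    """
    for word, seen in lex.entries.items():
        sm: Dict[str, float] = {tag: lex.mle(word, tag) for tag in seen}
        if beta > 0.0:
            wf = lex.word_freq(word)
            for tag in table.tags:
                if tag in seen:
                    continue
                tag_tokens = lex.tag_totals.get(tag, 0)
                if tag_tokens == 0:
                    continue
                m = msl_word_given_tag(table, word, tag, params.counting)
                if m > 0.0:
                    sm[tag] = beta * m * wf / tag_tokens
        lex.smoothed[word] = sm
    return lex
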