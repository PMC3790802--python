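"""Independent brute-force recomputations used as test oracles.

Everything here works by direct scans over a flat list of
(word, tag, count) lexicon items — no table construction, no reuse of the
package's aggregation code — so it can serve as an independent check of
the suffix and character-feature statistics.
"""

import math
from itertools import groupby

_CIDX = {"freq_1": 0, "freq_n": 1}


def eligible(word: str) -> bool:
    return word.isalpha()


def word_suffixes(word: str, L_max: int = 5):
    w = word.lower()
    return [w[-i:] for i in range(1, min(L_max, len(w) - 1) + 1)]


def suffix_freq(items, suffix, tag, counting, L_max=5):
    total = 0
    for word, t, count in items:
        if t != tag or not eligible(word):
            continue
        if suffix in word_suffixes(word, L_max):
            total += 1 if counting == "freq_1" else count
    return total


def suffix_total(items, suffix, counting, L_max=5):
    tags = {t for _, t, _ in items}
    return sum(suffix_freq(items, suffix, t, counting, L_max) for t in tags)


def suffix_mle(items, tag, suffix, counting, L_max=5):
    denom = suffix_total(items, suffix, counting, L_max)
    if denom == 0:
        return 0.0
    return suffix_freq(items, suffix, tag, counting, L_max) / denom


def p_tag(items, tag, counting, L_max=5):
    """Length-1-row tag distribution: each eligible word of length >= 2
    contributes its (weighted) count to its tag."""
    num = 0
    denom = 0
    for word, t, count in items:
        if not eligible(word) or len(word) < 2:
            continue
        c = 1 if counting == "freq_1" else count
        denom += c
        if t == tag:
            num += c
    return num / denom if denom else 0.0


def theta(items, tags, counting, L_max=5):
    k = len(tags)
    if k == 1:
        return 0.0
    mean = 1.0 / k
    var = sum((p_tag(items, t, counting, L_max) - mean) ** 2 for t in tags) / (k - 1)
    return math.sqrt(var)


def msl(items, word, tag, counting, L_max=5):
    for suffix in reversed(word_suffixes(word, L_max)):
        f = suffix_freq(items, suffix, tag, counting, L_max)
        if f > 0:
            return f / suffix_total(items, suffix, counting, L_max)
    return 0.0


def max_marked_length(items, word, tag, L_max=5):
    best = 0
    for i, suffix in enumerate(word_suffixes(word, L_max), start=1):
        if suffix_freq(items, suffix, tag, "freq_1", L_max) > 0:
            best = i
    return best


def interpolate(items, word, tag, tags, th, depth_method, counting, L_max=5):
    suffixes = word_suffixes(word, L_max)
    if depth_method == 1:
        depth = max((max_marked_length(items, word, t, L_max) for t in tags), default=0)
    elif depth_method == 2:
        depth = len(suffixes)
    else:
        depth = max_marked_length(items, word, tag, L_max)
    p = p_tag(items, tag, counting, L_max)
    for i in range(depth):
        s = suffixes[i]
        if suffix_total(items, s, counting, L_max) == 0:
            continue
        p = (suffix_mle(items, tag, s, counting, L_max) + th * p) / (1.0 + th)
    return p


def invert(items, p_tag_given_suffix, tag, counting, L_max=5):
    if p_tag_given_suffix == 0.0:
        return 0.0
    tags = {t for _, t, _ in items}
    all_suffixes = {s for w, _, _ in items for s in word_suffixes(w, L_max)}
    tag_total = sum(
        suffix_freq(items, s, tag, counting, L_max) for s in all_suffixes
    )
    if tag_total == 0:
        return 0.0
    grand = sum(
        suffix_freq(items, s, t, counting, L_max) for s in all_suffixes for t in tags
    )
    len1 = sum(
        suffix_freq(items, s, t, counting, L_max)
        for s in all_suffixes
        if len(s) == 1
        for t in tags
    )
    return p_tag_given_suffix * (len1 / grand) / (tag_total / grand)


# ---------------------------------------------------------------- char model

_GREEK_RANGES = ((0x0370, 0x03FF), (0x1F00, 0x1FFF))


def _char_class(ch: str) -> str:
    if ch in "-./()":
        return ch
    if any(lo <= ord(ch) <= hi for lo, hi in _GREEK_RANGES):
        return "g"
    if ch.isupper():
        return "A"
    if ch.islower():
        return "a"
    if ch.isdigit():
        return "0"
    return "S"


def feature(word: str) -> str:
    return "".join(sym for sym, _ in groupby(_char_class(c) for c in word))


def char_mle(items, word, tag):
    target = feature(word)
    num = sum(c for w, t, c in items if t == tag and feature(w) == target)
    denom = sum(c for _, t, c in items if t == tag)
    return num / denom if denom else 0.0
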