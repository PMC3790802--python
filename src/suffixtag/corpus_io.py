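"""Tagged-corpus and tag-set I/O, and the lexicon frequency table.

The corpus text format is the inline one-sentence-per-line dialect used by
MedPost-style biomedical corpora: each token is ``word_TAG`` (underscore
dialect) or ``word/TAG`` (slash dialect).  The lexicon table stores, for
every surface word form, its per-tag occurrence counts; the maximum
likelihood word-given-tag estimate is

    P_mle(w | t) = count(w, t) / sum_w' count(w', t)

which is zero for any (word, tag) pair absent from the training corpus.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "TagSet",
    "TaggedSentence",
    "LexiconTable",
    "CorpusError",
    "CorpusParseError",
    "TagValidationError",
    "read_tagset",
    "default_tagset",
    "read_tagged_corpus",
    "write_tagged_corpus",
    "build_lexicon",
    "lexicon_mle",
    "lookup_case_independent",
]

_DIALECT_SEP = {"underscore": "_", "slash": "/"}


class CorpusError(ValueError):
    """Base class for corpus-format problems."""


class CorpusParseError(CorpusError):
    """A token could not be split into word and tag."""


class TagValidationError(CorpusError):
    """A tag is not a member of the tag set."""


class TagSet:
    """Ordered collection of unique POS tag labels.

    The order is significant: it defines the tag index used for
    deterministic tie-breaking in decoding.
    """

    def __init__(self, tags: Iterable[str]):
        tags = tuple(tags)
        if not tags:
            raise ValueError("tag set must contain at least one tag")
        if any(not t or any(c.isspace() for c in t) for t in tags):
            raise ValueError("tags must be non-empty and free of whitespace")
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate tags in tag set")
        self.tags: Tuple[str, ...] = tags
        self._index = {t: i for i, t in enumerate(tags)}

    @property
    def k(self) -> int:
        return len(self.tags)

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, TagSet) and self.tags == other.tags

    def index(self, tag: str) -> int:
        return self._index[tag]

    def validate(self, tag: str) -> None:
        if tag not in self._index:
            raise TagValidationError(f"unknown tag: {tag!r}")

    @classmethod
    def from_file(cls, path) -> "TagSet":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(line.strip() for line in lines if line.strip())

    def to_file(self, path) -> None:
        Path(path).write_text("\n".join(self.tags) + "\n", encoding="utf-8")


def read_tagset(path) -> TagSet:
    return TagSet.from_file(path)


def default_tagset() -> TagSet:
    """The bundled 60-label MedPost-style tag set.

    This is a synthetic stand-in assembled from the published MedPost
    label inventory, not the exact supplementary list of any corpus
    release.
    """
    ref = importlib.resources.files("suffixtag.data") / "tagset60_synthetic.txt"
    lines = ref.read_text(encoding="utf-8").splitlines()
    return TagSet(line.strip() for line in lines if line.strip())


@dataclass(frozen=True)
class TaggedSentence:
    """A sentence as a sequence of (word, tag) pairs."""

    items: Tuple[Tuple[str, str], ...]

    def __post_init__(self):
        if not self.items:
            raise ValueError("a tagged sentence must contain at least one token")
        object.__setattr__(self, "items", tuple(tuple(it) for it in self.items))

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def words(self) -> Tuple[str, ...]:
        return tuple(w for w, _ in self.items)

    @property
    def tags(self) -> Tuple[str, ...]:
        return tuple(t for _, t in self.items)


def read_tagged_corpus(
    path,
    dialect: str = "underscore",
    tagset: Optional[TagSet] = None,
) -> List[TaggedSentence]:
    """Read a one-sentence-per-line tagged corpus.

    Raises :class:`CorpusParseError` (naming the line) for a token without
    the dialect separator, and :class:`TagValidationError` (naming the tag)
    when ``tagset`` is given and a parsed tag is not in it.
    """
    sep = _DIALECT_SEP[dialect]
    sentences: List[TaggedSentence] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            items = []
            for tok in line.split():
                word, _, tag = tok.rpartition(sep)
                if not word or not tag:
                    raise CorpusParseError(
                        f"line {lineno}: token {tok!r} has no {sep!r} separator"
                    )
                if tagset is not None:
                    tagset.validate(tag)
                items.append((word, tag))
            sentences.append(TaggedSentence(tuple(items)))
    return sentences


def write_tagged_corpus(
    sentences: Sequence[TaggedSentence], path, dialect: str = "underscore"
) -> None:
    sep = _DIALECT_SEP[dialect]
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            fh.write(" ".join(f"{w}{sep}{t}" for w, t in sent) + "\n")


@dataclass
class LexiconTable:
    """Word -> tag -> frequency counts from a training corpus.

    ``smoothed`` holds word-given-tag probabilities after suffix smoothing
    of unseen tags (see :func:`suffixtag.suffix_model
    .smooth_known_word_unseen_tags`); until then it is empty and
    :meth:`smoothed_prob` falls back to the raw MLE.  Keys preserve surface
    case; case-independent lookup is a view over a lowercase index.
    """

    entries: Dict[str, Dict[str, int]] = field(default_factory=dict)
    smoothed: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        self._rebuild_indexes()

    def _rebuild_indexes(self) -> None:
        self.tag_totals: Dict[str, int] = {}
        self._lower: Dict[str, List[str]] = {}
        for word, tags in self.entries.items():
            for tag, n in tags.items():
                self.tag_totals[tag] = self.tag_totals.get(tag, 0) + n
            self._lower.setdefault(word.lower(), []).append(word)

    def add(self, word: str, tag: str, n: int = 1) -> None:
        tags = self.entries.setdefault(word, {})
        if not tags:
            self._lower.setdefault(word.lower(), []).append(word)
        tags[tag] = tags.get(tag, 0) + n
        self.tag_totals[tag] = self.tag_totals.get(tag, 0) + n

    def word_freq(self, word: str) -> int:
        return sum(self.entries.get(word, {}).values())

    @property
    def words(self):
        return self.entries.keys()

    def mle(self, word: str, tag: str) -> float:
        total = self.tag_totals.get(tag, 0)
        if total == 0:
            return 0.0
        return self.entries.get(word, {}).get(tag, 0) / total

    def smoothed_prob(self, word: str, tag: str) -> float:
        sm = self.smoothed.get(word)
        if sm is not None:
            return sm.get(tag, 0.0)
        return self.mle(word, tag)

    def lookup_case_independent(self, word: str) -> Optional[str]:
        """Stored surface form matching ``word`` case-independently.

        An exact-case match wins; otherwise the most frequent candidate
        (ties broken lexicographically) is returned, or None.
        """
        if word in self.entries:
            return word
        candidates = self._lower.get(word.lower())
        if not candidates:
            return None
        return min(candidates, key=lambda w: (-self.word_freq(w), w))

    def to_dict(self) -> dict:
        return {"entries": self.entries, "smoothed": self.smoothed}

    @classmethod
    def from_dict(cls, payload: dict) -> "LexiconTable":
        return cls(
            entries={w: dict(t) for w, t in payload["entries"].items()},
            smoothed={w: dict(t) for w, t in payload.get("smoothed", {}).items()},
        )


def build_lexicon(corpus: Sequence[TaggedSentence]) -> LexiconTable:
    """Count (word, tag) occurrences over the corpus."""
    if not corpus:
        raise ValueError("cannot build a lexicon from an empty corpus")
    lex = LexiconTable()
    for sent in corpus:
        for word, tag in sent:
            lex.add(word, tag)
    return lex


def lexicon_mle(lex: LexiconTable, word: str, tag: str) -> float:
    return lex.mle(word, tag)


def lookup_case_independent(lex: LexiconTable, word: str) -> Optional[str]:
    return lex.lookup_case_independent(word)
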