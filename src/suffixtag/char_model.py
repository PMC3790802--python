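"""Character-feature strings and the feature-conditional tag table.

Unknown words that are not all-lowercase — gene symbols, units, chemical
names — are predicted from the *shape* of the word rather than its suffix.
Each character maps to a class symbol:

    uppercase -> 'A'   lowercase -> 'a'   digit -> '0'   Greek -> 'g'
    '-' '.' '/' '(' ')' kept literally    anything else -> 'S'

and maximal runs of the same symbol collapse to one occurrence, so
``IL-2`` -> ``A-0`` and ``p53`` -> ``a0``.  The table stores feature-string
x tag counts from the training lexicon; the emission estimate is
P(feature | tag) = count(feature, tag) / total(tag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from .corpus_io import LexiconTable

__all__ = ["CharFeatureTable", "feature_string", "build_char_table", "char_mle"]

_LITERALS = set("-./()")


def _is_greek(ch: str) -> bool:
    return "Ͱ" <= ch <= "Ͽ" or "ἀ" <= ch <= "῿"


def feature_string(word: str) -> str:
    """Map a word to its character-feature string (case sensitive)."""
    if not word:
        raise ValueError("word must be non-empty")
    out = []
    for ch in word:
        if ch in _LITERALS:
            sym = ch
        elif _is_greek(ch):
            sym = "g"
        elif ch.isupper():
            sym = "A"
        elif ch.islower():
            sym = "a"
        elif ch.isdigit():
            sym = "0"
        else:
            sym = "S"
        if not out or out[-1] != sym:
            out.append(sym)
    return "".join(out)


@dataclass
class CharFeatureTable:
    """(feature string, tag) -> count, with per-tag totals."""

    rows: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.tag_totals: Dict[str, int] = {}
        for cells in self.rows.values():
            for tag, n in cells.items():
                self.tag_totals[tag] = self.tag_totals.get(tag, 0) + n

    def add(self, feature: str, tag: str, n: int) -> None:
        cells = self.rows.setdefault(feature, {})
        cells[tag] = cells.get(tag, 0) + n
        self.tag_totals[tag] = self.tag_totals.get(tag, 0) + n

    def count(self, feature: str, tag: str) -> int:
        return self.rows.get(feature, {}).get(tag, 0)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("feature\ttag\tcount\n")
            for feature in sorted(self.rows):
                for tag in sorted(self.rows[feature]):
                    fh.write(f"{feature}\t{tag}\t{self.rows[feature][tag]}\n")

    def to_dict(self) -> dict:
        return {"rows": {f: dict(c) for f, c in self.rows.items()}}

    @classmethod
    def from_dict(cls, payload: dict) -> "CharFeatureTable":
        return cls(rows={f: dict(c) for f, c in payload["rows"].items()})


def build_char_table(lex: LexiconTable) -> CharFeatureTable:
    """Aggregate lexicon frequencies by (feature string, tag)."""
    if not lex.entries:
        raise ValueError("cannot build a char-feature table from an empty lexicon")
    table = CharFeatureTable()
    for word, tags in lex.entries.items():
        feature = feature_string(word)
        for tag, count in tags.items():
            table.add(feature, tag, count)
    return table


def char_mle(table: CharFeatureTable, word: str, tag: str) -> float:
    """P(feature_string(word) | tag); zero for unrepresented feature or tag."""
    total = table.tag_totals.get(tag, 0)
    if total == 0:
        return 0.0
    return table.count(feature_string(word), tag) / total
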