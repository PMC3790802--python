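"""Sentence splitting, tokenization and known-pattern classification.

Biomedical text is full of names like ``IL-2``, ``Ca(2+)`` or ``p38/MAPK``
whose internal punctuation is part of the name.  The tokenizer here never
splits a hyphen, slash, dot or parenthesis that sits inside an alphanumeric
run; punctuation is peeled only from token edges.  Sentence boundaries are
placed after ``.``, ``!`` or ``?`` when the next chunk opens with an
uppercase letter or digit, except after dotted abbreviations (``e.g.``,
``i.v.``) whose final period stays attached to the token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List

__all__ = ["Token", "tokenize", "classify_pattern", "PATTERN_KINDS"]

PATTERN_KINDS = ("number", "number_range", "ordinal", "none")

# optionally signed integer/decimal, thousands separators allowed
_NUMBER_RE = re.compile(r"[+-]?(?:\d{1,3}(?:,\d{3})+|\d+)(?:\.\d+)?")
# number-dash-number; the dash must be flanked directly by digits
_RANGE_RE = re.compile(r"\d+(?:\.\d+)?-\d+(?:\.\d+)?")
_ORDINAL_RE = re.compile(r"(?:\d*(?:1st|2nd|3rd)|\d+th)", re.IGNORECASE)


def classify_pattern(token: str) -> str:
    """Classify a token against the known surface patterns.

    Returns one of ``number``, ``number_range``, ``ordinal`` or ``none``.
    The three rule classes are mutually exclusive on any input, so exactly
    one kind is ever returned.
    """
    if _NUMBER_RE.fullmatch(token):
        return "number"
    if _RANGE_RE.fullmatch(token):
        return "number_range"
    if _ORDINAL_RE.fullmatch(token):
        return "ordinal"
    return "none"


def _is_greek(ch: str) -> bool:
    return "Ͱ" <= ch <= "Ͽ" or "ἀ" <= ch <= "῿"


def _is_wordchar(ch: str) -> bool:
    """Characters that anchor a token: letters (incl. Greek) and digits."""
    return ch.isalnum() or _is_greek(ch)


@dataclass(frozen=True)
class Token:
    """A single token with its pattern kind and case summary."""

    text: str
    pattern: str
    is_all_lower: bool

    @classmethod
    def from_text(cls, text: str) -> "Token":
        if not text or any(c.isspace() for c in text):
            raise ValueError(f"invalid token text: {text!r}")
        return cls(
            text=text,
            pattern=classify_pattern(text),
            is_all_lower=all(c.isalpha() and c.islower() for c in text),
        )


def _split_chunk(chunk: str) -> tuple[List[str], bool]:
    """Split one whitespace-delimited chunk into token texts.

    Returns (token texts, abbreviation_flag).  The flag is True when a final
    period was kept attached because the core contains internal dots (so the
    period must not be treated as a sentence terminator).
    """
    if classify_pattern(chunk) != "none":
        return [chunk], False

    leading: List[str] = []
    trailing: List[str] = []
    core = chunk
    abbrev = False

    # peel trailing punctuation
    while len(core) > 1 and not _is_wordchar(core[-1]):
        if core[-1] == "." and "." in core[:-1] and any(c.isalpha() for c in core):
            # dotted abbreviation: keep the period on the token
            abbrev = True
            break
        if core[-1] == ")" and any(
            c == "(" and i > 0 and _is_wordchar(core[i - 1])
            for i, c in enumerate(core[:-1])
        ):
            break  # closes a parenthetical inside a name, e.g. Ca(2+)
        trailing.append(core[-1])
        core = core[:-1]
    # peel leading punctuation (a sign glued to a number was caught above)
    while len(core) > 1 and not _is_wordchar(core[0]):
        if core[0] == "(" and any(
            c == ")" and i + 1 < len(core) and _is_wordchar(core[i + 1])
            for i, c in enumerate(core[1:], start=1)
        ):
            break  # opens a parenthetical inside a name, e.g. (1)H-NMR
        leading.append(core[0])
        core = core[1:]

    trailing.reverse()
    return leading + [core] + trailing, abbrev


def tokenize(text: str) -> List[List[Token]]:
    """Split raw text into sentences of :class:`Token`.

    Total function: any string (including empty) is accepted; the multiset
    of non-whitespace characters of the input is preserved in the output.
    """
    stream: List[str] = []
    for chunk in text.split():
        texts, _ = _split_chunk(chunk)
        stream.extend(texts)

    sentences: List[List[Token]] = []
    current: List[Token] = []
    for i, text_i in enumerate(stream):
        current.append(Token.from_text(text_i))
        nxt = stream[i + 1] if i + 1 < len(stream) else None
        if (
            text_i in {".", "!", "?"}
            and nxt is not None
            and (nxt[0].isupper() or nxt[0].isdigit())
        ):
            sentences.append(current)
            current = []
    if current:
        sentences.append(current)
    return sentences


def detokenize(sentences: Iterable[Iterable[Token]]) -> str:
    """Inverse-ish of :func:`tokenize`: space-join tokens, one sentence per line."""
    return "\n".join(" ".join(tok.text for tok in sent) for sent in sentences)
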