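"""Trigram HMM: transition smoothing, emission cascade, Viterbi decoding.

The joint probability of a tagged sentence factorizes as

    p(t_1..t_N, w_1..w_N) = prod_i p(t_i | t_{i-1}, t_{i-2}) p(w_i | t_i)

with two boundary pseudo-tags opening each sentence and one closing it.
Transitions are smoothed by deleted linear interpolation of the trigram,
bigram and unigram relative frequencies; the three weights are estimated
from the training counts by letting each trigram vote, with its count, for
the n-gram order whose held-out relative frequency is largest.

The emission p(w|t) is resolved through a cascade: lexicon lookup
(case-independent, suffix-smoothed) -> known surface pattern (numbers,
ranges, ordinals) -> character-feature table for words with capitals,
digits or symbols -> suffix predictor (MSL by default, or TnT-style
interpolation with Bayesian inversion) for unknown all-lowercase words.

Decoding is exact Viterbi in log-space; ties break toward the lower
tag-set index so output is reproducible across runs and platforms.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .char_model import CharFeatureTable, build_char_table, char_mle
from .corpus_io import LexiconTable, TaggedSentence, TagSet, build_lexicon
from .suffix_model import (
    InterpolationParams,
    SuffixTable,
    build_suffix_table,
    estimate_theta,
    interpolate_tag_given_suffix,
    invert_to_word_given_tag,
    msl_word_given_tag,
    smooth_known_word_unseen_tags,
)
from .tokenizer import Token

__all__ = [
    "BOS",
    "EOS",
    "TransitionModel",
    "TaggerConfig",
    "TaggerModel",
    "build_transition_model",
    "transition_prob",
    "emission_prob",
    "viterbi",
]

logger = logging.getLogger(__name__)

BOS = "<s>"   # two leading boundary pseudo-tags per sentence
EOS = "</s>"  # one trailing

_MODEL_FORMAT_VERSION = 1


class TransitionModel:
    """Tag n-gram counts and deleted-interpolation weights."""

    def __init__(self, corpus: Sequence[TaggedSentence]):
        if not corpus:
            raise ValueError("cannot build a transition model from an empty corpus")
        self.uni: Dict[str, int] = {}        # outcome counts (incl. EOS)
        self.bi: Dict[Tuple[str, str], int] = {}
        self.tri: Dict[Tuple[str, str, str], int] = {}
        self.ctx1: Dict[str, int] = {}       # events with this previous tag
        self.ctx2: Dict[Tuple[str, str], int] = {}
        self.n_events = 0
        tags_seen = []
        for sent in corpus:
            seq = [BOS, BOS, *sent.tags, EOS]
            for t in sent.tags:
                if t not in self.uni and t not in tags_seen:
                    tags_seen.append(t)
            for i in range(2, len(seq)):
                t1, t2, t3 = seq[i - 2], seq[i - 1], seq[i]
                self.uni[t3] = self.uni.get(t3, 0) + 1
                self.bi[(t2, t3)] = self.bi.get((t2, t3), 0) + 1
                self.tri[(t1, t2, t3)] = self.tri.get((t1, t2, t3), 0) + 1
                self.ctx1[t2] = self.ctx1.get(t2, 0) + 1
                self.ctx2[(t1, t2)] = self.ctx2.get((t1, t2), 0) + 1
                self.n_events += 1
        self.weights = self._estimate_weights()

    def _estimate_weights(self) -> Tuple[float, float, float]:
        """Deleted interpolation: each trigram votes for the order whose
        held-out (leave-this-trigram's-token-out) relative frequency wins;
        ties favor the lower order."""
        votes = [0.0, 0.0, 0.0]
        for (t1, t2, t3), c in self.tri.items():
            c12 = self.ctx2[(t1, t2)]
            c2 = self.ctx1[t2]
            f3 = (c - 1) / (c12 - 1) if c12 > 1 else 0.0
            f2 = (self.bi[(t2, t3)] - 1) / (c2 - 1) if c2 > 1 else 0.0
            f1 = (self.uni[t3] - 1) / (self.n_events - 1) if self.n_events > 1 else 0.0
            if f1 == f2 == f3 == 0.0:
                continue  # a singleton everywhere carries no evidence
            best = max(range(3), key=lambda i: ((f1, f2, f3)[i], -i))
            votes[best] += c
        total = sum(votes)
        if total == 0:
            return (1 / 3, 1 / 3, 1 / 3)
        return tuple(v / total for v in votes)  # type: ignore[return-value]

    def prob(self, t: str, t_prev: str, t_prev2: str) -> float:
        """w3 f(t|t_prev2,t_prev) + w2 f(t|t_prev) + w1 f(t)."""
        w1, w2, w3 = self.weights
        p = w1 * self.uni.get(t, 0) / self.n_events
        c2 = self.ctx1.get(t_prev, 0)
        if c2:
            p += w2 * self.bi.get((t_prev, t), 0) / c2
        c12 = self.ctx2.get((t_prev2, t_prev), 0)
        if c12:
            p += w3 * self.tri.get((t_prev2, t_prev, t), 0) / c12
        return p

    def bigram_mle(self, t: str, t_prev: str) -> float:
        c = self.ctx1.get(t_prev, 0)
        return self.bi.get((t_prev, t), 0) / c if c else 0.0

    def continuation_bigram_mle(self, t: str, t_prev: str) -> float:
        """Successor MLE conditioned on the sentence continuing.

        Sentence length acts as exogenous censoring of the tag chain, so
        the within-sentence successor law is estimated by excluding the
        end-of-sentence outcome from the conditioning mass.
        """
        c = self.ctx1.get(t_prev, 0) - self.bi.get((t_prev, EOS), 0)
        return self.bi.get((t_prev, t), 0) / c if c else 0.0

    def trigram_mle(self, t: str, t_prev: str, t_prev2: str) -> float:
        c = self.ctx2.get((t_prev2, t_prev), 0)
        return self.tri.get((t_prev2, t_prev, t), 0) / c if c else 0.0

    def to_dict(self) -> dict:
        return {
            "tri": [[*k, v] for k, v in self.tri.items()],
            "weights": list(self.weights),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TransitionModel":
        model = cls.__new__(cls)
        model.uni, model.bi, model.tri = {}, {}, {}
        model.ctx1, model.ctx2 = {}, {}
        model.n_events = 0
        for t1, t2, t3, c in payload["tri"]:
            model.tri[(t1, t2, t3)] = c
            model.bi[(t2, t3)] = model.bi.get((t2, t3), 0) + c
            model.uni[t3] = model.uni.get(t3, 0) + c
            model.ctx1[t2] = model.ctx1.get(t2, 0) + c
            model.ctx2[(t1, t2)] = model.ctx2.get((t1, t2), 0) + c
            model.n_events += c
        model.weights = tuple(payload["weights"])
        return model


def build_transition_model(corpus: Sequence[TaggedSentence]) -> TransitionModel:
    return TransitionModel(corpus)


def transition_prob(model: TransitionModel, t: str, t_prev: str, t_prev2: str) -> float:
    return model.prob(t, t_prev, t_prev2)


@dataclass(frozen=True)
class TaggerConfig:
    """Cascade and suffix-predictor configuration.

    ``suffix_method`` selects the unknown-word predictor ("msl" or
    "interpolation"); ``counting_method`` the suffix counting scheme;
    ``interpolation_method`` the interpolation depth rule (1, 2 or 3).
    ``pattern_tags`` maps surface pattern kinds to the tag they emit; when
    None, numeric patterns map to the tag set's cardinal-number tag ("MC")
    if present, else the pattern branch is skipped.  ``beta_unseen`` is the
    discount applied to suffix-derived probabilities of a known word's
    unseen tags.
    """

    suffix_method: str = "msl"
    counting_method: str = "freq_n"
    interpolation_method: int = 3
    max_suffix_len: int = 5
    beta_unseen: float = 0.1
    pattern_tags: Optional[Dict[str, str]] = None

    def __post_init__(self):
        if self.suffix_method not in ("msl", "interpolation"):
            raise ValueError(f"unknown suffix method: {self.suffix_method}")

    def resolve_pattern_tags(self, tagset: TagSet) -> Dict[str, str]:
        if self.pattern_tags is not None:
            return {k: v for k, v in self.pattern_tags.items() if v in tagset}
        if "MC" in tagset:
            return {"number": "MC", "number_range": "MC", "ordinal": "MC"}
        return {}


class TaggerModel:
    """All trained components assembled behind the emission cascade."""

    def __init__(
        self,
        tagset: TagSet,
        lexicon: LexiconTable,
        suffix_table: SuffixTable,
        char_table: CharFeatureTable,
        transitions: TransitionModel,
        params: InterpolationParams,
        config: TaggerConfig,
    ):
        self.tagset = tagset
        self.lexicon = lexicon
        self.suffix_table = suffix_table
        self.char_table = char_table
        self.transitions = transitions
        self.params = params
        self.config = config
        self._pattern_tags = config.resolve_pattern_tags(tagset)
        self._trans_cache: Optional[np.ndarray] = None

    # ------------------------------------------------------------------ train
    @classmethod
    def train(
        cls,
        corpus: Sequence[TaggedSentence],
        tagset: Optional[TagSet] = None,
        config: Optional[TaggerConfig] = None,
    ) -> "TaggerModel":
        config = config or TaggerConfig()
        if tagset is None:
            seen = []
            for sent in corpus:
                for _, t in sent:
                    if t not in seen:
                        seen.append(t)
            tagset = TagSet(sorted(seen))
        lexicon = build_lexicon(corpus)
        suffix_table = build_suffix_table(
            lexicon, L_max=config.max_suffix_len, tagset=tagset
        )
        params = estimate_theta(
            suffix_table,
            counting=config.counting_method,
            depth_method=config.interpolation_method,
            tags=tagset.tags,
        )
        smooth_known_word_unseen_tags(
            lexicon, suffix_table, params, beta=config.beta_unseen
        )
        char_table = build_char_table(lexicon)
        transitions = build_transition_model(corpus)
        return cls(tagset, lexicon, suffix_table, char_table, transitions, params, config)

    def with_config(self, **changes) -> "TaggerModel":
        """Same trained tables under a different cascade configuration."""
        config = replace(self.config, **changes)
        params = InterpolationParams(
            theta=estimate_theta(
                self.suffix_table, counting=config.counting_method, tags=self.tagset.tags
            ).theta,
            counting=config.counting_method,
            depth_method=config.interpolation_method,
            L_max=self.suffix_table.L_max,
        )
        return TaggerModel(
            self.tagset, self.lexicon, self.suffix_table, self.char_table,
            self.transitions, params, config,
        )

    # --------------------------------------------------------------- emission
    def suffix_emission(self, word: str, tag: str) -> float:
        """The configured suffix predictor's P(word | tag)."""
        if self.config.suffix_method == "msl":
            return msl_word_given_tag(
                self.suffix_table, word, tag, self.config.counting_method
            )
        p = interpolate_tag_given_suffix(self.suffix_table, word, tag, self.params)
        return invert_to_word_given_tag(
            p, self.suffix_table, tag, self.config.counting_method
        )

    def emission_prob(self, token: Union[Token, str], tag: str) -> float:
        """Resolve p(w|t) through the cascade; exactly one branch fires."""
        if isinstance(token, str):
            token = Token.from_text(token)
        branch, scores = self._emission_branch(token)
        return scores(tag)

    def _emission_branch(self, token: Token):
        text = token.text
        hit = self.lexicon.lookup_case_independent(text)
        if hit is not None:
            return "lexicon", lambda tag: self.lexicon.smoothed_prob(hit, tag)
        if token.pattern != "none" and token.pattern in self._pattern_tags:
            target = self._pattern_tags[token.pattern]
            return "pattern", lambda tag: 1.0 if tag == target else 0.0
        if not token.is_all_lower:
            return "char_feature", lambda tag: char_mle(self.char_table, text, tag)
        return "suffix", lambda tag: self.suffix_emission(text, tag)

    def emission_branch_name(self, token: Union[Token, str]) -> str:
        if isinstance(token, str):
            token = Token.from_text(token)
        return self._emission_branch(token)[0]

    def _emission_row(self, token: Token) -> np.ndarray:
        _, scores = self._emission_branch(token)
        row = np.array([scores(t) for t in self.tagset.tags], dtype=float)
        if not np.any(row > 0.0):
            logger.info(
                "all-zero emission row for token %r; using uniform fallback",
                token.text,
            )
            row[:] = 1.0 / len(self.tagset)
        return row

    # ---------------------------------------------------------------- viterbi
    def _transition_tensor(self) -> np.ndarray:
        """log p(next | prev2, prev): axes (prev2, prev, next); tag indices
        0..k-1, BOS = k on the conditioning axes, EOS = k on the next axis."""
        if self._trans_cache is None:
            k = len(self.tagset)
            cond = list(self.tagset.tags) + [BOS]
            nxt = list(self.tagset.tags) + [EOS]
            T = np.empty((k + 1, k + 1, k + 1), dtype=float)
            for a, t1 in enumerate(cond):
                for b, t2 in enumerate(cond):
                    for c, t3 in enumerate(nxt):
                        T[a, b, c] = self.transitions.prob(t3, t2, t1)
            with np.errstate(divide="ignore"):
                self._trans_cache = np.log(T)
        return self._trans_cache

    def viterbi(self, sentence: Sequence[Union[Token, str]]) -> List[str]:
        """Maximum-probability tag sequence for one tokenized sentence."""
        if not sentence:
            raise ValueError("cannot decode an empty sentence")
        tokens = [Token.from_text(t) if isinstance(t, str) else t for t in sentence]
        k = len(self.tagset)
        Tlog = self._transition_tensor()
        with np.errstate(divide="ignore"):
            E = np.stack([np.log(self._emission_row(t)) for t in tokens])

        N = len(tokens)
        NEG = -np.inf
        V = np.full((k + 1, k + 1), NEG)
        V[k, k] = 0.0  # (BOS, BOS)
        backs = np.zeros((N, k + 1, k + 1), dtype=np.intp)
        for i in range(N):
            # scores[a, b, c] = V[a, b] + Tlog[a, b, c] + E[i, c]
            scores = V[:, :, None] + Tlog
            best_a = np.argmax(scores, axis=0)            # lowest index wins ties
            newV = np.take_along_axis(scores, best_a[None], axis=0)[0]
            newV = newV[:, :k] + E[i][None, :]
            full = np.full((k + 1, k + 1), NEG)
            full[:, :k] = newV
            backs[i] = np.pad(best_a[:, :k], ((0, 0), (0, 1)), constant_values=0)
            V = full
        # close with the EOS transition
        final = V + Tlog[:, :, k]
        final[:, k] = NEG
        flat = int(np.argmax(final))
        b, c = divmod(flat, k + 1)
        path = [c]
        prev_pair = (b, c)
        for i in range(N - 1, 0, -1):
            a = int(backs[i][prev_pair])
            path.append(prev_pair[0])
            prev_pair = (a, prev_pair[0])
        path.reverse()
        return [self.tagset.tags[i] for i in path]

    def path_logscore(self, sentence: Sequence[Union[Token, str]], tags: Sequence[str]) -> float:
        """Joint log-probability of a (sentence, tag sequence) pair,
        including the closing boundary transition."""
        tokens = [Token.from_text(t) if isinstance(t, str) else t for t in sentence]
        if len(tokens) != len(tags):
            raise ValueError("sentence and tag sequence lengths differ")
        rows = [self._emission_row(t) for t in tokens]
        seq = [BOS, BOS, *tags, EOS]
        score = 0.0
        for i, tag in enumerate(tags):
            p_t = self.transitions.prob(tag, seq[i + 1], seq[i])
            p_e = rows[i][self.tagset.index(tag)]
            if p_t <= 0.0 or p_e <= 0.0:
                return -math.inf
            score += math.log(p_t) + math.log(p_e)
        p_end = self.transitions.prob(EOS, seq[-2], seq[-3])
        return score + (math.log(p_end) if p_end > 0.0 else -math.inf)

    def tag_sentences(
        self, sentences: Sequence[Sequence[Union[Token, str]]]
    ) -> List[TaggedSentence]:
        out = []
        for sent in sentences:
            tags = self.viterbi(sent)
            words = [t.text if isinstance(t, Token) else t for t in sent]
            out.append(TaggedSentence(tuple(zip(words, tags))))
        return out

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        payload = {
            "format_version": _MODEL_FORMAT_VERSION,
            "tagset": list(self.tagset.tags),
            "lexicon": self.lexicon.to_dict(),
            "suffix_table": self.suffix_table.to_dict(),
            "char_table": self.char_table.to_dict(),
            "transitions": self.transitions.to_dict(),
            "params": {
                "theta": self.params.theta,
                "counting": self.params.counting,
                "depth_method": self.params.depth_method,
                "L_max": self.params.L_max,
            },
            "config": {
                "suffix_method": self.config.suffix_method,
                "counting_method": self.config.counting_method,
                "interpolation_method": self.config.interpolation_method,
                "max_suffix_len": self.config.max_suffix_len,
                "beta_unseen": self.config.beta_unseen,
                "pattern_tags": self.config.pattern_tags,
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TaggerModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model archive version")
        config = TaggerConfig(**payload["config"])
        params = InterpolationParams(**payload["params"])
        return cls(
            tagset=TagSet(payload["tagset"]),
            lexicon=LexiconTable.from_dict(payload["lexicon"]),
            suffix_table=SuffixTable.from_dict(payload["suffix_table"]),
            char_table=CharFeatureTable.from_dict(payload["char_table"]),
            transitions=TransitionModel.from_dict(payload["transitions"]),
            params=params,
            config=config,
        )


def emission_prob(model: TaggerModel, token: Union[Token, str], tag: str) -> float:
    return model.emission_prob(token, tag)


def viterbi(model: TaggerModel, sentence: Sequence[Union[Token, str]]) -> List[str]:
    return model.viterbi(sentence)
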