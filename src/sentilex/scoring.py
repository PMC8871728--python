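"""Weighted dictionary scoring of comments.

Each sentiment-bearing token (polarity word or emoji gloss) with base
weight B contributes Ei = A × C × B, where A is the product of the degree
adverb weights and C the product of the negation weights (−1 each) found in
its modifier scope — by default, all modifiers since the previous sentiment
word within the sentence.  Modifiers are consumed: they apply to at most one
sentiment word, and a modifier with no following sentiment word in scope
contributes nothing.  Sentence value Esi = Σ Ei, comment value E = Σ Esi,
and the label is the sign of E (|E| ≤ tolerance → neutral).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .types import Comment, Role, ScoredComment, SentimentLexicon, Token, WordScore

log = logging.getLogger(__name__)

SENTENCE_DELIMITERS = frozenset("。！？!?.;；\n")


@dataclass(frozen=True)
class ScoringConfig:
    modifier_scope: str | tuple = "since_last_sentiment_word"  # or ("fixed_window", k)
    composition: str = "multiplicative"
    neutral_tolerance: float = 1e-9

    def __post_init__(self):
        if self.neutral_tolerance < 0:
            raise ValueError("neutral_tolerance must be >= 0")
        if self.composition != "multiplicative":
            raise ValueError(f"unknown composition {self.composition!r}")


def split_sentences(tokens: Sequence[Token]) -> list[list[Token]]:
    """Split at sentence-final punctuation; delimiters are dropped, no
    empty sublists.  No delimiter → one sentence."""
    sentences: list[list[Token]] = []
    current: list[Token] = []
    for t in tokens:
        if t.kind == "word" and t.surface in SENTENCE_DELIMITERS:
            if current:
                sentences.append(current)
                current = []
        else:
            current.append(t)
    if current:
        sentences.append(current)
    return sentences


def score_sentence(
    sentence_tokens: Sequence[Token],
    lexicon: SentimentLexicon,
    config: ScoringConfig = ScoringConfig(),
) -> tuple[float, list[WordScore]]:
    """Left-to-right scan applying Ei = (Π A) × (Π C) × B per sentiment word."""
    window = None
    if isinstance(config.modifier_scope, tuple):
        if config.modifier_scope[0] != "fixed_window":
            raise ValueError(f"unknown modifier scope {config.modifier_scope!r}")
        window = int(config.modifier_scope[1])
    elif config.modifier_scope != "since_last_sentiment_word":
        raise ValueError(f"unknown modifier scope {config.modifier_scope!r}")

    word_scores: list[WordScore] = []
    # pending modifiers since the previous sentiment word: (index, role, weight)
    pending: list[tuple[int, Role, float]] = []
    for i, tok in enumerate(sentence_tokens):
        entry = lexicon.lookup(tok.surface)
        if entry is None:
            continue
        if entry.role in (Role.degree_adverb, Role.negation):
            pending.append((i, entry.role, entry.weight))
            continue
        # polarity or emoji: collect modifiers in scope, then consume them
        in_scope = pending if window is None else [m for m in pending if i - m[0] <= window]
        a = c = 1.0
        for _, role, w in in_scope:
            if role is Role.degree_adverb:
                a *= w
            else:
                c *= w
        word_scores.append(
            WordScore(
                position=tok.position,
                word=tok.surface,
                base_weight=entry.weight,
                degree_weight=a,
                negation_weight=c,
            )
        )
        pending = []
    esi = sum(ws.value for ws in word_scores)
    return esi, word_scores


def _label(e: float, tol: float) -> str:
    if e > tol:
        return "positive"
    if e < -tol:
        return "negative"
    return "neutral"


def score_comment(
    comment: Comment,
    lexicon: SentimentLexicon,
    config: ScoringConfig = ScoringConfig(),
) -> ScoredComment:
    """Score a tokenized comment: E = Σ Esi, label = sign(E)."""
    sentence_scores: list[float] = []
    word_scores: list[WordScore] = []
    for sent in split_sentences(comment.tokens):
        esi, ws = score_sentence(sent, lexicon, config)
        sentence_scores.append(esi)
        word_scores.extend(ws)
    e = sum(sentence_scores)
    return ScoredComment(
        comment=comment,
        sentence_scores=sentence_scores,
        total=e,
        label=_label(e, config.neutral_tolerance),
        word_scores=word_scores,
    )


def batch_score(
    comments: Sequence[Comment],
    lexicon: SentimentLexicon,
    config: ScoringConfig = ScoringConfig(),
) -> tuple[list[ScoredComment], list[tuple[str, str]]]:
    """Order-preserving map of score_comment; per-comment failures isolated.

    Returns (scored, errors) where errors hold (comment id, reason).
    """
    scored: list[ScoredComment] = []
    errors: list[tuple[str, str]] = []
    for i, c in enumerate(comments, start=1):
        try:
            scored.append(score_comment(c, lexicon, config))
        except Exception as exc:  # defensive: a bad comment must not kill the run
            errors.append((c.id, str(exc)))
        if i % 10_000 == 0:
            log.info("scored %d comments", i)
    return scored, errors


class DictionarySentimentScorer(BaseEstimator):
    """Dictionary-method sentiment classifier over tokenized comments.

    Parameters mirror ScoringConfig; ``lexicon`` is the merged sentiment
    lexicon.  fit() validates the lexicon; predict(X) returns labels,
    decision_function(X) the raw comment values E, and score_comments(X)
    the full per-word audit.  X is a sequence of Comment objects (already
    tokenized) or plain token lists.
    """

    def __init__(
        self,
        lexicon: SentimentLexicon | None = None,
        modifier_scope="since_last_sentiment_word",
        neutral_tolerance: float = 1e-9,
    ):
        self.lexicon = lexicon
        self.modifier_scope = modifier_scope
        self.neutral_tolerance = neutral_tolerance

    def _config(self) -> ScoringConfig:
        return ScoringConfig(
            modifier_scope=self.modifier_scope, neutral_tolerance=self.neutral_tolerance
        )

    def fit(self, X=None, y=None):
        if self.lexicon is None or len(self.lexicon) == 0:
            raise ValueError("a non-empty lexicon is required")
        self._config()  # validates parameters
        self.n_entries_ = len(self.lexicon)
        return self

    @staticmethod
    def _as_comment(x, i: int) -> Comment:
        if isinstance(x, Comment):
            return x
        import datetime as _dt

        tokens = [
            t if isinstance(t, Token) else Token(surface=t, position=j)
            for j, t in enumerate(x)
        ]
        return Comment(
            id=f"x{i}", timestamp=_dt.datetime(1970, 1, 1), user_id="", tokens=tokens
        )

    def score_comments(self, X) -> list[ScoredComment]:
        if not hasattr(self, "n_entries_"):
            self.fit()
        cfg = self._config()
        return [score_comment(self._as_comment(x, i), self.lexicon, cfg) for i, x in enumerate(X)]

    def decision_function(self, X) -> np.ndarray:
        return np.array([sc.total for sc in self.score_comments(X)])

    def predict(self, X) -> np.ndarray:
        return np.array([sc.label for sc in self.score_comments(X)], dtype=object)
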