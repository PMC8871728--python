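"""Automated lexicon induction: TF-IDF term ranking, TextRank keyword
extraction and SO-PMI polarity expansion, as scikit-learn style estimators
with thin function wrappers.

TF-IDF here uses the classical corpus form score(w) = tf(w) · ln(N / df(w))
with tf the raw corpus frequency — it nominates candidate degree adverbs for
human level assignment.  TextRank runs the damped iteration

    WS(v) = (1 − d) + d · Σ_{u ∈ adj(v)} WS(u) / deg(u)

on the undirected word co-occurrence graph (edge iff two words co-occur
within ``window_size`` tokens) and nominates seed sentiment words.  The
SO-PMI classifier assigns ±1 polarity to candidate words by the sign of
their semantic orientation against positive/negative seed vocabularies.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .cooccurrence import SeedSet, build_cooccurrence, classify_by_sopmi, so_pmi
from .types import LexiconEntry, Role, SentimentLexicon


@dataclass(frozen=True)
class RankedTerm:
    word: str
    score: float
    rank: int  # 1-based, non-increasing score, ties lexicographic


def _surfaces(doc) -> list[str]:
    return [t.surface if hasattr(t, "surface") else t for t in doc]


def _ranked(scores: dict[str, float], top_k: int | None) -> list[RankedTerm]:
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ordered = ordered[:top_k]
    return [RankedTerm(word=w, score=s, rank=i + 1) for i, (w, s) in enumerate(ordered)]


def tfidf_rank(
    token_docs: Sequence[Sequence],
    candidate_filter: Callable[[str], bool] | None = None,
    top_k: int = 100,
    exclude: Iterable[str] = (),
) -> list[RankedTerm]:
    """Rank candidate terms by tf(w)·ln(N/df(w)); drop ``exclude`` words.

    ``exclude`` mirrors the dedupe step against an existing degree-adverb
    dictionary; ``candidate_filter`` restricts which tokens compete (e.g. a
    supplied adverb candidate list or a POS predicate).
    """
    if not token_docs:
        raise ValueError("empty corpus")
    excl = set(exclude)
    n_docs = len(token_docs)
    tf: Counter[str] = Counter()
    df: Counter[str] = Counter()
    for doc in token_docs:
        s = _surfaces(doc)
        tf.update(s)
        df.update(set(s))
    scores = {
        w: tf[w] * math.log(n_docs / df[w])
        for w in tf
        if w not in excl and (candidate_filter is None or candidate_filter(w))
    }
    return _ranked(scores, top_k)


def _textrank_graph(token_docs: Sequence[Sequence], window_size: int) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for doc in token_docs:
        s = _surfaces(doc)
        for w in s:
            adj.setdefault(w, set())
        for i, w1 in enumerate(s):
            for w2 in s[i + 1 : i + window_size]:
                if w1 != w2:
                    adj[w1].add(w2)
                    adj[w2].add(w1)
    return adj


def textrank_keywords(
    token_docs: Sequence[Sequence],
    window_size: int = 5,
    damping: float = 0.85,
    tol: float = 1e-6,
    max_iter: int = 200,
    top_k: int | None = None,
) -> list[RankedTerm]:
    """Damped iterative ranking on the word co-occurrence graph.

    Scores are invariant to document order; isolated words keep the
    baseline score 1 − d.  Non-convergence within ``max_iter`` warns and
    returns the last iterate.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    adj = _textrank_graph(token_docs, window_size)
    if not adj:
        return []
    nodes = sorted(adj)
    index = {w: i for i, w in enumerate(nodes)}
    deg = np.array([max(len(adj[w]), 1) for w in nodes], dtype=float)
    ws = np.ones(len(nodes), dtype=float)
    neighbors = [np.array([index[u] for u in sorted(adj[w])], dtype=int) for w in nodes]
    for _ in range(max_iter):
        contrib = ws / deg
        new = np.array(
            [(1.0 - damping) + damping * contrib[nb].sum() for nb in neighbors]
        )
        delta = np.abs(new - ws).max()
        ws = new
        if delta < tol:
            break
    else:
        warnings.warn(f"TextRank did not converge in {max_iter} iterations")
    return _ranked({w: float(ws[index[w]]) for w in nodes}, top_k)


def expand_lexicon(
    labels: dict[str, str], provenance: str = "sopmi_expanded"
) -> SentimentLexicon:
    """Turn SO-PMI polarity labels into ±1 lexicon entries; neutral excluded."""
    frag = SentimentLexicon()
    for word, label in labels.items():
        if label == "neutral":
            continue
        frag.add(
            LexiconEntry(
                word=word,
                role=Role.polarity,
                weight=1.0 if label == "positive" else -1.0,
                provenance=provenance,
            )
        )
    return frag


class SoPmiPolarityClassifier(BaseEstimator):
    """Assigns polarity to candidate words by the sign of SO-PMI.

    fit(X) consumes tokenized documents (lists of tokens or strings) and
    builds the co-occurrence model; predict(words) returns labels in
    {"positive", "neutral", "negative"}; decision_function(words) returns
    the raw SO-PMI values.
    """

    def __init__(
        self,
        positive_seeds: Iterable[str] = (),
        negative_seeds: Iterable[str] = (),
        smoothing: float = 1.0,
        neutral_tol: float = 1e-12,
        window="document",
    ):
        self.positive_seeds = positive_seeds
        self.negative_seeds = negative_seeds
        self.smoothing = smoothing
        self.neutral_tol = neutral_tol
        self.window = window

    def fit(self, X, y=None):
        self.seeds_ = SeedSet(frozenset(self.positive_seeds), frozenset(self.negative_seeds))
        self.model_ = build_cooccurrence(X, window=self.window)
        self.n_docs_ = self.model_.n_units
        return self

    def decision_function(self, words: Iterable[str]) -> np.ndarray:
        return np.array(
            [so_pmi(self.model_, w, self.seeds_, smoothing=self.smoothing) for w in words]
        )

    def predict(self, words: Sequence[str]) -> np.ndarray:
        labels = classify_by_sopmi(
            words, self.model_, self.seeds_,
            smoothing=self.smoothing, neutral_tol=self.neutral_tol,
        )
        return np.array([labels[w] for w in words], dtype=object)

    def expanded_lexicon(self, words: Sequence[str]) -> SentimentLexicon:
        labels = classify_by_sopmi(
            words, self.model_, self.seeds_,
            smoothing=self.smoothing, neutral_tol=self.neutral_tol,
        )
        return expand_lexicon(labels)


class TfidfTermRanker(BaseEstimator):
    """fit(X) ranks candidate terms by corpus TF-IDF into ``ranking_``."""

    def __init__(self, candidate_filter=None, top_k: int = 100, exclude: Iterable[str] = ()):
        self.candidate_filter = candidate_filter
        self.top_k = top_k
        self.exclude = exclude

    def fit(self, X, y=None):
        self.ranking_ = tfidf_rank(
            X, candidate_filter=self.candidate_filter, top_k=self.top_k, exclude=self.exclude
        )
        return self


class TextRankKeywordExtractor(BaseEstimator):
    """fit(X) scores words on the co-occurrence graph into ``ranking_``."""

    def __init__(
        self,
        window_size: int = 5,
        damping: float = 0.85,
        tol: float = 1e-6,
        max_iter: int = 200,
        top_k: int | None = None,
    ):
        self.window_size = window_size
        self.damping = damping
        self.tol = tol
        self.max_iter = max_iter
        self.top_k = top_k

    def fit(self, X, y=None):
        self.ranking_ = textrank_keywords(
            X,
            window_size=self.window_size,
            damping=self.damping,
            tol=self.tol,
            max_iter=self.max_iter,
            top_k=self.top_k,
        )
        return self
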