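"""Co-occurrence counting, pointwise mutual information and SO-PMI.

PMI(w1, w2) = log2( P(w1 & w2) / (P(w1) · P(w2)) ), with probabilities
estimated as document (or sliding-window) frequencies over the corpus.
The semantic orientation of a candidate word is

    SO-PMI(w) = Σ_{p ∈ positive seeds} PMI(w, p) − Σ_{n ∈ negative seeds} PMI(w, n)

and its sign assigns polarity: > 0 positive, < 0 negative, = 0 neutral.
Additive smoothing ε (default 1, applied to the pair count) avoids log-zero;
ε = 0 reproduces the bare formula and raises on a zero co-occurrence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

log = logging.getLogger(__name__)


class UnseenWordError(KeyError):
    """Word has zero document frequency in the co-occurrence model."""


class ZeroCooccurrenceError(ValueError):
    """P(w1 & w2) = 0 with smoothing disabled: bare PMI is −∞."""


@dataclass(frozen=True)
class SeedSet:
    """Positive/negative seed vocabularies for SO-PMI."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))
        if not self.positives or not self.negatives:
            raise ValueError("both seed sets must be non-empty")
        if self.positives & self.negatives:
            raise ValueError("seed sets must be disjoint")

    def swapped(self) -> "SeedSet":
        return SeedSet(self.negatives, self.positives)


@dataclass
class CooccurrenceModel:
    n_units: int  # documents, or sliding windows
    doc_freq: dict[str, int] = field(default_factory=dict)
    pair_doc_freq: dict[tuple[str, str], int] = field(default_factory=dict)
    window: str = "document"

    def df(self, w: str) -> int:
        return self.doc_freq.get(w, 0)

    def pair(self, w1: str, w2: str) -> int:
        return self.pair_doc_freq.get((min(w1, w2), max(w1, w2)), 0)


def _iter_units(token_docs: Sequence[Sequence], window) -> Iterable[frozenset[str]]:
    def surfaces(doc):
        return [t.surface if hasattr(t, "surface") else t for t in doc]

    if window == "document":
        for doc in token_docs:
            yield frozenset(surfaces(doc))
    elif isinstance(window, tuple) and window[0] == "sliding":
        k = int(window[1])
        if k < 2:
            raise ValueError("sliding window size must be >= 2")
        for doc in token_docs:
            s = surfaces(doc)
            if len(s) <= k:
                yield frozenset(s)
            else:
                for i in range(len(s) - k + 1):
                    yield frozenset(s[i : i + k])
    else:
        raise ValueError(f"unknown window {window!r}")


def build_cooccurrence(token_docs: Sequence[Sequence], window="document") -> CooccurrenceModel:
    """Count exact document (or window) frequencies for words and pairs."""
    if not token_docs:
        raise ValueError("empty corpus")
    model = CooccurrenceModel(n_units=0, window="document" if window == "document" else "sliding")
    for unit in _iter_units(token_docs, window):
        model.n_units += 1
        for w in unit:
            model.doc_freq[w] = model.doc_freq.get(w, 0) + 1
        for w1, w2 in combinations(sorted(unit), 2):
            model.pair_doc_freq[(w1, w2)] = model.pair_doc_freq.get((w1, w2), 0) + 1
    return model


def pmi(model: CooccurrenceModel, w1: str, w2: str, smoothing: float = 1.0) -> float:
    """log2[(P12 + ε′) / (P1·P2 + ε′)] with ε′ = ε / n_units."""
    n = model.n_units
    df1, df2 = model.df(w1), model.df(w2)
    if df1 == 0:
        raise UnseenWordError(w1)
    if df2 == 0:
        raise UnseenWordError(w2)
    p1, p2 = df1 / n, df2 / n
    p12 = model.pair(w1, w2) / n
    eps = smoothing / n
    if eps == 0.0 and p12 == 0.0:
        raise ZeroCooccurrenceError(f"{w1!r} and {w2!r} never co-occur (ε = 0)")
    return math.log2((p12 + eps) / (p1 * p2 + eps))


def so_pmi(model: CooccurrenceModel, word: str, seeds: SeedSet, smoothing: float = 1.0) -> float:
    """Positive-seed PMI sum minus negative-seed PMI sum.

    Seeds absent from the corpus contribute 0 (logged once per call).
    """
    total = 0.0
    for sign, group in ((+1.0, seeds.positives), (-1.0, seeds.negatives)):
        for seed in sorted(group):
            if model.df(seed) == 0:
                log.debug("seed %r unseen in corpus; contributes 0", seed)
                continue
            total += sign * pmi(model, word, seed, smoothing=smoothing)
    return total


def classify_by_sopmi(
    candidates: Iterable[str],
    model: CooccurrenceModel,
    seeds: SeedSet,
    smoothing: float = 1.0,
    neutral_tol: float = 1e-12,
) -> dict[str, str]:
    """Sign rule: SO-PMI > 0 positive, < 0 negative, |·| ≤ τ neutral."""
    out: dict[str, str] = {}
    for w in candidates:
        v = so_pmi(model, w, seeds, smoothing=smoothing)
        if v > neutral_tol:
            out[w] = "positive"
        elif v < -neutral_tol:
            out[w] = "negative"
        else:
            out[w] = "neutral"
    return out
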