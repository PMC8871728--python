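"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: counting is nested-loop,
scoring re-derives each word's modifier scope by direct index arithmetic,
and TextRank is a naive dict-based fixed-point iteration.
"""

from __future__ import annotations

import math
from itertools import combinations

from sentilex.types import Role


def brute_force_sentence_score(tokens, lexicon):
    """Direct evaluation of Ei = (Π A)(Π C)B with scope = since the
    previous sentiment word, no scan state."""
    entries = [lexicon.lookup(t.surface) for t in tokens]
    sent_idx = [
        i for i, e in enumerate(entries) if e is not None and e.role in (Role.polarity, Role.emoji)
    ]
    values = []
    for k, i in enumerate(sent_idx):
        prev = sent_idx[k - 1] if k > 0 else -1
        a = c = 1.0
        for x in range(prev + 1, i):
            e = entries[x]
            if e is None:
                continue
            if e.role is Role.degree_adverb:
                a *= e.weight
            elif e.role is Role.negation:
                c *= e.weight
        values.append(a * c * entries[i].weight)
    return sum(values), values


def brute_force_counts(docs):
    """Nested-loop document/pair frequencies over token-surface docs."""
    sets = [set(d) for d in docs]
    vocab = sorted(set().union(*sets)) if sets else []
    df = {w: sum(1 for s in sets if w in s) for w in vocab}
    pair = {}
    for w1, w2 in combinations(vocab, 2):
        pair[(w1, w2)] = sum(1 for s in sets if w1 in s and w2 in s)
    return len(docs), df, pair


def direct_pmi(n, df, pair, w1, w2):
    """Bare-formula PMI from raw counts (no smoothing)."""
    key = (min(w1, w2), max(w1, w2))
    p12 = pair.get(key, 0) / n
    return math.log2(p12 / ((df[w1] / n) * (df[w2] / n)))


def textrank_power_iteration(adjacency: dict[str, set[str]], damping=0.85, sweeps=500):
    """Naive fixed-point iteration of WS(v) = (1-d) + d·Σ WS(u)/deg(u)."""
    ws = {v: 1.0 for v in adjacency}
    for _ in range(sweeps):
        new = {}
        for v in adjacency:
            acc = sum(ws[u] / max(len(adjacency[u]), 1) for u in adjacency[v])
            new[v] = (1.0 - damping) + damping * acc
        if max(abs(new[v] - ws[v]) for v in adjacency) < 1e-13:
            ws = new
            break
        ws = new
    return ws


def window_graph(docs, window_size):
    """Co-occurrence graph by direct pairwise position comparison."""
    adj: dict[str, set[str]] = {}
    for doc in docs:
        for w in doc:
            adj.setdefault(w, set())
        for i in range(len(doc)):
            for j in range(len(doc)):
                if i != j and abs(i - j) < window_size and doc[i] != doc[j]:
                    adj[doc[i]].add(doc[j])
    return adj


def merge_by_rules(fragment_entry_lists):
    """Word-by-word reapplication of the precedence rules: pick the entries
    with the highest role precedence; among those the last fragment wins."""
    from sentilex.types import ROLE_PRECEDENCE

    by_word: dict[str, list] = {}
    for entries in fragment_entry_lists:
        for e in entries:
            by_word.setdefault(e.word, []).append(e)
    out = {}
    for word, candidates in by_word.items():
        best = max(ROLE_PRECEDENCE[e.role] for e in candidates)
        out[word] = [e for e in candidates if ROLE_PRECEDENCE[e.role] == best][-1]
    return out
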