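import numpy as np
import pytest

from sentilex.synthetic import SyntheticSpec, generate_corpus, make_lexicon
from sentilex.types import (
    DEGREE_WEIGHTS,
    DegreeLevel,
    LexiconEntry,
    NEGATION_WEIGHT,
    Role,
    SentimentLexicon,
    Token,
)


@pytest.fixture(scope="session")
def small_lexicon() -> SentimentLexicon:
    """Hand-built lexicon: one adverb per level, two negations, ±1 polarity
    words and one emoji gloss of each sign."""
    lex = SentimentLexicon()
    lex.add(LexiconEntry("happy", Role.polarity, 1.0))
    lex.add(LexiconEntry("great", Role.polarity, 1.0))
    lex.add(LexiconEntry("awful", Role.polarity, -1.0))
    lex.add(LexiconEntry("sad", Role.polarity, -1.0))
    for level in DegreeLevel:
        lex.add(
            LexiconEntry(f"adv_{level.value}", Role.degree_adverb, DEGREE_WEIGHTS[level], level=level)
        )
    lex.add(LexiconEntry("not", Role.negation, NEGATION_WEIGHT))
    lex.add(LexiconEntry("never", Role.negation, NEGATION_WEIGHT))
    lex.add(LexiconEntry("smile", Role.emoji, 1.0, provenance="emoji"))
    lex.add(LexiconEntry("tears", Role.emoji, -1.0, provenance="emoji"))
    return lex


def toks(*surfaces: str) -> list[Token]:
    return [Token(surface=s, position=i) for i, s in enumerate(surfaces)]


@pytest.fixture(scope="session")
def synth_lexicon():
    spec = SyntheticSpec(seed=0)
    return make_lexicon(spec)


@pytest.fixture(scope="session")
def random_sentence_factory(synth_lexicon):
    """Random token sentences over the synthetic lexicon plus distractors,
    stressing every role combination (runs of modifiers, orphans, emoji)."""
    lexicon, vocab = synth_lexicon
    pools = (
        vocab.positive
        + vocab.negative
        + [w for w, _ in vocab.adverbs]
        + vocab.negations
        + vocab.emoji_positive
        + vocab.emoji_negative
        + vocab.distractors[:40]
    )
    # weight modifiers and sentiment words up so interactions are frequent
    weights = np.array(
        [3.0 if not p.startswith("fill") else 1.0 for p in pools], dtype=float
    )
    weights /= weights.sum()

    def make(rng: np.random.Generator, n_tokens: int) -> list[Token]:
        idx = rng.choice(len(pools), size=n_tokens, p=weights)
        out = []
        for i, k in enumerate(idx):
            surf = pools[int(k)]
            kind = "emoji_gloss" if surf.startswith("emo") else "word"
            out.append(Token(surface=surf, kind=kind, position=i))
        return out

    return make


@pytest.fixture(scope="session")
def medium_corpus():
    """~1,200-comment corpus with planted duplicates/invalids, shared across
    integration-style tests."""
    spec = SyntheticSpec(seed=42, n_days=6, volume_curve=("constant", 200))
    return generate_corpus(spec)
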