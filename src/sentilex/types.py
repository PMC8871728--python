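"""Domain types: comments, tokens, lexicon entries and the merged sentiment lexicon.

The lexicon model follows the standard dictionary-method decomposition for
Chinese microblog text: *polarity* words carry a base weight B (±1 by
convention, graded weights allowed), *negation* ("privative") words carry a
fixed weight C = −1, *degree adverbs* carry an intensity weight A drawn from
six fixed levels, and *emoji glosses* behave like polarity words.  A scored
sentiment word contributes A × C × B to its sentence.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field


class Role(str, enum.Enum):
    """What a lexicon word does during scoring."""

    polarity = "polarity"
    negation = "negation"
    degree_adverb = "degree_adverb"
    emoji = "emoji"


class DegreeLevel(str, enum.Enum):
    """Six intensity levels for degree adverbs, strongest to weakest."""

    extremely_most = "extremely_most"
    super = "super"
    very = "very"
    relatively = "relatively"
    slightly = "slightly"
    under = "under"


#: Fixed weight A for each degree-adverb level.
DEGREE_WEIGHTS: dict[DegreeLevel, float] = {
    DegreeLevel.extremely_most: 2.0,
    DegreeLevel.super: 1.5,
    DegreeLevel.very: 1.25,
    DegreeLevel.relatively: 1.2,
    DegreeLevel.slightly: 0.8,
    DegreeLevel.under: 0.5,
}

#: Fixed weight C for negation words.
NEGATION_WEIGHT: float = -1.0

#: Merge precedence when one surface form occurs in several dictionaries
#: (higher wins).  Negation first prevents scope errors: a word that can
#: negate must keep that role or polarity flips are silently lost.
ROLE_PRECEDENCE: dict[Role, int] = {
    Role.negation: 3,
    Role.degree_adverb: 2,
    Role.emoji: 1,
    Role.polarity: 0,
}

REGION_BUCKETS = ("eastern", "central", "western", "northeast", "overseas", "unspecified")
DOMESTIC_BUCKETS = ("eastern", "central", "western", "northeast")


class LexiconValidationError(ValueError):
    """A lexicon entry or file violates the weight/level invariants."""


@dataclass(frozen=True)
class Token:
    surface: str
    kind: str = "word"  # "word" | "emoji_gloss"
    position: int = 0

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if self.kind not in ("word", "emoji_gloss"):
            raise ValueError(f"unknown token kind {self.kind!r}")


@dataclass
class Comment:
    """One social-media comment; ``tokens`` is empty until preprocessing."""

    id: str
    timestamp: _dt.datetime
    user_id: str
    region: str = ""
    gender: str = "unknown"  # female | male | unknown
    text: str = ""
    tokens: list[Token] = field(default_factory=list)


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    role: Role
    weight: float
    level: DegreeLevel | None = None
    provenance: str = "base"  # base | user_defined | tfidf_adverb | sopmi_expanded | emoji

    def __post_init__(self) -> None:
        if not self.word:
            raise LexiconValidationError("lexicon word must be non-empty")
        if self.role is Role.negation and self.weight != NEGATION_WEIGHT:
            raise LexiconValidationError(
                f"negation word {self.word!r} must have weight -1, got {self.weight}"
            )
        if self.role is Role.degree_adverb:
            if self.level is None:
                raise LexiconValidationError(
                    f"degree adverb {self.word!r} needs a level"
                )
            expected = DEGREE_WEIGHTS[self.level]
            if self.weight != expected:
                raise LexiconValidationError(
                    f"degree adverb {self.word!r} level {self.level.value} "
                    f"requires weight {expected}, got {self.weight}"
                )
        elif self.level is not None:
            raise LexiconValidationError(
                f"{self.word!r}: level is only valid for degree adverbs"
            )

    def validate_strict(self) -> None:
        """Strict mode: polarity/emoji base weights restricted to ±1."""
        if self.role in (Role.polarity, Role.emoji) and self.weight not in (1.0, -1.0):
            raise LexiconValidationError(
                f"{self.role.value} word {self.word!r}: strict mode requires weight "
                f"±1, got {self.weight}"
            )


@dataclass
class SentimentLexicon:
    """One role/weight per surface form; lookup is total (absent → None)."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def lookup(self, word: str) -> LexiconEntry | None:
        return self.entries.get(word)

    def words(self, role: Role | None = None) -> set[str]:
        if role is None:
            return set(self.entries)
        return {w for w, e in self.entries.items() if e.role is role}

    def add(self, entry: LexiconEntry) -> None:
        self.entries[entry.word] = entry


@dataclass(frozen=True)
class WordScore:
    """Per-word audit record: Ei = A-product × C-product × B."""

    position: int
    word: str
    base_weight: float
    degree_weight: float = 1.0
    negation_weight: float = 1.0

    @property
    def value(self) -> float:
        return self.degree_weight * self.negation_weight * self.base_weight


@dataclass
class ScoredComment:
    comment: Comment
    sentence_scores: list[float]
    total: float  # E
    label: str  # positive | neutral | negative
    word_scores: list[WordScore] = field(default_factory=list)


class RegionMap:
    """Total map from free-text province/area strings to region buckets.

    Unknown or empty strings fall back to ``unspecified``.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        mapping = dict(mapping or {})
        for prov, bucket in mapping.items():
            if bucket not in REGION_BUCKETS:
                raise ValueError(f"unknown region bucket {bucket!r} for {prov!r}")
        self.mapping = mapping

    def bucket(self, region: str) -> str:
        if not region or not region.strip():
            return "unspecified"
        return self.mapping.get(region.strip(), "unspecified")
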