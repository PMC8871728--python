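"""Cleaning, emoji normalization, tokenization and stop-word filtering.

Cleaning removes repeated, invalid and irrelevant records and orders the
stream chronologically.  Emoji are normalized to bracket-marked glosses
("[smile]") that survive tokenization as atomic ``emoji_gloss`` tokens;
emoji with no known sentiment gloss are deleted.  The built-in segmenter is
a deterministic greedy longest-match over the user dictionary with a
character-by-character fallback; a statistical segmenter can be plugged in
behind the same contract.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .types import Comment, Role, SentimentLexicon, Token

log = logging.getLogger(__name__)

#: Default "irrelevant data" patterns: URL-only comments and ad keywords.
DEFAULT_INVALID_PATTERNS = (
    r"^\s*(https?://\S+\s*)+$",
    r"(代购|推广链接|加微信)",
)


@dataclass
class CleaningRules:
    dedupe_scope: str = "user_text"  # "user_text" | "text"
    invalid_patterns: tuple[str, ...] = DEFAULT_INVALID_PATTERNS
    drop_empty: bool = True


@dataclass
class CleaningReport:
    n_input: int = 0
    n_duplicates_removed: int = 0
    n_invalid_removed: int = 0
    n_output: int = 0
    per_rule: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_output == self.n_input - self.n_duplicates_removed - self.n_invalid_removed
        assert min(self.n_input, self.n_output, self.n_duplicates_removed,
                   self.n_invalid_removed) >= 0


def _norm_text(text: str) -> str:
    return " ".join(text.split())


def clean_comments(
    comments: Sequence[Comment], rules: CleaningRules | None = None
) -> tuple[list[Comment], CleaningReport]:
    """Remove invalid and duplicated records; sort by (timestamp, id).

    Invalid records (empty text, configured irrelevant patterns) are removed
    first, then duplicates (same dedupe key, first occurrence kept).  Every
    removal is counted in the report; nothing is dropped silently.
    Idempotent: cleaning a cleaned stream changes nothing.
    """
    rules = rules or CleaningRules()
    report = CleaningReport(n_input=len(comments))
    compiled = [(p, re.compile(p)) for p in rules.invalid_patterns]

    valid: list[Comment] = []
    for c in comments:
        if rules.drop_empty and not c.text.strip():
            report.n_invalid_removed += 1
            report.per_rule["empty_text"] = report.per_rule.get("empty_text", 0) + 1
            continue
        hit = next((p for p, rx in compiled if rx.search(c.text)), None)
        if hit is not None:
            report.n_invalid_removed += 1
            report.per_rule[hit] = report.per_rule.get(hit, 0) + 1
            continue
        valid.append(c)

    seen: set = set()
    kept: list[Comment] = []
    for c in sorted(valid, key=lambda c: (c.timestamp, c.id)):
        key = (
            (c.user_id, _norm_text(c.text))
            if rules.dedupe_scope == "user_text"
            else _norm_text(c.text)
        )
        if key in seen:
            report.n_duplicates_removed += 1
            report.per_rule["duplicate"] = report.per_rule.get("duplicate", 0) + 1
            continue
        seen.add(key)
        kept.append(c)

    report.n_output = len(kept)
    report.check()
    return kept, report


_BRACKET_RE = re.compile(r"\[([^\[\]]+)\]")


def normalize_emojis(
    text: str,
    emoji_lexicon: SentimentLexicon,
    code_map: dict[str, str] | None = None,
) -> str:
    """Replace known emoji with "[gloss]" tokens; delete unknown emoji.

    ``code_map`` maps raw platform emoji codes (unicode emoji characters or
    platform shortcodes) to glosses.  Bracket-marked spans already in the
    text are kept when their gloss carries a sentiment entry and deleted
    otherwise (mirroring the pruning of emoji with no clear emotional
    tendency).
    """
    glosses = emoji_lexicon.words(Role.emoji)
    if code_map:
        # longest code first so multi-char codes are not shadowed
        for code in sorted(code_map, key=len, reverse=True):
            gloss = code_map[code]
            repl = f"[{gloss}]" if gloss in glosses else ""
            if not repl:
                log.debug("dropping emoji code %r (no sentiment gloss)", code)
            text = text.replace(code, repl)

    def _sub(m: re.Match) -> str:
        if m.group(1) in glosses:
            return m.group(0)
        log.debug("dropping unknown emoji %r", m.group(0))
        return ""

    return _BRACKET_RE.sub(_sub, text)


def greedy_segment(chunk: str, dictionary: frozenset[str] | set[str], max_len: int) -> list[str]:
    """Deterministic longest-match-first segmentation; single chars otherwise."""
    out: list[str] = []
    i, n = 0, len(chunk)
    while i < n:
        match = None
        for L in range(min(max_len, n - i), 1, -1):
            cand = chunk[i : i + L]
            if cand in dictionary:
                match = cand
                break
        if match is None:
            match = chunk[i]
        out.append(match)
        i += len(match)
    return out


def tokenize(
    text: str,
    lexicon_words: Iterable[str] = (),
    segmenter: Callable[[str], list[str]] | None = None,
) -> list[Token]:
    """Segment text into tokens; dictionary words and emoji glosses stay atomic.

    Bracket-marked spans become single ``emoji_gloss`` tokens (surface is the
    gloss without brackets).  Remaining spans are split on whitespace, then
    each chunk is segmented: a chunk that is itself a dictionary word is one
    token; otherwise the pluggable ``segmenter`` (default: greedy longest
    match over ``lexicon_words``, character-by-character fallback) applies.
    """
    dictionary = frozenset(lexicon_words)
    max_len = max((len(w) for w in dictionary), default=1)
    if segmenter is None:
        segmenter = lambda chunk: greedy_segment(chunk, dictionary, max_len)

    tokens: list[Token] = []
    pos = 0
    # re.split with one capture group alternates plain / captured pieces:
    # odd indices are bracket-marked glosses.
    for idx, piece in enumerate(_BRACKET_RE.split(text)):
        if not piece:
            continue
        if idx % 2 == 1:
            tokens.append(Token(surface=piece, kind="emoji_gloss", position=pos))
            pos += 1
            continue
        for chunk in piece.split():
            if chunk in dictionary:
                surfaces = [chunk]
            else:
                surfaces = segmenter(chunk)
            for s in surfaces:
                if s:
                    tokens.append(Token(surface=s, kind="word", position=pos))
                    pos += 1
    return tokens


def remove_stopwords(tokens: Sequence[Token], stoplist: Iterable[str]) -> list[Token]:
    """Filter stop-word tokens, preserving order and positions.

    Emoji-gloss tokens are exempt: they carry sentiment weight and must
    reach the scorer even if a gloss collides with a stop word.
    """
    stop = set(stoplist)
    return [t for t in tokens if t.kind == "emoji_gloss" or t.surface not in stop]
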