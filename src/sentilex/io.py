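"""Readers and writers for the on-disk dialects.

Comments travel as CSV (RFC-4180 quoting, header ``id,time,user,region,
gender,text``) or JSON-lines with the same keys; lexicons as UTF-8 TSV with
columns ``word, role, level, weight`` and ``#`` comment lines; region maps
and stop-word lists as plain TSV / one-token-per-line text.  Malformed
comment records are reported with their line numbers, never silently
dropped.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io as _io
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .types import (
    Comment,
    DegreeLevel,
    LexiconEntry,
    LexiconValidationError,
    RegionMap,
    Role,
    ROLE_PRECEDENCE,
    ScoredComment,
    SentimentLexicon,
)

log = logging.getLogger(__name__)

COMMENT_FIELDS = ("id", "time", "user", "region", "gender", "text")
_GENDERS = {"female", "male", "unknown", ""}


@dataclass(frozen=True)
class RecordError:
    line: int
    reason: str


def _parse_timestamp(raw: str) -> _dt.datetime:
    ts = _dt.datetime.fromisoformat(raw.strip())
    if ts.tzinfo is not None:  # stored naive-local in the configured timezone
        ts = ts.replace(tzinfo=None)
    return ts


def _record_to_comment(rec: dict, line: int) -> Comment | RecordError:
    if not str(rec.get("id", "") or "").strip():
        return RecordError(line, "missing id")
    if "text" not in rec or rec["text"] is None:
        return RecordError(line, "missing text field")
    raw_time = str(rec.get("time", "") or "")
    try:
        ts = _parse_timestamp(raw_time)
    except ValueError:
        return RecordError(line, f"unparseable timestamp {raw_time!r}")
    gender = str(rec.get("gender", "") or "").strip() or "unknown"
    if gender not in _GENDERS:
        return RecordError(line, f"unknown gender {gender!r}")
    return Comment(
        id=str(rec["id"]).strip(),
        timestamp=ts,
        user_id=str(rec.get("user", "") or ""),
        region=str(rec.get("region", "") or ""),
        gender=gender,
        text=str(rec["text"]),
    )


def read_comments(path, format: str = "delimited") -> tuple[list[Comment], list[RecordError]]:
    """Read a comment file; returns (comments, record-level errors).

    ``format``: "delimited" (CSV) or "record_per_line" (JSON-lines).
    An unreadable file raises; a malformed record yields a RecordError
    carrying its line number.
    """
    path = Path(path)
    comments: list[Comment] = []
    errors: list[RecordError] = []
    with open(path, encoding="utf-8", newline="") as fh:
        if format == "delimited":
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return [], []
            missing = {"id", "time", "text"} - set(reader.fieldnames)
            if missing:
                raise ValueError(f"{path}: comment CSV missing columns {sorted(missing)}")
            for i, rec in enumerate(reader, start=2):  # line 1 is the header
                out = _record_to_comment(rec, i)
                (comments if isinstance(out, Comment) else errors).append(out)
        elif format == "record_per_line":
            for i, raw in enumerate(fh, start=1):
                if not raw.strip():
                    continue
                try:
                    rec = json.loads(raw)
                except json.JSONDecodeError:
                    errors.append(RecordError(i, "invalid JSON"))
                    continue
                out = _record_to_comment(rec, i)
                (comments if isinstance(out, Comment) else errors).append(out)
        else:
            raise ValueError(f"unknown comment format {format!r}")
    seen: set[str] = set()
    for c in comments:
        if c.id in seen:
            log.warning("duplicate comment id %s", c.id)
        seen.add(c.id)
    return comments, errors


def write_comments(path, comments, format: str = "delimited") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if format == "delimited":
            w = csv.writer(fh)
            w.writerow(COMMENT_FIELDS)
            for c in comments:
                w.writerow(
                    [c.id, c.timestamp.isoformat(), c.user_id, c.region, c.gender, c.text]
                )
        elif format == "record_per_line":
            for c in comments:
                fh.write(
                    json.dumps(
                        {
                            "id": c.id,
                            "time": c.timestamp.isoformat(),
                            "user": c.user_id,
                            "region": c.region,
                            "gender": c.gender,
                            "text": c.text,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
        else:
            raise ValueError(f"unknown comment format {format!r}")


def read_lexicon(
    path,
    role_default: Role | None = None,
    provenance: str = "base",
    strict: bool = False,
) -> SentimentLexicon:
    """Load one lexicon fragment from TSV (word, role, level, weight).

    Blank and ``#``-prefixed lines are ignored.  Entries are validated
    against the role invariants at load time; any violation or duplicate
    word raises LexiconValidationError naming the offending line.
    """
    path = Path(path)
    frag = SentimentLexicon()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                cols = cols + [""] * (4 - len(cols))
            word, role_s, level_s, weight_s = (c.strip() for c in cols[:4])
            try:
                role = Role(role_s) if role_s else role_default
                if role is None:
                    raise LexiconValidationError("missing role and no default")
                level = DegreeLevel(level_s) if level_s else None
                weight = float(weight_s)
                entry = LexiconEntry(
                    word=word, role=role, weight=weight, level=level, provenance=provenance
                )
                if strict:
                    entry.validate_strict()
            except (ValueError, KeyError) as exc:
                raise LexiconValidationError(f"{path}:{lineno}: {exc}") from exc
            if word in frag:
                raise LexiconValidationError(f"{path}:{lineno}: duplicate word {word!r}")
            frag.add(entry)
    return frag


def write_lexicon(path, lexicon: SentimentLexicon) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# word\trole\tlevel\tweight\n")
        for word in sorted(lexicon.entries):
            e = lexicon.entries[word]
            level = e.level.value if e.level is not None else ""
            fh.write(f"{e.word}\t{e.role.value}\t{level}\t{e.weight:g}\n")


def merge_lexicons(fragments) -> SentimentLexicon:
    """Merge fragments into one lexicon, one role per word.

    Precedence: negation > degree_adverb > emoji > polarity; within equal
    role, the later fragment overrides the earlier.  Every resolved
    conflict is recorded in ``lexicon.conflicts`` and logged.
    """
    merged = SentimentLexicon()
    for fi, frag in enumerate(fragments):
        for word, entry in frag.entries.items():
            old = merged.lookup(word)
            if old is None:
                merged.add(entry)
                continue
            if ROLE_PRECEDENCE[entry.role] > ROLE_PRECEDENCE[old.role]:
                msg = (
                    f"{word!r}: role {old.role.value} replaced by "
                    f"{entry.role.value} (fragment {fi})"
                )
                merged.add(entry)
            elif ROLE_PRECEDENCE[entry.role] < ROLE_PRECEDENCE[old.role]:
                msg = (
                    f"{word!r}: kept role {old.role.value}, ignored "
                    f"{entry.role.value} (fragment {fi})"
                )
            else:
                msg = (
                    f"{word!r}: same role {old.role.value}, weight "
                    f"{old.weight:g} overridden by {entry.weight:g} (fragment {fi})"
                )
                merged.add(entry)
            merged.conflicts.append(msg)
            log.info("lexicon merge: %s", msg)
    return merged


SCORED_FIELDS = ("id", "time", "region", "E", "label")


def write_scored(path, scored, region_map: RegionMap | None = None) -> None:
    """Write scored comments as CSV (id, time, region bucket, E, label)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SCORED_FIELDS)
        for sc in scored:
            c = sc.comment
            region = region_map.bucket(c.region) if region_map is not None else c.region
            w.writerow([c.id, c.timestamp.isoformat(), region, repr(sc.total), sc.label])


def read_scored(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "region": str, "label": str}, keep_default_na=False)
    df["time"] = pd.to_datetime(df["time"])
    df["E"] = df["E"].astype(float)
    return df


def read_stopwords(path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def read_region_map(path) -> RegionMap:
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            prov, bucket = line.split("\t")[:2]
            mapping[prov.strip()] = bucket.strip()
    return RegionMap(mapping)


def write_region_map(path, region_map: RegionMap) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for prov in sorted(region_map.mapping):
            fh.write(f"{prov}\t{region_map.mapping[prov]}\n")


def read_seed_sets(path):
    """TSV word<TAB>polarity → (positives, negatives) sets."""
    positives: set[str] = set()
    negatives: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            word, pol = line.split("\t")[:2]
            if pol.strip() == "positive":
                positives.add(word.strip())
            elif pol.strip() == "negative":
                negatives.add(word.strip())
            else:
                raise ValueError(f"unknown seed polarity {pol!r}")
    return positives, negatives
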