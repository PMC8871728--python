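"""End-to-end orchestration: clean → normalize emojis → tokenize →
stop-filter → (optional) lexicon induction → score → segment → summarize.

A run directory receives the scored CSV, stage and region JSON reports,
per-stage keyword TSVs, the cleaning report and a manifest listing every
output with a content hash; reruns with the same inputs and seed are
byte-identical for all outputs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as _io
from .analytics import (
    keyword_frequency_by_stage,
    region_aggregate,
    segment_stages,
    stage_summary,
)
from .cooccurrence import SeedSet, build_cooccurrence, classify_by_sopmi
from .induction import expand_lexicon
from .preprocess import CleaningRules, clean_comments, normalize_emojis, remove_stopwords, tokenize
from .scoring import ScoringConfig, batch_score
from .types import RegionMap, SentimentLexicon

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    comments: str = ""
    comments_format: str = "delimited"
    lexicons: list[str] = field(default_factory=list)
    stopwords: str | None = None
    region_map: str | None = None
    seeds: str | None = None
    induce_lexicon: bool = False
    induction_min_df: int = 5
    smoothing: float = 1.0
    breakpoints: list[str] = field(default_factory=list)  # ISO dates
    auto_stages: bool = False
    timezone: str = "Asia/Shanghai"
    seed: int = 0
    dedupe_scope: str = "user_text"
    modifier_scope: str = "since_last_sentiment_word"
    neutral_tolerance: float = 1e-9
    top_k_keywords: int = 30

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}

    def validate(self) -> None:
        if not self.comments:
            raise ValueError("config: 'comments' path is required")
        for p in [self.comments, *self.lexicons]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for p in (self.stopwords, self.region_map, self.seeds):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.breakpoints and self.auto_stages:
            raise ValueError("config: set breakpoints or auto_stages, not both")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(
        json.dumps(obj, sort_keys=True, indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def prepare(config: PipelineConfig):
    """Load, clean and tokenize; returns (comments, report, lexicon, region_map).

    Deterministic: the same inputs always yield the same token streams.
    Lexicon words are exempt from stop-word removal so negators listed in a
    stop list cannot break scoring.
    """
    config.validate()
    comments, errors = _io.read_comments(config.comments, format=config.comments_format)
    for err in errors:
        log.warning("skipping record at line %d: %s", err.line, err.reason)
    fragments = [_io.read_lexicon(p) for p in config.lexicons]
    lexicon = _io.merge_lexicons(fragments) if fragments else SentimentLexicon()
    stopwords = _io.read_stopwords(config.stopwords) if config.stopwords else set()
    stopwords -= lexicon.words()
    region_map = _io.read_region_map(config.region_map) if config.region_map else RegionMap()

    comments, report = clean_comments(comments, CleaningRules(dedupe_scope=config.dedupe_scope))
    # stop words join the segmentation dictionary so multi-character stop
    # words are segmented atomically and can then be removed
    dictionary = lexicon.words() | stopwords
    for c in comments:
        text = normalize_emojis(c.text, lexicon)
        c.tokens = remove_stopwords(tokenize(text, dictionary), stopwords)
    return comments, report, lexicon, region_map


def induce(config: PipelineConfig, comments, lexicon: SentimentLexicon) -> SentimentLexicon:
    """SO-PMI expansion of the lexicon from the corpus itself (optional)."""
    positives, negatives = _io.read_seed_sets(config.seeds)
    token_docs = [c.tokens for c in comments]
    model = build_cooccurrence(token_docs)
    known = lexicon.words()
    candidates = sorted(
        w
        for w, df in model.doc_freq.items()
        if df >= config.induction_min_df and w not in known and len(w) > 1
    )
    labels = classify_by_sopmi(
        candidates, model, SeedSet(frozenset(positives), frozenset(negatives)),
        smoothing=config.smoothing,
    )
    frag = expand_lexicon(labels)
    log.info("SO-PMI expansion added %d polarity words", len(frag))
    return _io.merge_lexicons([lexicon, frag])


def run_score(config: PipelineConfig, outdir) -> list:
    """Clean, tokenize, (optionally) induce, score; writes scored.csv,
    cleaning_report.json and the merged lexicon."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comments, report, lexicon, region_map = prepare(config)
    if config.induce_lexicon:
        if not config.seeds:
            raise ValueError("induce_lexicon requires a seeds file")
        lexicon = induce(config, comments, lexicon)
    scoring_cfg = ScoringConfig(
        modifier_scope=config.modifier_scope, neutral_tolerance=config.neutral_tolerance
    )
    scored, errors = batch_score(comments, lexicon, scoring_cfg)
    for cid, reason in errors:
        log.error("failed to score comment %s: %s", cid, reason)
    _write_json(
        outdir / "cleaning_report.json",
        {
            "n_input": report.n_input,
            "n_duplicates_removed": report.n_duplicates_removed,
            "n_invalid_removed": report.n_invalid_removed,
            "n_output": report.n_output,
            "per_rule": report.per_rule,
        },
    )
    _io.write_scored(outdir / "scored.csv", scored, region_map=region_map)
    _io.write_lexicon(outdir / "lexicon_merged.tsv", lexicon)
    return scored


def run_analyze(config: PipelineConfig, outdir) -> dict:
    """Stage segmentation, per-stage statistics, keywords, region shares."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comments, report, lexicon, region_map = prepare(config)
    if config.induce_lexicon:
        lexicon = induce(config, comments, lexicon)
    scoring_cfg = ScoringConfig(
        modifier_scope=config.modifier_scope, neutral_tolerance=config.neutral_tolerance
    )
    scored, _ = batch_score(comments, lexicon, scoring_cfg)

    from collections import Counter

    volume = Counter(sc.comment.timestamp.date() for sc in scored)
    bps = [_dt.date.fromisoformat(b) for b in config.breakpoints]
    plan = segment_stages(dict(volume), breakpoints=bps or None, auto=config.auto_stages)
    summaries = stage_summary(scored, plan)
    _write_json(outdir / "stage_summary.json", [s.to_dict() for s in summaries])

    keywords = keyword_frequency_by_stage(comments, plan, top_k=config.top_k_keywords)
    for label, ranking in keywords.items():
        with open(outdir / f"keywords_{label}.tsv", "w", encoding="utf-8") as fh:
            for word, count in ranking:
                fh.write(f"{word}\t{count}\n")

    regions = region_aggregate(comments, region_map)
    _write_json(outdir / "region_summary.json", regions.to_dict())
    return {
        "stages": summaries,
        "regions": regions,
        "keywords": keywords,
        "n_scored": len(scored),
    }


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Full run; returns the run directory containing all outputs + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_score(config, outdir)
    run_analyze(config, outdir)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True).encode()
    outputs = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json).hexdigest(),
        "seed": config.seed,
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    _write_json(outdir / "manifest.json", manifest)
    return outdir
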