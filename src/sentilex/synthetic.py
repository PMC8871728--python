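"""Synthetic comment corpora with known ground truth.

The generator emulates the shape of a crawled microblog corpus around a
public-health opinion event: a multi-week stream whose daily volume rises
sharply to a peak on the second day and decays, per-period planted
positive/neutral/negative mixtures, comments composed of distractor tokens
plus sentiment words with degree-adverb and negation modifiers, emoji
glosses, categorical region strings with an "unspecified" mass, and planted
duplicate/invalid records.  Every planted quantity (label, comment value E,
region, duplicate/invalid flags) is recorded in a ground-truth table, so
recovery by the pipeline is exactly checkable.

Surfaces are ASCII pseudo-words with disjoint prefixes (``goodw``/``badw``/
``advX``/``notw``/``emo``/``fill``), so no real lexical resources are
needed; a negation insertion is always paired with a polarity flip of its
head word, keeping planted labels exact rather than approximate.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cooccurrence import SeedSet
from .types import (
    Comment,
    DegreeLevel,
    DEGREE_WEIGHTS,
    DOMESTIC_BUCKETS,
    LexiconEntry,
    NEGATION_WEIGHT,
    RegionMap,
    Role,
    SentimentLexicon,
)

#: Region-bucket masses: 72.55% domestic (split 55.5/23.3/15.4/5.9 across the
#: four economic regions), 6.78% overseas, 20.67% region not filled in.
DEFAULT_REGION_DISTRIBUTION = {
    "eastern": 0.7255 * 0.555,
    "western": 0.7255 * 0.233,
    "central": 0.7255 * 0.154,
    "northeast": 0.7255 * 0.059,
    "overseas": 0.0678,
    "unspecified": 0.2067,
}

#: Per-period (pos, neu, neg) mixtures keyed by day-offset ranges, matching a
#: 37-day event window: a 2-day outbreak with negative dominance, a
#: fluctuation period with positive ascendancy, and an even recession tail.
DEFAULT_STAGE_MIXTURES = (
    (0, 1, (0.343, 0.172, 0.485)),
    (2, 20, (0.45, 0.20, 0.35)),
    (21, 36, (0.34, 0.33, 0.33)),
)


@dataclass
class SyntheticSpec:
    seed: int = 0
    start_date: _dt.date = _dt.date(2019, 11, 25)
    n_days: int = 37
    # ("unimodal_outbreak", peak_day, peak_volume, decay_rate) or ("constant", v)
    volume_curve: tuple = ("unimodal_outbreak", 1, 900, 0.18)
    stage_mixtures: tuple = DEFAULT_STAGE_MIXTURES
    n_pos_words: int = 80
    n_neg_words: int = 80
    n_adverbs_per_level: int = 4
    n_negations: int = 11
    n_emoji: int = 10
    n_distractors: int = 300
    tokens_per_comment: tuple[int, int] = (6, 16)
    p_adverb: float = 0.3
    p_negation: float = 0.15
    p_emoji: float = 0.1
    p_sentence_break: float = 0.1
    signal_words: int = 2  # >= 2 is the strong-signal regime
    duplicate_rate: float = 0.05
    invalid_rate: float = 0.03
    region_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_DISTRIBUTION)
    )
    n_provinces_per_bucket: int = 3
    gender_distribution: dict[str, float] = field(
        default_factory=lambda: {"female": 0.55, "male": 0.35, "unknown": 0.10}
    )

    def validate(self) -> None:
        for lo, hi, mix in self.stage_mixtures:
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"mixture for days {lo}-{hi} does not sum to 1")
        for name in ("p_adverb", "p_negation", "p_emoji", "p_sentence_break",
                     "duplicate_rate", "invalid_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        # printed survey shares can carry rounding; masses are renormalized
        if abs(sum(self.region_distribution.values()) - 1.0) > 1e-2:
            raise ValueError("region distribution must sum to 1")
        if self.signal_words < 1:
            raise ValueError("signal_words must be >= 1")


@dataclass
class Vocabulary:
    positive: list[str]
    negative: list[str]
    adverbs: list[tuple[str, float]]  # (word, weight A)
    negations: list[str]
    emoji_positive: list[str]
    emoji_negative: list[str]
    distractors: list[str]

    @property
    def dictionary_words(self) -> set[str]:
        """The segmentation dictionary: every generated surface form."""
        return (
            set(self.positive)
            | set(self.negative)
            | {w for w, _ in self.adverbs}
            | set(self.negations)
            | set(self.distractors)
        )


def make_lexicon(spec: SyntheticSpec) -> tuple[SentimentLexicon, Vocabulary]:
    """Build a collision-free synthetic lexicon mirroring the role structure."""
    spec.validate()
    levels = list(DegreeLevel)
    vocab = Vocabulary(
        positive=[f"goodw{i:03d}" for i in range(spec.n_pos_words)],
        negative=[f"badw{i:03d}" for i in range(spec.n_neg_words)],
        adverbs=[
            (f"adv{li}{j:02d}", DEGREE_WEIGHTS[level])
            for li, level in enumerate(levels)
            for j in range(spec.n_adverbs_per_level)
        ],
        negations=[f"notw{i:02d}" for i in range(spec.n_negations)],
        emoji_positive=[f"emop{i:02d}" for i in range((spec.n_emoji + 1) // 2)],
        emoji_negative=[f"emon{i:02d}" for i in range(spec.n_emoji // 2)],
        distractors=[f"fill{i:03d}" for i in range(spec.n_distractors)],
    )
    lex = SentimentLexicon()
    for w in vocab.positive:
        lex.add(LexiconEntry(w, Role.polarity, 1.0))
    for w in vocab.negative:
        lex.add(LexiconEntry(w, Role.polarity, -1.0))
    for li, level in enumerate(levels):
        for j in range(spec.n_adverbs_per_level):
            w = f"adv{li}{j:02d}"
            lex.add(LexiconEntry(w, Role.degree_adverb, DEGREE_WEIGHTS[level], level=level))
    for w in vocab.negations:
        lex.add(LexiconEntry(w, Role.negation, NEGATION_WEIGHT))
    for w in vocab.emoji_positive:
        lex.add(LexiconEntry(w, Role.emoji, 1.0, provenance="emoji"))
    for w in vocab.emoji_negative:
        lex.add(LexiconEntry(w, Role.emoji, -1.0, provenance="emoji"))
    return lex, vocab


def make_region_map(spec: SyntheticSpec) -> tuple[RegionMap, dict[str, list[str]]]:
    """Deterministic province → bucket map; overseas is a single string,
    unspecified is the empty region string."""
    mapping: dict[str, str] = {}
    provinces: dict[str, list[str]] = {}
    for bucket in DOMESTIC_BUCKETS:
        provs = [f"{bucket}_prov{i}" for i in range(spec.n_provinces_per_bucket)]
        provinces[bucket] = provs
        for p in provs:
            mapping[p] = bucket
    mapping["overseas"] = "overseas"
    provinces["overseas"] = ["overseas"]
    provinces["unspecified"] = [""]
    return RegionMap(mapping), provinces


def daily_volumes(spec: SyntheticSpec) -> list[int]:
    """Comment counts per day-offset under the configured volume curve."""
    kind = spec.volume_curve[0]
    if kind == "constant":
        return [int(spec.volume_curve[1])] * spec.n_days
    if kind != "unimodal_outbreak":
        raise ValueError(f"unknown volume curve {kind!r}")
    _, peak_day, peak_volume, decay = spec.volume_curve
    out = []
    for d in range(spec.n_days):
        if d >= peak_day:
            v = peak_volume * math.exp(-decay * (d - peak_day))
        else:  # steeper ramp-up before the peak
            v = peak_volume * math.exp(-2.0 * decay * (peak_day - d))
        out.append(max(1, round(v)))
    return out


def _mixture_for_day(spec: SyntheticSpec, day: int) -> tuple[float, float, float]:
    for lo, hi, mix in spec.stage_mixtures:
        if lo <= day <= hi:
            return mix
    return spec.stage_mixtures[-1][2]


_LABELS = ("positive", "neutral", "negative")


def _compose_tokens(rng, label: str, vocab: Vocabulary, spec: SyntheticSpec):
    """Compose a token-surface list with exactly the planted sign.

    Sentiment words travel in atomic modifier+head blocks, so negations and
    adverbs always bind to their intended head; a negation flips the head's
    base polarity so the planted sign of the block is preserved.
    """
    lo, hi = spec.tokens_per_comment
    n_tok = int(rng.integers(lo, hi + 1))
    blocks: list[list[str]] = []
    planted_e = 0.0
    if label != "neutral":
        head_sign = 1.0 if label == "positive" else -1.0
        for _ in range(spec.signal_words):
            use_neg = rng.random() < spec.p_negation
            use_adv = rng.random() < spec.p_adverb
            base_sign = -head_sign if use_neg else head_sign
            block: list[str] = []
            a = 1.0
            if use_adv:
                word, a = vocab.adverbs[int(rng.integers(len(vocab.adverbs)))]
                block.append(word)
            if use_neg:
                block.append(vocab.negations[int(rng.integers(len(vocab.negations)))])
            if rng.random() < spec.p_emoji:
                pool = vocab.emoji_positive if base_sign > 0 else vocab.emoji_negative
                head = f"[{pool[int(rng.integers(len(pool)))]}]"
            else:
                pool = vocab.positive if base_sign > 0 else vocab.negative
                head = pool[int(rng.integers(len(pool)))]
            block.append(head)
            blocks.append(block)
            c = NEGATION_WEIGHT if use_neg else 1.0
            planted_e += a * c * base_sign
    n_fill = max(0, n_tok - sum(len(b) for b in blocks))
    slots: list[list[str]] = blocks + [
        [vocab.distractors[int(rng.integers(len(vocab.distractors)))]]
        for _ in range(n_fill)
    ]
    order = rng.permutation(len(slots))
    surfaces: list[str] = []
    for k, si in enumerate(order):
        surfaces.extend(slots[si])
        if k + 1 < len(slots) and rng.random() < spec.p_sentence_break:
            surfaces.append("。")
    return surfaces, planted_e


def generate_comments(
    spec: SyntheticSpec,
    vocab: Vocabulary,
    provinces: dict[str, list[str]],
) -> tuple[list[Comment], pd.DataFrame]:
    """Generate the raw comment stream plus its ground-truth table.

    Duplicate records copy (user, text) of a source comment; invalid
    records have empty text.  The returned order is shuffled, so cleaning
    must re-sort chronologically.
    """
    spec.validate()
    if spec.n_pos_words == 0 and any(m[2][0] > 0 for m in spec.stage_mixtures):
        raise ValueError("planted positive labels but n_pos_words = 0")
    if spec.n_neg_words == 0 and any(m[2][2] > 0 for m in spec.stage_mixtures):
        raise ValueError("planted negative labels but n_neg_words = 0")
    rng = np.random.default_rng(spec.seed)
    buckets = sorted(spec.region_distribution)
    bucket_p = np.array([spec.region_distribution[b] for b in buckets])
    bucket_p = bucket_p / bucket_p.sum()
    genders = sorted(spec.gender_distribution)
    gender_p = np.array([spec.gender_distribution[g] for g in genders])
    gender_p = gender_p / gender_p.sum()

    comments: list[Comment] = []
    truth_rows: list[dict] = []
    serial = 0
    for day, volume in enumerate(daily_volumes(spec)):
        pi_pos, pi_neu, pi_neg = _mixture_for_day(spec, day)
        date = spec.start_date + _dt.timedelta(days=day)
        label_idx = rng.choice(3, size=volume, p=[pi_pos, pi_neu, pi_neg])
        minutes = np.sort(rng.integers(0, 1440, size=volume))
        for j in range(volume):
            label = _LABELS[label_idx[j]]
            surfaces, planted_e = _compose_tokens(rng, label, vocab, spec)
            bucket = buckets[int(rng.choice(len(buckets), p=bucket_p))]
            region = provinces[bucket][int(rng.integers(len(provinces[bucket])))]
            gender = genders[int(rng.choice(len(genders), p=gender_p))]
            ts = _dt.datetime.combine(date, _dt.time(0)) + _dt.timedelta(
                minutes=int(minutes[j])
            )
            cid = f"c{serial:06d}"
            comments.append(
                Comment(
                    id=cid,
                    timestamp=ts,
                    user_id=f"u{serial:06d}",
                    region=region,
                    gender=gender,
                    text=" ".join(surfaces),
                )
            )
            truth_rows.append(
                {
                    "id": cid,
                    "label": label,
                    "planted_E": planted_e,
                    "day": day,
                    "region": region,
                    "region_bucket": bucket,
                    "gender": gender,
                    "is_duplicate": False,
                    "is_invalid": False,
                }
            )
            serial += 1

    n_base = len(comments)
    n_dup = round(spec.duplicate_rate * n_base)
    n_inv = round(spec.invalid_rate * n_base)
    if n_dup:
        for src_i in rng.choice(n_base, size=n_dup, replace=False):
            src = comments[int(src_i)]
            cid = f"d{serial:06d}"
            comments.append(
                Comment(
                    id=cid,
                    timestamp=src.timestamp + _dt.timedelta(minutes=1),
                    user_id=src.user_id,
                    region=src.region,
                    gender=src.gender,
                    text=src.text,
                )
            )
            src_truth = truth_rows[int(src_i)]
            truth_rows.append({**src_truth, "id": cid, "is_duplicate": True})
            serial += 1
    for _ in range(n_inv):
        cid = f"i{serial:06d}"
        day = int(rng.integers(spec.n_days))
        ts = _dt.datetime.combine(
            spec.start_date + _dt.timedelta(days=day), _dt.time(0)
        ) + _dt.timedelta(minutes=int(rng.integers(0, 1440)))
        comments.append(
            Comment(id=cid, timestamp=ts, user_id=f"u{serial:06d}", text="")
        )
        truth_rows.append(
            {
                "id": cid,
                "label": "invalid",
                "planted_E": 0.0,
                "day": day,
                "region": "",
                "region_bucket": "unspecified",
                "gender": "unknown",
                "is_duplicate": False,
                "is_invalid": True,
            }
        )
        serial += 1

    order = rng.permutation(len(comments))
    comments = [comments[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order]).set_index("id")
    return comments, truth


@dataclass
class SyntheticCorpus:
    spec: SyntheticSpec
    lexicon: SentimentLexicon
    vocab: Vocabulary
    region_map: RegionMap
    comments: list[Comment]
    truth: pd.DataFrame


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Convenience wrapper bundling lexicon, region map, stream and truth."""
    lexicon, vocab = make_lexicon(spec)
    region_map, provinces = make_region_map(spec)
    comments, truth = generate_comments(spec, vocab, provinces)
    return SyntheticCorpus(
        spec=spec,
        lexicon=lexicon,
        vocab=vocab,
        region_map=region_map,
        comments=comments,
        truth=truth,
    )


def generate_seed_corpus(
    n_docs: int = 500,
    contrast: tuple[float, float] = (0.6, 0.1),
    n_candidates: tuple[int, int] = (20, 20),
    n_seeds: tuple[int, int] = (4, 4),
    n_fillers: int = 30,
    fillers_per_doc: int = 2,
    seed: int = 0,
) -> tuple[list[list[str]], SeedSet, dict[str, str]]:
    """Planted corpus for SO-PMI: positive-class candidates co-occur with
    positive seeds at the high rate and negative seeds at the low rate,
    symmetrically for the negative class.  Returns (docs, seeds, truth)."""
    p_hi, p_lo = contrast
    if not (0.0 <= p_hi <= 1.0 and 0.0 <= p_lo <= 1.0):
        raise ValueError("contrast rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pos_cands = [f"candp{i:02d}" for i in range(n_candidates[0])]
    neg_cands = [f"candn{i:02d}" for i in range(n_candidates[1])]
    pos_seeds = [f"seedp{i}" for i in range(n_seeds[0])]
    neg_seeds = [f"seedn{i}" for i in range(n_seeds[1])]
    fillers = [f"fw{i:02d}" for i in range(n_fillers)]
    all_cands = pos_cands + neg_cands
    truth = {w: "positive" for w in pos_cands}
    truth.update({w: "negative" for w in neg_cands})

    docs: list[list[str]] = []
    for i in range(n_docs):
        cand = all_cands[i % len(all_cands)]
        is_pos = truth[cand] == "positive"
        doc = [cand]
        for s in pos_seeds:
            if rng.random() < (p_hi if is_pos else p_lo):
                doc.append(s)
        for s in neg_seeds:
            if rng.random() < (p_lo if is_pos else p_hi):
                doc.append(s)
        if fillers:
            doc.extend(
                fillers[int(k)] for k in rng.integers(0, n_fillers, size=fillers_per_doc)
            )
        docs.append(doc)
    return docs, SeedSet(frozenset(pos_seeds), frozenset(neg_seeds)), truth


def generate_ratings(m: int, n: int, agreement: float, seed: int = 0) -> np.ndarray:
    """m × n rating matrix: agreement 1 → identical rankings, 0 → independent."""
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = rng.permutation(n).astype(float) + 1.0
    if agreement == 1.0:
        return np.tile(base, (m, 1))
    noise = rng.uniform(0.0, n, size=(m, n))
    return agreement * base[None, :] + (1.0 - agreement) * noise
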