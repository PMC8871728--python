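"""Opinion aggregation: stage segmentation of the comment timeline,
per-stage emotion statistics, keyword frequencies, four-region geographic
aggregation, and Kendall's coefficient of concordance W for expert-panel
ratings.

Stage segmentation follows the outbreak / fluctuation / recession
life-cycle of an online public-opinion event.  Manual breakpoints are the
faithful mode; the auto heuristic gives an explicit reproducible rule:
the outbreak stage ends at the last day whose volume is ≥ 50% of the peak,
and the recession stage begins at the first day of the terminal run of
days with volume ≤ 10% of the peak.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .types import (
    DOMESTIC_BUCKETS,
    REGION_BUCKETS,
    RegionMap,
    ScoredComment,
)

THREE_STAGE_LABELS = ("outbreak", "fluctuation", "recession")
LABELS = ("negative", "neutral", "positive")


@dataclass(frozen=True)
class Stage:
    label: str
    start: _dt.date
    end: _dt.date  # inclusive

    def __contains__(self, day: _dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass
class StagePlan:
    stages: list[Stage]

    @property
    def T(self) -> int:
        return len(self.stages)

    def __post_init__(self):
        if not self.stages:
            raise ValueError("at least one stage required")
        for a, b in zip(self.stages, self.stages[1:]):
            if b.start != a.end + _dt.timedelta(days=1):
                raise ValueError(f"stages not contiguous at {a.label}/{b.label}")
        for s in self.stages:
            if s.end < s.start:
                raise ValueError(f"stage {s.label} ends before it starts")

    def stage_of(self, day: _dt.date) -> Stage | None:
        return next((s for s in self.stages if day in s), None)


def _stage_labels(t: int) -> list[str]:
    return list(THREE_STAGE_LABELS) if t == 3 else [f"stage-{i + 1}" for i in range(t)]


def segment_stages(
    daily_volume: Mapping[_dt.date, int],
    breakpoints: Sequence[_dt.date] | None = None,
    auto: bool = False,
) -> StagePlan:
    """Partition the corpus date range into contiguous stages.

    ``breakpoints`` cut *after* each listed date.  ``auto`` applies the
    50%-of-peak / 10%-of-peak run heuristic described in the module
    docstring; setting both is an error.
    """
    if not daily_volume:
        raise ValueError("empty volume series")
    days = sorted(daily_volume)
    start, end = days[0], days[-1]
    if breakpoints and auto:
        raise ValueError("pass breakpoints or auto, not both")

    if auto:
        # fill missing days with 0 so runs are well-defined
        full = [start + _dt.timedelta(days=i) for i in range((end - start).days + 1)]
        vol = {d: int(daily_volume.get(d, 0)) for d in full}
        peak = max(vol.values())
        outbreak_end = max(d for d in full if vol[d] >= 0.5 * peak)
        rec_start = end + _dt.timedelta(days=1)
        for d in reversed(full):
            if vol[d] <= 0.1 * peak:
                rec_start = d
            else:
                break
        if outbreak_end >= end:  # volume never falls below half peak
            return StagePlan([Stage("stage-1", start, end)])
        breakpoints = [outbreak_end]
        if rec_start <= end:
            if rec_start <= outbreak_end + _dt.timedelta(days=1):
                raise ValueError("auto heuristic: recession overlaps outbreak")
            breakpoints.append(rec_start - _dt.timedelta(days=1))

    if not breakpoints:
        return StagePlan([Stage("stage-1", start, end)])

    bps = list(breakpoints)
    if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    if bps[0] < start or bps[-1] >= end:
        raise ValueError("breakpoints must lie inside the corpus date range")
    bounds = [start] + [b + _dt.timedelta(days=1) for b in bps] + [end + _dt.timedelta(days=1)]
    labels = _stage_labels(len(bounds) - 1)
    stages = [
        Stage(lab, lo, hi - _dt.timedelta(days=1))
        for lab, lo, hi in zip(labels, bounds, bounds[1:])
    ]
    return StagePlan(stages)


@dataclass
class StageSummary:
    label: str
    n_comments: int
    counts: dict[str, int]
    proportions: dict[str, float] | None  # None when the stage is empty
    min_E: float | None
    max_E: float | None
    sum_positive_E: float
    sum_abs_negative_E: float
    daily_volume: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_comments": self.n_comments,
            "counts": self.counts,
            "proportions": self.proportions,
            "min_E": self.min_E,
            "max_E": self.max_E,
            "sum_positive_E": self.sum_positive_E,
            "sum_abs_negative_E": self.sum_abs_negative_E,
            "daily_volume": self.daily_volume,
        }


def stage_summary(scored: Iterable[ScoredComment], plan: StagePlan) -> list[StageSummary]:
    """Per-stage emotion statistics; every comment must fall in some stage."""
    buckets: dict[str, list[ScoredComment]] = {s.label: [] for s in plan.stages}
    outside: list[str] = []
    for sc in scored:
        st = plan.stage_of(sc.comment.timestamp.date())
        if st is None:
            outside.append(sc.comment.id)
        else:
            buckets[st.label].append(sc)
    if outside:
        raise ValueError(f"comments outside the stage plan: {outside[:10]}")

    out: list[StageSummary] = []
    for stage in plan.stages:
        # canonical order makes the float sums exactly input-order invariant
        group = sorted(
            buckets[stage.label], key=lambda sc: (sc.comment.timestamp, sc.comment.id)
        )
        n = len(group)
        counts = {lab: sum(1 for sc in group if sc.label == lab) for lab in LABELS}
        es = [sc.total for sc in group]
        vol = Counter(sc.comment.timestamp.date().isoformat() for sc in group)
        out.append(
            StageSummary(
                label=stage.label,
                n_comments=n,
                counts=counts,
                proportions=(
                    {lab: counts[lab] / n for lab in LABELS} if n else None
                ),
                min_E=min(es) if es else None,
                max_E=max(es) if es else None,
                sum_positive_E=float(sum(e for e in es if e > 0)),
                sum_abs_negative_E=float(-sum(e for e in es if e < 0)),
                daily_volume=dict(sorted(vol.items())),
            )
        )
    return out


def keyword_frequency_by_stage(
    comments, plan: StagePlan, top_k: int = 30
) -> dict[str, list[tuple[str, int]]]:
    """Per-stage token frequency ranking (count desc, ties lexicographic)."""
    counters: dict[str, Counter] = {s.label: Counter() for s in plan.stages}
    for c in comments:
        st = plan.stage_of(c.timestamp.date())
        if st is None:
            continue
        counters[st.label].update(t.surface for t in c.tokens)
    out: dict[str, list[tuple[str, int]]] = {}
    for label, ctr in counters.items():
        ranked = sorted(ctr.items(), key=lambda kv: (-kv[1], kv[0]))
        out[label] = ranked[:top_k]
    return out


@dataclass
class RegionSummary:
    counts: dict[str, int]  # per bucket, descending share order
    share_all: dict[str, float]
    share_domestic: dict[str, float]  # four regions over region-known domestic users

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "share_all": self.share_all,
            "share_domestic": self.share_domestic,
        }


def region_aggregate(comments, region_map: RegionMap) -> RegionSummary:
    """Map each comment's region string to a bucket and compute shares.

    Shares are reported over two denominators: all users, and region-known
    domestic users (the four economic regions only).
    """
    counts = {b: 0 for b in REGION_BUCKETS}
    for c in comments:
        counts[region_map.bucket(c.region)] += 1
    total = sum(counts.values())
    domestic = sum(counts[b] for b in DOMESTIC_BUCKETS)
    share_all = {b: (counts[b] / total if total else 0.0) for b in REGION_BUCKETS}
    share_domestic = {
        b: (counts[b] / domestic if domestic else 0.0) for b in DOMESTIC_BUCKETS
    }
    order = sorted(REGION_BUCKETS, key=lambda b: (-share_all[b], b))
    return RegionSummary(
        counts={b: counts[b] for b in order},
        share_all={b: share_all[b] for b in order},
        share_domestic={
            b: share_domestic[b]
            for b in sorted(DOMESTIC_BUCKETS, key=lambda b: (-share_domestic[b], b))
        },
    )


@dataclass(frozen=True)
class KendallWResult:
    W: float
    chi2: float
    p_value: float
    m: int
    n: int

    def consensus(self, w_threshold: float = 0.6, alpha: float = 0.05) -> bool:
        """Consensus rule for Delphi panels: W above threshold and significant."""
        return self.W > w_threshold and self.p_value < alpha


def kendalls_w(ratings) -> KendallWResult:
    """Kendall's coefficient of concordance with mid-rank tie correction.

    ``ratings`` is an m (raters) × n (items) array of scores.  Scores are
    converted to within-rater ranks (mid-ranks for ties) and

        W = 12·S / (m²·(n³ − n) − m·ΣT_j),

    with S the sum of squared deviations of item rank-sums from their mean
    and T_j = Σ(t³ − t) the tie correction per rater.  The chi-square
    approximation χ² = m(n − 1)W has n − 1 degrees of freedom.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2:
        raise ValueError("ratings must be 2-D (raters × items)")
    m, n = R.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 raters and 2 items")
    ranks = np.apply_along_axis(_stats.rankdata, 1, R)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_sum = 0.0
    for row in R:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_sum
    if denom <= 0:
        raise ValueError("Kendall's W undefined: every rater ties all items")
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    p = float(_stats.chi2.sf(chi2, df=n - 1))
    return KendallWResult(W=float(w), chi2=float(chi2), p_value=p, m=m, n=n)
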