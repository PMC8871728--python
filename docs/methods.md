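# Methods

## Scoring model

The scorer implements the classical weighted-dictionary composition for
Chinese microblog text. A merged lexicon assigns each surface form exactly
one role: polarity word (base weight B, conventionally ±1), negation word
(C = −1), degree adverb (A from six fixed levels — extremely/most 2,
super 1.5, very 1.25, relatively 1.2, slightly 0.8, under 0.5), or emoji
gloss (±1, scored like a polarity word). Scanning a sentence left to right,
every polarity/emoji token receives

    Ei = (Π A over degree adverbs in scope) × (Π C over negations in scope) × B

with **modifier scope = all modifier tokens since the previous sentiment
word within the sentence** (tokens without a role leave the scope open).
Modifiers are consumed: each binds to at most one sentiment word, and a
trailing modifier with no head contributes nothing. Sentence and comment
values are plain sums (Esi = Σ Ei, E = Σ Esi) and the label is the sign of
E.

Two compositional choices deserve explanation because the basic algorithm
statement treats the adverb case (A·B) and the negation case (C·B)
separately and is silent on their combination:

* **Joint modifiers compose multiplicatively** (A × C × B). This is the
  only composition consistent with both single-modifier cases and is the
  standard convention in the dictionary-method literature ("不很好" ≈
  −1.25 × B). It sits behind `ScoringConfig.composition` should a variant
  ever be needed.
* **Negation words modify the following sentiment word** rather than being
  scored as sentiment words themselves. Read literally, "if vi in
  privative_words then Ei = C·B" would score the negator itself; under that
  reading C could never flip the polarity of anything, contradicting the
  stated purpose of the negation dictionary. The adopted reading is
  directly testable: `[not, happy] → −1`.

An alternative `fixed_window(k)` scope (modifiers bind only within k tokens
of the head) is available for corpora with long clauses.

`neutral_tolerance` (default 1e−9) widens the E = 0 band: weights such as
1.2 and 0.8 are not binary-exact, so sums of products can carry float error
on the order of 1e−16; the tolerance absorbs it without affecting any
honest non-zero score.

## Lexicon construction

* **Merging.** Fragments (base dictionary, user-defined words, emoji,
  TF-IDF adverbs, SO-PMI expansion) merge with role precedence
  negation > degree_adverb > emoji > polarity; within equal role the later
  fragment wins. Precedence matters because the same surface form can
  appear in several source dictionaries and a lost negation role silently
  flips scores; every resolved conflict is logged and kept on the merged
  lexicon's `conflicts` list for audit.
* **PMI / SO-PMI.** Probabilities are document frequencies by default
  (each comment is one document — microblog comments are short); a sliding
  window is available for long texts. Additive smoothing ε (default 1, on
  the pair count: PMI = log₂[(P₁₂ + ε/N)/(P₁P₂ + ε/N)]) avoids log-zero;
  ε = 0 reproduces the bare formula and raises on zero co-occurrence. A
  candidate is neutral when |SO-PMI| ≤ 1e−12 — exact zero is measure-zero
  under smoothing, so the tolerance only catches constructed symmetric
  cases. Neutral candidates never enter the expanded lexicon; the others
  enter with weight ±1. Seed words absent from the corpus contribute 0 and
  are logged.
* **TF-IDF** uses the classical corpus form score(w) = tf(w)·ln(N/df(w))
  with tf the raw corpus frequency. Which tokens compete is delegated to a
  `candidate_filter` predicate (a POS tagger or a candidate adverb list),
  and terms already present in the degree-adverb dictionary are removed via
  `exclude`. The output is a ranked nomination list plus, on the CLI, a
  template file with an empty level column: level assignment is a human
  judgment, never guessed automatically.
* **TextRank** builds an undirected graph with an edge whenever two words
  co-occur within `window_size` tokens (default 5) and iterates
  WS(v) = (1−d) + d·Σ WS(u)/deg(u) with damping 0.85 to sup-norm
  tolerance 1e−6 (max 200 iterations, warning on non-convergence). These
  are the standard TextRank settings. Scores are deterministic: nodes are
  processed in lexicographic order and ties in every ranking break
  lexicographically.

## Preprocessing

Cleaning removes invalid records first (empty text; configurable
"irrelevant" regexes, default URL-only and ad-keyword comments), then
duplicates (key = (user_id, whitespace-normalized text) by default — the
conservative reading of "repeated"; a text-only key is available), then
sorts by (timestamp, id). Every removal is counted; the operation is
idempotent.

Emoji are normalized to bracket-marked glosses (`[smile]`) that tokenize
atomically as `emoji_gloss` tokens; emoji without a sentiment gloss are
deleted, mirroring the manual pruning of emoticons with no clear emotional
tendency. Emoji glosses are exempt from stop-word removal so they always
reach the scorer.

The built-in segmenter is a deterministic greedy longest match against the
combined user dictionary with a character-by-character fallback; any
statistical segmenter (e.g. jieba) can be plugged in behind the same
contract (`segmenter=callable`). Stop words join the segmentation
dictionary so multi-character stop words segment atomically before being
removed; lexicon words are subtracted from the stop list so a negator
listed in a stop list cannot break scoring.

## Analytics

Stage segmentation is faithful to manual breakpoints (dates cut *after*
each breakpoint; three stages are labeled outbreak/fluctuation/recession).
The optional auto heuristic replaces "chosen by eye" with an explicit rule:
the outbreak ends at the last day with volume ≥ 50% of peak and the
recession begins at the first day of the terminal run with volume ≤ 10% of
peak; if the curve never leaves half-peak the plan degenerates to one
stage. Stage summaries report counts, proportions, min/max E, the summed
positive E and summed |negative E| (the rationality-vs-venting contrast),
and daily volumes; distribution bodies are reported as exact extremes and
sums rather than an eyeballed "concentration" interval. Empty stages report
`None` sentinels rather than 0/0 proportions. Sums are computed in a
canonical (timestamp, id) order so results are exactly input-order
invariant.

Region aggregation maps free-text province strings through a user-supplied
table into eastern/central/western/northeast plus overseas and unspecified
(the fallback for empty or unknown strings). Shares are reported over two
denominators — all users, and region-known domestic users — because public
reporting mixes both.

Kendall's W uses mid-ranks for ties with the tie-corrected denominator
W = 12S/(m²(n³−n) − mΣTⱼ), the standard form for Likert-scale panel data,
with χ² = m(n−1)W on n−1 degrees of freedom; all-ties input is an explicit
error. A `consensus(w_threshold=0.6, alpha=0.05)` helper encodes the usual
Delphi consensus rule. The χ² statistic is cross-checked in the tests
against the Friedman test, to which it is algebraically identical.

## Synthetic generator

The generator emulates the shape of a crawled event corpus, not its
language. Defaults encode a 37-day event window starting 2019-11-25 with
volume peaking on day 1 and decaying exponentially (rise rate twice the
decay rate); per-period (pos, neu, neg) mixtures of (0.343, 0.172, 0.485)
for the 2-day outbreak, (0.45, 0.20, 0.35) for the fluctuation period and
(0.34, 0.33, 0.33) for the recession tail; region masses 0.4027/0.1690/
0.1117/0.0428 (eastern/western/central/northeast), 0.0678 overseas and
0.2067 unspecified; 5% planted duplicates and 3% invalid (empty-text)
records; 24 degree adverbs (4 per level), 11 negation words, 80+80 polarity
words, 10 emoji glosses and 300 distractors. Comments draw 6–16 tokens;
each non-neutral comment carries `signal_words = 2` sentiment blocks (the
strong-signal regime), each block optionally prefixed by an adverb
(p = 0.3) and/or a negation (p = 0.15).

Two design choices make the ground truth *exact* rather than approximate:
a negation insertion is always paired with flipping its head word's base
polarity, so the block keeps the planted sign; and modifier+head blocks are
atomic when shuffled among distractors, so a modifier can never capture a
different head. Consequently the scorer reproduces the planted E of every
valid comment bit-for-bit, which the tests assert at 100%.

What the generator does **not** emulate: Zipfian token frequencies,
discourse structure, sarcasm, code-switching, segmentation ambiguity
(surfaces are space-separated ASCII pseudo-words by default — CJK surfaces
are exercised separately in the tokenizer tests), or correlation between
region and sentiment. Passing recovery tests therefore demonstrates that
the pipeline's bookkeeping and numerics are correct under known conditions,
not that the dictionary method is accurate on real microblog language —
dictionary coverage and segmentation quality dominate real-world accuracy.

All sampling uses a single `numpy.random.default_rng(seed)`; a fixed seed
gives byte-identical corpora, and the pipeline manifest hashes every output
so reruns are verifiably identical.

## Problem sizes

The repository's checks run on deliberately moderate sizes chosen so the
binomial sampling error is well inside the asserted tolerances: 10,000
random sentences for scorer-oracle equivalence, 5,000 comments per stage
(±0.02 on proportions ≈ 3 sampling σ), 15,000 comments for region shares
(±0.015), 500 documents for SO-PMI recovery, 1,000 random matrices for the
Kendall's W bounds. Larger corpora only tighten these margins.

## Known limitations

* One role per word after merging: a surface form cannot be both a negator
  and a polarity word in different contexts (precedence picks one).
* The greedy segmenter has no statistical disambiguation; real Chinese text
  should plug in a trained segmenter.
* Degree adverbs and negations are treated as order-free within a scope
  (A·C products commute), so "不很好" and "很不好" score identically.
* SO-PMI polarity is binary ±1; no graded orientation magnitude is kept.
* Stage auto-segmentation assumes a unimodal volume curve; multi-peak
  events need manual breakpoints.
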