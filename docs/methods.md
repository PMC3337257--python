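# Methods

## Model

Each MeSH heading is annotated by its own binary classifier; the task is
multi-label only in the sense that all per-heading decisions are taken
independently. The classifier is a two-class conditional exponential
(Maximum-Entropy) model over binary features. With shared binary features the
two per-class weight vectors β₁, β₀ enter the likelihood only through their
difference d = β₁ − β₀, while the symmetric Gaussian prior
(−(‖β₁‖² + ‖β₀‖²)/2σ²) is minimized, at fixed d, by β₁ = −β₀ = d/2. Training
therefore reduces exactly to ridge-penalized binary logistic regression in d
with penalty ‖d‖²/(4σ²), and the per-class vectors are recovered as ±d/2.
This identity is also used as a test oracle: predictions must agree with an
independently fitted `sklearn` logistic regression at C = 2σ² to 1e-6.

Optimization is IRLS/Newton on the penalized objective: at each iteration
the Hessian Xᵀ W X + λI (intercept unpenalized) is solved against the
gradient, with step halving whenever a full Newton step would decrease the
objective — the objective trace is non-decreasing by construction, which the
unit tests assert per iteration. Convergence is declared when the relative
objective change falls below `tol` (default 1e-6) within `max_iter` (default
100). The one collinearity in the design — the `year:after1951` indicator
fires for every document, duplicating the intercept — is harmless because
the ridge term keeps the Hessian positive definite.

Decisions use the threshold t = 0.5 + δ with a *strict* inequality; δ = 0.1
by default, selected per heading (if desired) by grid search over
{0.0, …, 0.4} on a class-stratified 10% validation split, ties broken toward
the smaller δ. Raising δ can only trade recall for precision, a monotonicity
the acceptance tests check on fixed models.

## Features

Four namespaces, all binary presence indicators (no counts or tf-idf), each
token prefixed with its namespace so title and abstract occurrences of the
same token remain distinct:

* `title:` / `abstract:` — lowercased tokens split on non-alphanumeric runs,
  stopword-filtered (fixed ~150-word function-word list shipped in
  `stopwords.py`; removal precedes stemming), then Porter-stemmed. The
  stemmer implements the classic five-step algorithm in-package and is
  pinned by hand-traced canonical examples.
* `journal:` — the lowercased, whitespace-collapsed journal name.
* `year:` — `afterY` for Y in 1951..y and `beforeY` for Y in y+1..2009 for a
  document published in year y. Both range endpoints are excluded so the
  block always contains exactly 59 features; out-of-range years are clamped
  to the nearest interior year with a warning. (Including the endpoints
  would give 61 features for a 1990 document; the 59-count is taken as the
  governing constraint and endpoint exclusion is the minimal consistent
  encoding.)

## Tree distance and negative selection

The MeSH hierarchy is a forest of dotted codes; a heading may hold several
(polyhierarchy). Distance between headings is
d(t₁,t₂) = L(t₁) + L(t₂) − 2·CP, with L the minimal component count over a
heading's tree numbers (top-level codes have depth 1) and CP the maximal
shared-prefix length over all tree-number pairs — the most generous
(smallest) distance under polyhierarchy. On monohierarchic trees this equals
the shortest-path edge count through a virtual root joining the top-level
codes, which a breadth-first oracle verifies over all pairs in the tests.
A heading is *semantically distant* from a document iff the **maximum**
distance to any of the document's gold headings strictly exceeds the depth
threshold (default 6). The max convention means a single distant gold
heading qualifies a document; documents without gold headings are skipped
(the maximum over an empty set is left undefined rather than guessed, and
`term_abstract_distance` raises on an empty set).

Negative pools always exclude the heading's positives. `literal` matching is
performed on stemmed contiguous token runs (consistent with the Exact
Matching baseline); synonym matching is configurable and off by default.
A consequence of the distance definition worth knowing: a heading at depth
ℓ can be at distance at most ℓ + maxdepth from any other heading, so
headings at depth ≤ 2 in a depth-4 tree can never clear a threshold of 6 and
their `literal_distant` pool is empty by geometry. Such headings — and any
heading with fewer than two positives or an empty pool — are reported as
untrainable and excluded from macro averages rather than silently defaulted.
When the eligible pool is smaller than the positive set, all of it is taken
and a warning is recorded (classes may then be mildly imbalanced).

## Evaluation protocol

Per heading: positives (capped at 10,000 by uniform seeded subsampling) plus
equally many strategy negatives, drawn once, are split into 10
class-stratified folds; each fold is classified at δ by a model trained on
the other nine; tp/fp/fn pool across folds into per-heading P/R/F (defined
as 0 on zero denominators). The summary is the unweighted macro mean across
trainable headings. Baselines run on identical instance sets and folds:
Bernoulli Naive Bayes (`sklearn` BernoulliNB, add-one smoothing,
maximum-posterior decision) and Exact Matching (annotate iff the stemmed
heading string occurs contiguously in title or abstract — no training).
Seeds fan out from one master seed per heading via a CRC32 hash, making full
runs byte-reproducible.

## Synthetic data

The generator produces the study conditions, not realistic text: a complete
binary (by default) tree of depth 4 → 30 headings, 10% of leaves
polyhierarchic; 3,000 documents, each carrying 1–3 gold headings. A
heading's surface token appears in positive titles/abstracts with
probability `signal_strength` (default 0.9) along with two context tokens;
noise tokens (default ~5 title, ~45 abstract slots at rate 0.9) are drawn
from a vocabulary that includes every heading's surface token, so literal
mentions without annotation — the negative pools of strategies (b)/(c) —
arise naturally. Each heading has a home journal (affinity 0.8) and a
Gaussian publication-year trend (width 8 around a random peak year; a
document's year follows its first gold heading's trend). Ambiguous pairs
share one surface token across different top-level branches while differing
in context tokens, journal and trend — exact matching cannot separate them,
context-based models can.

What passing tests on this generator do **not** show: robustness to real
MEDLINE lexical statistics (Zipfian vocabulary, long abstracts, heading
co-occurrence structure), to annotation noise, or to the real MeSH topology
with tens of thousands of headings. The generator isolates the mechanisms
(vocabulary signal, journal affinity, year trends, surface ambiguity) rather
than emulating their real-world magnitudes.

## Problem sizes and numerical choices

The shipped test and acceptance runs use the desk-scale preset (30 headings
× 3,000 documents for recovery over three seeds; 1,500 documents for the
ambiguity ordering; 800 for reproducibility), chosen so a full suite
completes in a few minutes on one CPU. Newton solves use a dense Cholesky
(`scipy.linalg.solve(assume_a="pos")`); per-iteration weights are clipped
below at 1e-10 to avoid degenerate curvature; model files store weights as
`repr` floats for lossless text round-trips. Stratified folds come from
`sklearn` `StratifiedKFold(shuffle=True)` with the per-heading seed.

## Known limitations

* Strategy (b)'s PubMed query is emulated on the local corpus; hierarchical
  explosion of headings (`[mh:noexp]` vs exploded search) is not modelled.
* The Gaussian prior variance is a free parameter (default 1.0); no
  sensitivity analysis is bundled.
* The C4.5 decision-tree comparison and any live-corpus experiment are out
  of scope; ablation and training-size behaviour are demonstrated
  qualitatively on synthetic corpora only.
* Exact Matching is evaluated on the same pos/neg instance sets as the
  learners; because literal-strategy negatives contain the heading string by
  construction, its precision there is structurally low — the intended
  stress, but worth remembering when reading its absolute numbers.
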