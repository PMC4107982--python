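# Methods

## Task

Semantic category disambiguation (SCD): a contiguous text span in a
document, a fixed inventory of semantic categories, and two outputs — a
single-label classification, or a minimal set of candidate categories whose
summed confidence clears a threshold. The multi-suggestion mode targets
annotation support: the useful quantity is how far the candidate set is
narrowed (ambiguity reduction) while still containing the right answer
(recall).

## Model

An L2-regularised multinomial logistic regression (scikit-learn
`LogisticRegression`, lbfgs, `max_iter=2000`) over sparse binary feature
vectors (`DictVectorizer`). A linear probabilistic classifier is the
natural choice here: the suggestion rule consumes calibrated-ish softmax
confidences, the features are high-dimensional sparse indicators, and
determinism under a fixed seed is required for reproducible evaluation.
Regularisation strength `C` defaults to 1.0 and is exposed in the API and
CLI; no per-dataset tuning is performed.

The category inventory of a trained model is the ordered subset of the
corpus inventory present in the training spans: a category with no training
evidence cannot be predicted or suggested. All ties (equal confidences, in
sorting and argmax) break by inventory order, so runs are bit-reproducible.

### Feature families

* `int:` — derived solely from the span text: lowercased text, tokens,
  token count, character prefixes/suffixes of lengths 2–4, collapsed word
  shape (`Fibrin → Xx+`), contains-digit / contains-hyphen / all-caps
  flags, character bigrams and trigrams. No context outside the span is
  used.
* `gaz:` — one indicator per lexical resource, fired by strict membership
  of the normalised span text.
* `sim:` — one indicator per (resource, τ) for τ in {0.6, 0.7, 0.8, 0.9,
  1.0}, fired when some entry's character-trigram cosine similarity
  reaches τ. The grid is a design choice spanning loose-to-exact matching
  with a small feature blow-up; a strict hit implies every `sim:` feature
  up to τ = 1.0, so the approximate family subsumes the strict one.
* `np*:` — text of the NP-head and Base-NP, plus the same strict
  (`npgaz:`) and approximate (`npsim:`) lookups applied to both, in their
  own namespaces.

Feature values are binary throughout: dictionary lookup has presence
semantics, and counts add nothing for single-span classification. Model
variants (`INT`, `INT.GAZ`, `INT.SIM`, `INT.NP.GAZ`, `INT.NP.SIM`) are
unions of families; namespacing makes collisions impossible.

### Text normalisation

All lookups (strict and approximate, both sides) operate on NFKC,
case-folded text with internal whitespace collapsed to single spaces.
Corpus casing and dictionary casing conventions differ too often for exact
case matching to be useful, and normalising both sides keeps the
strict ⇒ approximate-at-τ=1 implication exact.

### Approximate matching

Strings are represented as multisets of character trigrams after padding
with two distinct begin/end markers (control characters U+0002/U+0003,
outside any realistic entry alphabet), so a string of length L yields
L + 2 grams. Similarity is multiset cosine: |p ∩ q| / √(|p|·|q|) with
min-count intersection. The index inverts grams within buckets keyed by
profile size; a query at threshold τ only scans buckets in
[⌈τ²·|p|⌉, ⌊|p|/τ²⌋], since cosine is bounded by √(min/max) of the profile
sizes — outside the band τ is unreachable. Candidates sharing at least one
gram are then verified with the exact cosine, so index results are
identical to the exhaustive-scan oracle (`oracle_lookup`), which the test
suite checks on randomised dictionaries. Feature generation performs one
candidate scan per resource at the lowest grid τ and reads every grid
threshold off the resulting maximum similarity.

### NP-head heuristic

The head is the last word token strictly before the first post-modifier
boundary — the first preposition in {of, in, on, for, with, to, by, from,
at}, the first comma, or the first opening parenthesis — or the span's last
word token when no boundary exists. The Base-NP is the span text from its
start through the head token. No parsing is attempted; the boundary list is
a declared heuristic, adequate for the compound constructions the feature
targets ("Complex of fibrin and plasminogen" → head "Complex").

### Suggestion rule

Categories are ordered by descending confidence (ties by inventory order);
the suggestion set is the shortest prefix with cumulative confidence ≥ the
threshold. Cumulative sums carry a 1e−12 tolerance so a distribution
summing to 1 − ε still yields the full inventory at threshold 1.0. The
prefix construction provably returns a minimal-size set with maximal mass
among minimal sets; the tests confirm this against exhaustive subset
enumeration. Thresholds may be given as fractions (0.995) or percentages
(99.5) on the CLI.

## Corpus handling

brat-convention standoff: `T`-lines define spans; relation/event/attribute
lines are skipped with a logged count; offset or surface mismatches are
hard errors, since they indicate corpus corruption. Discontinuous fragment
lists are merged to their covering span (min start, max end) and duplicates
created by merging are dropped, as are duplicates created by category
collapsing. Splitting into train/dev/test is by annotation at ratios
1/2, 1/4, 1/4 (train ⌈n/2⌉, dev ⌈remainder/2⌉), unstratified, driven by
`numpy.random.default_rng(seed)`; spans of one document may land in
different folds. Subsampling for learning curves takes
⌊fraction·n + 0.5⌋ spans without replacement. All three split parts share
the parent inventory, so ambiguity reduction is always normalised by the
full candidate set.

## Evaluation protocol

`evaluate` scores accuracy (argmax), recall and mean ambiguity (suggestion
sets at one threshold), ambiguity reduction `(|C| − ambiguity)/(|C| − 1)`,
and the harmonic mean of the last two. A test span whose gold category is
unknown to the model counts as both a classification and a recall miss
(logged) — conservative, and irrelevant when splits come from one corpus.
Learning curves train on repeated random subsamples at each fraction of the
5%…100% grid; per-point metrics are means over `samples_per_point` repeats
(default 5 — "several" samples is otherwise unquantified; subsample seeds
derive deterministically from the master seed and point index), and the
curve summary is the mean over points, approximating area under the curve.
Metrics are stored on [0, 1] and reported ×100 with two decimals.
Statistical significance testing is out of scope; per-span correctness
vectors are exposed (`evaluate(..., return_details=True)`, and the
prediction dump TSV) for external tests.

## Synthetic data generator

The generator emulates exactly the structure the method exploits, and
nothing else:

* **Lexicons**: 300 pairwise-disjoint pronounceable CV-syllable strings
  per category (3–5 syllables). 300 entries per category means a 500-span
  training sample covers well under half of any category's lexicon —
  as with real gazetteers, most test-time dictionary hits are for strings
  the classifier never saw in training, which is precisely where lookup
  features pay off.
* **Noise channel**: each surface character independently substituted,
  doubled with a random insertion, or deleted with probability
  `noise_rate` (default 0.05). Noise applies to corpus surfaces only;
  dictionaries keep canonical forms, matching how real resources relate to
  text variants. At 5% per character, roughly 60% of ~9-character surfaces
  are verbatim entries — enough signal for strict lookup to help, enough
  variation for approximate lookup to beat it.
* **Compound spans**: with probability `compound_fraction`, a span is
  "X of Y" with head X from the gold category and modifier Y from a
  different one — the construction NP-head features disambiguate.
* **Granularity**: `fine` resources are the per-category lexicons;
  `merged` resources union consecutive pairs of categories (odd remainder
  folded into the last group), so lookups cannot separate categories
  within a group — emulating coarse upper-level classes.
* **Filler text** between spans comes from a closed English-like token set
  disjoint from all lexicons (collisions rejected at generation), so no
  accidental dictionary hits occur.

What passing the synthetic studies does *not* show: real biomedical token
distributions, realistic inter-category confusability (real categories
share morphology; synthetic lexicons are disjoint), resource noise
(real dictionaries contain errors and cross-category entries), or corpus
scale. The studies demonstrate that the implementation recovers the
method's qualitative behaviour — approximate matching beats strict
matching under surface variation, resource granularity bounds attainable
accuracy, head-word lookups rescue compound spans, and the confidence
threshold trades ambiguity against recall — not that the absolute numbers
transfer to any real corpus.

## Study sizes

The acceptance studies use 5 categories (2 for the threshold study),
500 training and 200 test spans, chosen as the smallest sizes at which the
variant contrasts are stable across seeds; each study trains in a few
seconds on one CPU.

## Known limitations

* The NP-head heuristic handles only premodified heads with a small
  closed boundary set; postmodifying constructions outside it ("receptor
  expressed in liver" vs "receptor liver-expressed") fall back to
  last-token heads.
* Softmax confidences from logistic regression are used raw; no
  post-hoc calibration, so the threshold's semantics drift with training
  size and regularisation.
* The size-band candidate filter guarantees exactness only down to the
  lowest queried τ; the reported maximum similarity below that floor may
  be an underestimate (never affects feature firing).
* Tokenisation is whitespace/punctuation splitting with no
  language-specific analysis, by design.
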