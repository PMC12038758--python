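# Methods

This note documents the models, rules and numerical choices behind
`promdoc`, and what its synthetic-data experiments do and do not show.

## Corpus preparation

**Merging.** Multiple authored notes (e.g. resident + attending) describing
one visit are concatenated in service order, ties broken by note id, joined
by a fixed improbable delimiter (`@@@|||NOTE-BREAK|||@@@`). Order matters
only for reproducibility; the matcher is order-insensitive. Body length is
conserved: `len(body) = Σ len(texts) + (k−1)·len(delimiter)`.

**Metadata headers.** Each merged note carries a key-value header (patient,
visit, date, facility, consult date, `visit {i} of {n}`, days since/to
neighbouring visits) terminated by a distinct header delimiter. Headers
round-trip losslessly through `parse_metadata_header` and are never scanned
for PROM mentions — they are plumbing, not clinical text.

**Visit categories.** Within one year of the first (consult) visit, each
visit receives exactly one of: FIRST_CONSULT, FINAL_WITHIN_YEAR, PRE_GAP,
POST_GAP, INTERMEDIATE. A *care gap* is an inter-visit interval **strictly
greater than** `gap_threshold_days` (default 60); the ≥/> choice is
configurable since either reading is defensible. When labels collide the
fixed precedence FIRST_CONSULT > FINAL_WITHIN_YEAR > PRE_GAP > POST_GAP >
INTERMEDIATE resolves the tie (a single-visit patient is FIRST_CONSULT; a
final visit that also follows a gap counts as FINAL). Day arithmetic is on
calendar dates, never timestamps.

**Length statistics.** Note length = number of maximal non-whitespace runs.
Histograms use an overflow bin above 2,000 tokens. Group comparisons use
the Kruskal-Wallis omnibus test (rank-based, appropriate for right-skewed
length distributions) with Dunn's rank-based pairwise z tests, tie
correction, and Bonferroni adjustment over m = k(k−1)/2 pairs. No installed
package provides Dunn's test, so the standard statistic is implemented
directly; the omnibus delegates to `scipy.stats.kruskal`.

**Stratified sampling.** The annotation sampler draws per-category quotas
differing by at most one, repeats the draw (default 25 candidates) under a
seeded generator, and keeps the candidate covering the most distinct
facilities — a deterministic emulation of "redraw until facility coverage
is maximal". Shortfalls in a category spill into an unconstrained top-up.

## Lexicon and matcher

**Catalog.** 18 default instruments (spine/pain PROMs; ODI and both
Bournemouth variants among them), each with aliases, uppercase
abbreviations (≥ 2 chars), a fuzzy opt-in flag and a category tag. All
surface forms of the Numerical Rating Scale and Visual Analog Scale are on
an exclusion list that dominates compilation: an excluded surface form
yields no pattern even if also listed as an alias. The default inventory is
a configuration file, not a claim — sites should align it with their local
instrument list.

**Patterns.** Aliases compile to case-insensitive regexes with collapsed
internal whitespace and non-word boundaries; abbreviations compile to
case-sensitive word-boundary regexes (`ODI` never matches inside `ODIN`,
nor lower-case `odi`). Fuzzy matching is a sliding token-window scan:
word-tokens (internal hyphens/apostrophes kept, surrounding punctuation
stripped — the same tokenization used to normalize alias forms) are
compared by restricted Damerau-Levenshtein distance, with a total budget of
`max_edits` (default 1) per alias and edits allowed only in tokens of
length ≥ `min_token_len` (default 5). Abbreviations are always exact. The
rationale: single-character typos are the dominant error class, and
allowing edits in short tokens explodes false positives.

**Overlap resolution.** Among overlapping candidates the longest match
wins, ties by earliest start, then catalog order, then match kind (alias >
abbreviation > fuzzy). So `Bournemouth Questionnaire neck` beats the nested
`Bournemouth Questionnaire`. A consequence worth knowing: adding a lexicon
entry whose matches overlap an existing entry's can legitimately re-segment
a span; monotonicity under lexicon growth holds for non-overlapping
additions.

**Sectionization.** Headers are matched against a configurable lexicon:
line-initial phrases of ≤ 6 tokens ending in a colon (`Subjective:`), plus
`inline: true` patterns that may open a section mid-line without a colon
(`outcome measures`). Every character belongs to exactly one section; text
before the first header is an include-disposition "preamble". The governing
section of a span is the nearest preceding header — even mid-line. This
positional rule intentionally reproduces the known behaviour on
`"Goals of Care: Improve outcome measures, reduce ODI by 20%"`: the
excluded Goals-of-Care section is re-opened by the inline include header,
and the ODI span is kept. We treat this as a documented property rather
than a defect to be patched, since patching it requires semantic rules that
overfit. Default excluded sections: medication lists, allergies,
abbreviation legends, goals of care, patient education/instructions,
template boilerplate.

**Note cast.** A note is PROM-positive iff ≥ 1 span survives filtering;
per-measure flags are derived the same way. Dropped spans are returned as
an audit trail.

## Evaluation

**Span tasks.** Strict pairing counts a true positive only when start, end
and prom_id are all equal (multiset intersection). Soft pairing admits any
pair with ≥ 1 character of overlap and equal prom_id, and computes the
**optimal** one-to-one pairing via an assignment solve (cardinality first,
total overlap as tie-break). A greedy longest-overlap heuristic is not
maximum-cardinality in general (one prediction overlapping two golds can
strand a match), and the package's contract is equality with brute-force
maximum matching, so the assignment formulation is used. Span tasks have no
true negatives.

**Note task.** Standard 2×2 confusion over a shared id set; accuracy
reported when TN exists. Precision = TP/(TP+FP), recall = TP/(TP+FN),
F = 2PR/(P+R), all on the percent scale, one-decimal reporting. Zero
denominators are reported as 0 with a structured warning (degenerate CV
folds must not abort a run); F = 0 iff TP = 0, and min(P,R) ≤ F ≤ max(P,R).

**AUC-ROC.** The Mann-Whitney concordance probability (ties counted half),
computed via `sklearn.metrics.roc_auc_score` and cross-checked in the test
suite against an O(n²) all-pairs oracle. Only defined for probabilistic
models — the rule-based pipeline emits binary decisions and gets no AUC.

**Inter-annotator agreement.** Reported as the pooled soft-boundary,
attribute-constrained F-measure between two annotators' span sets
(symmetric by construction). Note-level percent agreement is a reasonable
alternative reading of "agreement"; span-level F is the stricter statistic
and the one implemented.

**Cross-validation.** Monte Carlo CV: each cycle draws a fresh random
75/15/10 train/dev/test split; 100 cycles by default. Repeated k-fold: per
repeat a k-way partition (label-stratified on request, which pins per-fold
prevalence within ±1 item); cycle *i* takes fold *i* as test, fold *i+1 mod
k* as dev, the rest as training — 8/1/1 at k = 10, and k·repeats = 100
cycles at defaults. Trainers receive (train, dev, seed) and may ignore dev.
One master seed expands to per-cycle seeds by a counter and is recorded in
the summary, so identical seeds give bit-identical summaries. Per-cycle
metrics are summarized as mean ± 1.96·sd/√n (normal approximation); a
percentile summary would also be defensible, but the normal form is the
default because cycle distributions at n = 100 are near-symmetric and the
form is analytic.

## Baselines

The note-categorization baselines are deliberately small, sized for
corpora of hundreds of documents:

* **bow** — logistic regression (L2, C = 1) on unigram+bigram counts over
  whitespace tokens; vocabulary fitted on the training portion only.
* **cnn** — embeddings (d = 16) → one 1-D convolution (window 3, 24
  filters) → ReLU → global max-pool → logistic head, trained per-document
  with Adam (lr 1e-3, 15 epochs, L2 1e-4) on manual numpy gradients;
  documents truncated at 300 tokens; OOV tokens share index 0.
* **ensemble** — α·bow + (1−α)·cnn with α tuned on the development set by
  grid search over {0, 0.1, …, 1} maximizing F.

All expose `scores(texts) → [0,1]` with a 0.5 threshold and are
deterministic given the seed. These are functional baselines, not tuned
competitors; their role is to be compared against the rule-based pipeline
under identical CV machinery.

## Synthetic corpus generator

The generator emulates the structure the pipeline consumes:

* **Visit histories** — visits per patient ~ 1 + Geometric(p = 0.16)
  (median 5), inter-visit intervals 5–20 days, all visits within 365 days
  of consult. With probability `gap_probability` (default 0.25, matching
  the ~25% of patients with a care gap in real corpora of this kind) one
  early interval is forced to 61–120 days, placed so the 1-year window
  never truncates it — so the realized gap fraction equals the configured
  probability exactly in expectation. A consequence of the `1 +` shift is
  that single-visit patients never occur in generated corpora; the
  single-visit precedence rule is covered by direct unit tests instead.
* **Notes** — SOAP-style templates with include sections (Subjective,
  Objective, Assessment, Plan, …) and exclude sections (Medications,
  Patient Education); filler sentences are drawn from a fixed pool that
  contains no lexicon term. With probability `prom_prevalence` (default
  0.17, the documented-use rate this tooling is built around) 1–3 mentions
  are planted in include sections — alias, abbreviation, or (at
  `typo_rate`, default 0.05) a single-edit typo aligned with the fuzzy
  policy — with exact offsets recorded as gold spans. With probability
  `excluded_mention_rate` (default 0.10) a decoy term is planted **only**
  inside an appended abbreviation legend: lexically positive, gold
  negative. First-consult notes draw ~2× the filler sentences, reproducing
  the longer consult-note length structure.
* **Manifest** — seed, config hash and per-stratum counts; the same config
  regenerates the corpus byte-identically.

**What passing on synthetic data shows — and what it does not.** The
generator plants mentions as clean sentence-level insertions, so
clean-corpus recall of 100% demonstrates the matcher's mechanics (offsets,
boundaries, sectioning, filtering), not robustness to real clinical
language: creative misspellings beyond one edit, OCR noise, novel
instrument names, tables, or terms embedded in templated boilerplate are
all absent. Likewise the ablation result (filtering removes all
decoy-driven false positives) certifies the filter's logic, not the
completeness of any site's section lexicon. Typo'd multi-word mentions can
be recovered with slightly different boundaries than the planted span
(punctuation at token edges), which is precisely why soft-boundary scoring
exists.

## Numerical and degenerate-input conventions

Offsets are 0-based, half-open, code-point based. Percentages are reported
to one decimal. Empty span lists are valid inputs everywhere; empty
denominators raise or warn as documented per function. `summarize_cycles`
requires ≥ 2 values (a single cycle has no spread; CV summaries degrade to
a zero-width interval in that case). Seeds are kept below 2³¹ so they are
valid for every underlying generator.

## Known limitations

* The section grammar is positional; nested include-inside-exclude regions
  beyond the inline-header mechanism are not modeled.
* Fuzzy matching is bounded at one edit per alias by default; heavier
  corruption requires raising `max_edits`, at a precision cost.
* The default catalog and section lexicons are starting points; real
  deployments must localize both.
* The baselines are desk-scale reference implementations; no pretrained
  embeddings or large language models are used.
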