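# Methods

## The disambiguation model

The package treats abbreviation expansion as sense ranking by binary pair
classification. Each occurrence of an ambiguous abbreviation is stored in a
six-field schema — `index, target, left, right, label, negs` — where the
target abbreviation is kept in its original written form and "marked" purely
by its position between the left and right context (no inline sentinel
tokens, so candidate strings can contain arbitrary punctuation without
collision). The sense inventory maps each surface form to its admissible
expansions; it is the union over the corpus of `{label} ∪ negs`,
deduplicated and lexicographically ordered so every downstream enumeration is
reproducible.

An instance with *n* candidates becomes *n* two-segment token sequences
(`[CLS] context [SEP] candidate [SEP]`), exactly one labelled 1. At
prediction time the same sequences are scored and the argmax of the class-1
probability wins; exact ties go to the lexicographically smaller candidate.
This one-to-all formulation shares a single model across all abbreviations
and naturally extends to unseen abbreviations whose candidates have
informative context statistics.

### Truncation

Sequences longer than the token budget (default 512) are trimmed
first-in-first-out: the oldest tokens of the combined
`left + target + right` context stream are removed until the sequence fits.
Two deliberate properties:

* the candidate segment is never trimmed — it is the class descriptor;
* the target abbreviation is **not** protected — if it sits early in a long
  context it can be truncated away. This mirrors the known failure mode of
  FIFO trimming and is surfaced rather than hidden.

The alternative reading (trim only the left context) was considered and
rejected in favour of oldest-of-the-full-stream, which is simpler and treats
left/right symmetrically. Duplicate pairs that can arise after truncation are
kept, not deduplicated. A truncated sequence must retain at least one context
token; otherwise a capacity error names the offending candidate.

### Classification head

The head is two linear layers with a rectified linear unit between them:
pooled input vector → hidden width 50 → 2 logits → softmax. Both widths are
configurable but default to (50, 2). The head is implemented in numpy with
float64 arithmetic and a max-shifted softmax; it is verified against a
loop-level brute-force oracle to 1e-9 on randomized small instances.

### Scorer backends

Two backends satisfy the same contract (`score(pair) → p₁ ∈ [0, 1]`,
bit-reproducible for a fixed trained scorer):

* **lexical** — logistic regression (liblinear, C = 10, seeded) over sparse
  named features of the pair: a candidate-identity indicator,
  candidate × context-word co-occurrence counts, the number of candidate
  tokens literally present in the context, and the candidate token length.
  The co-occurrence features let the model learn which context vocabulary
  signals which sense; the identity feature lets it learn a per-candidate
  prior (critically, a candidate that only ever appears with label 0 acquires
  a strongly negative weight and can never win the argmax — the mechanism
  behind the unseen-sense behaviour in the incremental protocol).
* **mlp** — the (50, 2) head itself, trained end to end by seeded mini-batch
  gradient descent (softmax cross-entropy, default 3 epochs, learning rate
  0.1, batch 16) on an L2-normalized 1024-dimensional signed-hash encoding
  (crc32) of the same sparse features. This exercises the head architecture
  for real; an encoder-based backend would satisfy the identical contract by
  replacing the hashed features with its pooled `[CLS]` vector and is out of
  scope here.

Training rejects degenerate inputs (empty, or single-class) rather than
silently fitting. Scorer archives are a directory with a JSON manifest
(backend, config, seed, format version) plus a JSON parameter file; loading a
corrupted or version-mismatched archive raises a format error.

## Evaluation

Per abbreviation: a confusion matrix over its candidate expansions (gold ×
predicted), instance count, correct count and accuracy. Corpus level:
macroaccuracy is the unweighted mean of per-abbreviation accuracies —
averaging over abbreviations, not over senses — and microaccuracy is pooled
correct/total, algebraically the instance-count-weighted mean of the
per-abbreviation accuracies. All accuracies are on the percent scale;
human-readable tables print two decimals, JSON keeps full precision.

## Experiment protocols

**Coverage-constrained split.** A seeded shuffle partitions the corpus at a
9:1 ratio (no cross-validation), after screening so that every
(abbreviation, gold sense) class lands in training at least once — a sense
with no training pairs is unlearnable by a pair classifier. Singleton classes
are forced into training; if the constraint pushes the training side above
the requested fraction, a warning is attached rather than an error.

**Incremental cross-site learning.** "Documents" are instances (one marked
abbreviation occurrence each). A base-corpus scorer is evaluated on a
new-site corpus (k = 0), then k ∈ {5, 10} site documents — selected by a
seeded round-robin stratified across abbreviations, so prefixes give nested
selections — are added to the training pair multiset and training continues;
evaluation uses the remaining site instances. For the convex lexical backend,
"continuing" is a refit on the expanded multiset, which reaches the same
optimum as warm-started descent; the mlp backend resumes gradient descent
from its current parameters. Selected documents are excluded from the test
side, and k = 0 is bit-identical to evaluating the base scorer on the full
site corpus.

## Synthetic data generator

The generator emulates the *structure* of clinical disambiguation corpora,
not clinical language: a configurable number of abbreviations (default 5,
echoing a five-abbreviation validation set), each with 2–6 candidate
expansions, 20 instances per sense, and contexts sampled as exchangeable word
multisets. Each sense owns a disjoint 8-word signature vocabulary; every
context word is a signature word with probability `p_sig` (default 0.8) and
a background word (200-word shared vocabulary) otherwise, so `p_sig` dials
separability from chance (0) to perfect (1). Context lengths are uniform in
a configurable range (default 3–12 words per side); setting the maxima above
the token budget guarantees the truncation path is exercised. Expansions are
two random words so candidates tokenize to multiple tokens.

A second "site" shares surface forms and candidate sets but shifts the
distribution three ways: a fraction of (abbreviation, sense) classes has zero
base-corpus instances (at most one per abbreviation, so base coverage of the
rest survives); a fraction of signature vocabulary is replaced by
site-specific words; and the sense prior of an affected abbreviation moves
toward its withheld sense. An oracle classifier that sees the true signature
vocabularies (which no trained scorer does) provides the independent accuracy
ceiling; everything is a pure function of the configuration, with the master
seed expanded into named substreams (string-seeded `random.Random`, stable
across runs and Python versions).

Because contexts are bag-of-words with disjoint signatures, passing tests
demonstrate that the pipeline machinery — pair construction, truncation,
training, ranking, splitting, adaptation — behaves correctly when the lexical
signal is present; they do not demonstrate robustness to real clinical
phenomena (negation, syntax-borne cues, misspellings, overlapping sense
vocabulary, label noise).

## Problem sizes and structural-check scenarios

The shipped experiment scenarios use 5 abbreviations × 2–6 senses × 20
instances per sense (several hundred instances, a few thousand pairs) — large
enough for stable accuracy estimates with the deterministic backends, small
enough to run in seconds on one CPU. The unseen-sense incremental scenario is
run at `p_sig = 1.0` with 6–12-word sides: it is a structural check (a sense
with only negative training pairs can never win the argmax; a handful of
added site documents makes it learnable), so the clean perfect-signal
condition is used rather than a noisy one where one-shot learning from a
single short context would be a coin flip.

## Numerical choices and edge cases

* Softmax is computed with max-subtraction; probabilities sum to 1 within
  1e-9 over randomized heads.
* Normalization lowercases and maps every character outside an explicit
  whitelist (letters, digits, space, `. , ( ) / - #`) to a space, collapsing
  runs; it is idempotent, never touches the target surface form (when
  `preserve_target` is set), and never touches labels or negatives, which are
  inventory keys.
* The canonical TSV stores negatives comma-joined and therefore rejects
  expansions containing commas; the JSONL corpus format carries them
  losslessly.
* Candidate strings are compared case-sensitively after whitespace trimming.
* Ties in ranking and in the oracle break lexicographically.
* `round()` (banker's rounding) sets the training-set size from the fraction;
  the split clamps to leave at least one instance on each side before the
  coverage constraint applies.

## Known limitations

* No encoder backend ships with the package; the contract is designed for
  one, but all shipped scorers are lexical-feature models, so results on
  synthetic corpora say nothing about transformer fine-tuning quality.
* The whitespace tokenizer is the pipeline default; the WordPiece tokenizer
  requires a user-supplied vocabulary and is used for subword-layout tests.
* The generator's bag-of-words assumption makes separability essentially
  monotone in `p_sig`; real corpora mix signal types and are harder.
* Incremental adaptation with the lexical backend refits on the combined
  multiset; with very large base corpora this is O(total pairs) per k.
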