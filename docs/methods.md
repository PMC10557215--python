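# Methods

This note documents the models, conventions and defaults behind `slrminer`,
the choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Task and data model

The package extracts typed entity mentions and typed relations from
clinical-style text for systematic-review data extraction.  An *extraction
schema* is pure data: an ordered list of entity types plus relation rows,
each row either a directed `refers_to` link between two named types or the
symmetric `equivalent` link with unconstrained (`ANY`) arguments.  Two
presets ship with the package: `slr1` (oncology outcomes: treatment arms,
dosages, progression-free-survival metrics and results, study type, title,
authors) and `slr2` (renal function: eGFR metric/number/subgroup/time point,
age metric/number, arms, dosages, study type).  The `slr2` preset contains a
directed `eGFR metric → age number` row; it is kept verbatim from the source
schema without further interpretation.

Character offsets are 0-based and half-open throughout, matching the BRAT
standoff convention — the interchange format of the annotation tooling this
package interoperates with.  `equivalent` is modelled as unordered; when
serialised, its arguments are emitted in document-offset order, which makes
round trips canonical.

Sentence segmentation is rule-based (terminal punctuation with decimal and
abbreviation guards), not model-based, so it is deterministic and
dependency-free.  Paragraphs are blank-line blocks.  Dataset partition
operates at *paragraph* granularity with uniform random allocation
(unstratified) and largest-remainder rounding, so split sizes are exact and
deterministic for a given seed; relations whose arguments land in different
paragraphs cannot survive a paragraph-level split and are dropped with a
log message.

### BIO conventions

Single-layer BIO cannot represent overlapping mentions, so overlapping gold
annotations are resolved before tag conversion by keeping the longer mention
(tie: earlier start); drops are logged.  Mention boundaries falling mid-word
are snapped outward to word boundaries, since tagging is word-granular.
Mentions crossing a sentence boundary are split at the boundary for
training; optional re-merging of adjacent same-type runs across sentences is
available at prediction time but off by default.  Discontinuous BRAT spans
are rejected: the supported schemas annotate contiguous phrases.

## Tokenisation

Two stages: (1) word splitting on whitespace and punctuation, every
punctuation mark becoming a single-character word; (2) greedy
longest-match-first WordPiece decomposition against a vocabulary,
continuation pieces prefixed `##`, unmatched words mapping to `[UNK]`.
Lowercasing is on by default.  Word classifiers consume only each word's
*first* piece vector, so the tokeniser also exposes a first-piece mask.

The vocabulary builder is frequency-based over the training text and always
includes every single character seen (plus `##` continuations), which
guarantees that any word over the training alphabet decomposes without
`[UNK]` — numbers and unseen drug names degrade gracefully to character
pieces.  Loading an external one-piece-per-line vocabulary file is
supported but never required.

## Encoders

Two interchangeable contextual encoders map wordpiece ids to per-piece
vectors:

* **transformer** — pre-norm self-attention encoder with learned positional
  embeddings.  Desk-scale defaults: 2 layers, width 128, 4 heads, maximum
  sequence 256 pieces, trained from random initialisation.  Width 768 and
  more layers are plain configuration changes.
* **bilstm** — the conventional baseline: one forward and one backward LSTM
  pass whose outputs are concatenated (width split across the two
  directions, so the hidden width must be even).

Both are implemented on a small reverse-mode autodiff core over float32
numpy arrays (`slrminer.nn`): broadcasting arithmetic, batched matmul,
stable `softmax`/`log_softmax`/`logsumexp` primitives and gather/scatter
indexing.  Float64 inputs keep their precision end to end, which is what
the CRF correctness tests use to compare against exhaustive enumeration at
1e-6 tolerance.  Everything is single-threaded and seeded, so training runs
are bit-reproducible.

Masked-language-model pretraining is available at desk scale: 15% of
positions are sampled per sentence (80% replaced by `[MASK]`, 10% by a
random piece, 10% kept), and only sampled positions contribute to the
cross-entropy.  Pretraining is optional everywhere; the benchmark results
below are from-scratch.

## Decoders

Emission scores over the BIO label set (`2·|types| + 1` labels, `O` at
index 0) come from a linear head on the selected first-piece vectors.

* **linear** — position-wise argmax (ties towards the lowest label index,
  i.e. `O`), followed by a repair pass rewriting stray `I-x` to `B-x`.
* **crf** — linear-chain CRF with transition, start and end scores.  The
  normaliser is computed by the forward recursion in log space; decoding is
  Viterbi with deterministic tie-breaking (lowest label index).  BIO
  validity is enforced structurally: an additive constraint mask pins
  forbidden transitions (`O → I-x`, `B-y → I-x` for `y ≠ x`, start at
  `I-x`) at −10⁴, a finite stand-in for −∞ that keeps float arithmetic
  clean while making forbidden paths numerically irrelevant.  The mask is
  not trainable, so a constrained CRF can never emit an invalid sequence —
  the repair pass is unnecessary for it by construction.

Training minimises per-word cross-entropy (linear) or sequence NLL
`log Z − score(gold)` (CRF) with Adam, linear warm-up over the first 50
steps, gradient-norm clipping at 5, and batches of 32 sentences bucketed by
(piece count, word count) so no padding or masking is ever needed.  Default
learning rates are 5e-4 for the transformer and 2e-3 for the BiLSTM —
recurrent nets trained from scratch need the larger step to leave the
all-`O` regime; both values were fixed during development and recorded in
the training configuration.  Model selection keeps the epoch with the best
validation relaxed F1.  Models serialise to a single `.npz` archive
(config + vocabulary + parameters) and reload bit-exactly.

## Relation extraction

Sentence distance is the absolute difference of the containing-sentence
indices of the two argument *start* offsets: same sentence ⇒ 0, so a
"3-sentence window" admits distances 0–3 inclusive (the reading consistent
with corpus statistics of the form "at most three sentences in 92% of
cases").  Candidate pairs are exactly the type-admissible ordered pairs
within the window; symmetric labels contribute each unordered pair once, in
canonical offset order.  Negatives are all admissible within-window pairs
without a gold relation (no subsampling by default; a ratio cap is
configurable) — the window restriction already bounds their number.  Gold
relations beyond the window are dropped from training and counted.

**Relation classification (one step).**  The window text (sentences from
the first argument's to the second's) is encoded with learned *marker
embeddings* added to the piece representations of the two argument spans;
the classifier input is the concatenation of the mean-pooled window
representation and the two arguments' first-piece vectors, over
`{refers_to, equivalent, no_relation}`.  Predictions are filtered to
schema-admissible outputs, and `equivalent` is classified once per pair in
canonical order.  Marker-based argument encoding is this package's design
choice; it is the standard realisation of "the same architecture as entity
recognition, with two provided entities".

**Role labelling (two steps).**  Given a query mention, step one tags the
words of its ±window context (query span marked) with BIO over role
classes — `arg1_of_refers_to`, `arg2_of_refers_to` (naming the found
span's argument slot) and `equivalent` — step two maps each recovered span
to the best-overlapping known mention and types its relation to the query,
keeping only schema-admissible outputs.  The two-step decomposition is one
defensible reading of a "find related entities, then type the relation"
architecture; the precise original is underdetermined, and this
implementation is labelled as the package's own.

## Evaluation

`precision = correct/predicted`, `recall = correct/actual`,
`F1 = 2PR/(P+R)` (0 when both are 0; zero-denominator cases are reported
as 0 with an explicit `*_defined` flag).  Strict entity matching requires
identical span and type; relaxed requires the same type and an overlap of
at least one character (no minimum-fraction threshold).  Pairing is
one-to-one per document: exact-boundary pairs are seeded first in document
order, then the assignment is grown to a *maximum-cardinality* bipartite
matching by augmenting paths (preferring larger overlaps).  Augmentation
never unmatches a matched vertex and the relaxed edge set contains the
strict one, so relaxed F1 ≥ strict F1 holds for every input, and the
reported counts equal the maximum matching — verified in the tests against
an independent matching oracle.  One gold span never credits more than one
prediction.

Relations match when the label agrees and each argument matches the
corresponding gold argument (relaxed argument spans by default,
configurable); symmetric labels match in either order.  Reports cover
overall, per-type and per-entity-type-pair scores.  Confusion matrices give
each gold mention one row event — the type of its relaxed-matched
prediction (same-type pairs made first, then cross-type by overlap) or
"unlabelled" — with raw counts conserved per row and percentages rounded to
one decimal.

## Synthetic corpus generator

The generator emulates the *structure* of annotated review corpora, which
are typically copyright-encumbered and not redistributable.  Documents are
assembled from relation *clusters*, one paragraph each: a study-type
statement; one arm-description/arm-dosage cluster per treatment arm (1–4
arms per document); an optional `equivalent` cluster re-mentioning an arm;
and, each with probability 0.5, one cluster per remaining admissible pair
kind (eGFR metric→number/subgroup/time point/age number, eGFR
number→subgroup, age metric→number).  Within a cluster, the pair's sentence
distance *d* is drawn from `distance_mix`, a distribution over distances
0–5 defaulting to (0.50, 0.22, 0.12, 0.08, 0.05, 0.03) — placing 92% of
related pairs within 3 sentences and echoing the corpus statistic that
motivates 3/5-sentence context windows; distance is realised as a merged
single-sentence template (d = 0) or head + (d−1) distractors + tail.
Entity-free distractor sentences (rate 0.3) keep the `O` class dominant.
Slot phrases echo the style of review text ("median progression-free
survival", "20.5 mL/min/1.73 m2", "Among patients >60 years old", "at
4-month follow-up"); numeric slots are drawn from plausible uniform ranges
and are generator parameters, not clinical claims.  `relation_density`
(default 1.0) controls the fraction of eligible slot pairs actually
annotated.  With 500 documents and a 77% training share, every admissible
pair kind clears 150+ training relation examples.

Every generated span equals its text slice exactly, every relation
validates against the schema, and generation is byte-reproducible per seed;
a ledger records each document's clusters, distances and per-pair counts.

**What passing tests show — and don't.**  The templates have limited
lexical variety, no anaphora, no tables, no nested or overlapping entities,
and no genuinely ambiguous boundaries, so scores here are upper bounds on
real-text behaviour.  The benchmark validates the *machinery* — tagging,
windowed relation classification, evaluation, reproducibility — not
biomedical language understanding.  Difficulty comes from held-out slot
values (numbers are always unseen; drug names decompose to character
pieces) and from multi-arm documents where several same-kind clusters must
be disentangled by proximity and ordering.

## Benchmark configurations and observed behaviour

The test suite trains from scratch on one CPU at these problem sizes
(chosen to keep the default run in minutes):

* **Entity recognition**: 400/50/50-document corpora, transformer+CRF and
  BiLSTM+linear, 4 epochs.  The suite asserts held-out relaxed F1 ≥ 0.90
  for transformer+CRF and that it strictly exceeds BiLSTM+linear — the
  expected ordering of contextual-encoder quality, asserted on synthetic
  data only.
* **Relation classification**: 500 documents split 77/11.5/11.5 at
  paragraph level, window 3, 2 epochs; the suite asserts per-pair F1 ≥ 0.90
  on every pair with ≥ 80 training examples, the data-sufficiency threshold
  this task exhibits.  `scripts/acceptance.py` recomputes this number from
  scratch.
* Overfitting sanity runs (tiny 32-wide encoders) verify both relation
  architectures recover their own training relations.

## Numerical and degenerate-input conventions

* Ties: argmax always takes the lowest index; label 0 is `O`.
* Empty ann file ⇒ a document with no annotations; empty document ⇒ no
  predictions; empty candidate set ⇒ no relations.
* Sequences longer than the encoder maximum are truncated at word
  boundaries with a log message during dataset preparation; the encoder
  itself rejects over-length input.
* The split of a corpus with fewer than 3 paragraphs is refused; ratios
  must sum to 1 within 1e-9.
* All randomness flows from explicit integer seeds; the CLI fans a single
  global seed out to per-stage seeds by stage-name hashing (CRC32), keeping
  stages independently reproducible.

## Known limitations

* No PDF/XML ingestion, no annotation GUI, no ontology normalisation of
  extracted terms, no cross-document or n-ary relations, no
  bootstrap confidence intervals.
* First-piece word representation discards the rest of a word's pieces;
  alternative pooling is a possible extension.
* The BiLSTM baseline is intentionally minimal (single layer by default).
* Role labelling underperforms relation classification and needs more
  epochs to train — consistent with it solving a strictly harder task.
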