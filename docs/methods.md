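# Methods

## Problem setting

A care-record application proposes a sentence (the *suggestion*) and the
caregiver's actually recorded sentence is the *ground truth*.  The package
scores the informational similarity of such a pair on [0, 1], and provides
a harness for validating any pair metric against human similarity
judgments by correlation.  Care-record sentences are short (the working
regime is ≤ 13 tokens per side), frequently subject-less, and rich in
domain terminology, which motivates a representation built on subword
embeddings and topics rather than on exact n-gram overlap.

## The EmbedHDP model

### Tokenization

Sentences are NFKC-normalized and segmented either by whitespace
(pre-segmented or synthetic input) or by a pluggable morphological
analyzer producing wakati-style surface tokens.  Japanese particles
(は, へ, で, を, の, て, ます, し, あり, ある, する, なる by default)
are re-attached to their host word by an explicit post-pass: an analyzer
normally emits them as standalone tokens, but as standalone tokens they
carry no content of their own while still diluting the representation.
The merge is a deterministic fold into the preceding token (a
sentence-initial particle attaches forward instead), conserves the
character multiset, and the particle list is user-extensible.
Lemmatization and stemming are deliberately skipped: surface forms carry
grammatical information that matters in this domain.

### Embeddings

A backend maps a token to a dense vector of fixed dimension,
deterministically.  Production use loads a pretrained subword model (the
300-dimensional Japanese fastText model); development and testing use a
hash backend that composes seeded pseudo-random unit vectors keyed by the
token's character n-grams (n = 2…4 plus the whole token, boundary-marked)
and L2-normalizes their mean.  The n-gram construction reproduces the
property the method depends on: out-of-vocabulary and rare medical terms
still get vectors, and orthographically related tokens correlate.  Vector
derivation uses a keyed BLAKE2 digest, not Python's process-salted
`hash()`, so backends are bit-reproducible across processes.

### Quantization into pseudo-Bag-of-Words

Topic models consume (term, count) documents.  The bridge treats
embedding *dimensions* as pseudo-terms: per token vector, negative
components are clipped to zero (an absolute-value mode exists), the
L = 10 largest components are kept (ties break toward the lower dimension
index, for determinism), and survivors are scaled by 100.  Raw components
of a normalized vector are small and nearly flat; without the scaling the
fitted topics collapse onto each other.  Clipping is the minimal
treatment that actually guarantees the positivity a count-style document
requires — scaling alone cannot.  Weights stay real-valued: the topic
model accepts fractional counts, and rounding would erase exactly the
small component differences the scaling preserves.  Summing per-token
documents yields the sentence document; the pair [C₁, C₂] with the union
dictionary D is the entire training corpus.

Two dictionary modes exist: the default builds D from the pair alone; a
*lexicon mode* additionally seeds D with the quantized terms of a
user-supplied domain word list (one term per line, `#` comments), so
curated care-record vocabulary shapes the term space even when absent
from the pair.  Both are exposed because either is defensible; the
pairwise mode is the default.

### The HDP and its inference

The model is the two-level stick-breaking hierarchical Dirichlet process:
corpus-level sticks (concentration γ) define global topic weights σ;
each document draws its own sticks (concentration α) over *tables* that
point at global topics; topics φₖ are Dirichlet(η) over the pseudo-term
vocabulary.  The number of topics is not a model parameter — T (global)
and K (per document) truncate only the variational posterior.

Inference is batch coordinate-ascent variational Bayes with the standard
mean-field factorization (Dirichlet topics, Beta sticks at both levels,
multinomial table-to-topic and term-to-table responsibilities).  Defaults:
γ = α = 1, η = 0.01, T = 150, K = 150, at most 100 sweeps with a
convergence tolerance of 10⁻⁶ (relative to the total corpus weight) on
the topic-matrix change.  Early stopping is deterministic, so a
(corpus, params, seed) triple reproduces the fitted state bit-for-bit.

Three inference-side choices deserve emphasis, because a textbook setup
degenerates on a two-document corpus:

- **K equals T (one table per distinct term).**  A pseudo-document has
  roughly as many distinct terms as the embedding dimension engaged by
  its tokens (tens).  If K is much smaller, unrelated terms are forced to
  share tables, each table must commit to a single topic, and the
  groupings differ between the two documents — the converged fit then
  assigns each document one private topic and the score collapses to a
  same/different indicator.
- **Term-anchored topic initialization.**  The topic matrix is
  initialized as η plus a small seeded jitter, plus unit mass anchoring
  term v to topic v mod T.  The initial term→topic affinity is therefore
  injective and *identical for both documents*, so shared terms land in
  shared topics.  A symmetric random initialization instead maps terms to
  arbitrary topics and chance collisions between unrelated terms dominate
  the pair score.  The coordinate ascent remains free to merge or reshape
  topics where the data support it.
- **Round-robin table seeding.**  Document-side responsibilities start
  with term i on table i mod K.  A uniform start leaves all tables
  identical forever (the updates preserve the symmetry), which is the
  same single-private-topic degeneracy.  The seeding is a deterministic
  function of the document, so identical documents receive identical
  factors — which is what makes score(s, s) = 1 hold to machine
  precision rather than approximately.

A document's topic distribution is re-inferred from the frozen global
state (deterministic initialization, same tolerance), making it a pure
function of (model, document): θₖ = Σₜ E[πₜ] ζₜₖ, normalized.  The final
score is the cosine of the two θ vectors, clamped to [0, 1] against
floating-point excursions.

With these choices the score responds smoothly and monotonically to
token-level overlap (verified by the test suite on seeded synthetic
pairs), rather than jumping between ~0 and 1.  All hyperparameters remain
configuration-exposed.

### Length filter

Pairs where either side exceeds `max_len` = 13 tokens (under the active
tokenizer configuration — the filter counts what the metric consumes) are
excluded from benchmarking rather than scored: long sentences pack
several information units into one pair document and the two-document
topic fit cannot resolve them.  The filter is a pure partition: kept and
removed preserve input order and always sum to the input.

## Baseline metrics

Implemented from their definitions, for the comparator panel:

- **BLEU** (sentence level): geometric mean of clipped n-gram precisions,
  n = 1…4, times the brevity penalty exp(1 − r/c) for c < r.  Two
  accommodations for very short sentences: zero precisions are floored at
  10⁻⁹, and the order is capped at the shorter sentence length
  (*effective order*) — otherwise no two-token sentence could score 1
  even against itself.
- **ROUGE-N**: clipped n-gram overlap as precision/recall/F (β = 1).
- **ROUGE-L**: longest common subsequence by the standard dynamic
  program; P = ℓ/|cand|, R = ℓ/|ref|.
- **BoW cosine**: cosine of term-frequency vectors over the union
  vocabulary — order-insensitive by construction.
- **BERTScore** is an adapter slot only (any callable mapping a raw-text
  pair to [0, 1]); contextual-embedding metrics are out of scope.

## Benchmark harness

CSV/TSV datasets with columns `suggestion`, `ground_truth`, and `human`
or `human_1..k` (plus optional `id`) load into pair records; malformed
rows are rejected with their 1-based line numbers.  The harness applies
the length filter, scores each panel metric on the kept pairs, and
reports Pearson's r (Spearman behind a flag) between metric scores and
the per-pair mean (or median) of the rater scores.  Human scores are used
on their native scale — correlation is affine-invariant, so no
normalization is imposed.  A metric failing on one pair loses that pair
(logged, excluded from its n_used); a metric with undefined correlation
(zero variance) is reported as such without aborting the panel.  Report
serialization is canonical (sorted keys), hence byte-stable for a fixed
configuration and seed.

## Synthetic data generator

Each pair carries a latent overlap θ ~ U(0, 1).  The ground truth draws
its tokens from one half of a synthetic vocabulary (with probability 0.2
one token is replaced by a pseudo-medical lexicon term, exercising the
domain-dictionary path); the suggestion copies ⌈θ·ℓ⌉ ground-truth tokens
in order — the kept positions are a prefix of a θ-independent permutation,
so at fixed seed a larger θ strictly extends the copied set — and fills
the rest from the *other*, disjoint vocabulary half, making θ = 0 exact
zero overlap and θ = 1 an exact copy.  Each of 3 simulated raters reports
θ + N(0, sd) clamped to [0, 1] (sd = 0.1 by default, on the score scale).
A configurable share of pairs (default 10%) is drawn at 14–18 tokens per
side to exercise the filter with known labels; both sides of a pair share
one length, mirroring the equal-length character of the intended data.

What the generator emulates: graded informational overlap, multi-rater
noise, filter-boundary lengths, occasional domain terms.  What it does
not: real Japanese morphology and syntax (tokens are symbolic), rater
bias and scale effects, paraphrase without lexical overlap (synonymy) —
so a high metric–human correlation here demonstrates that a metric tracks
*content overlap under noise*, not that it resolves true semantic
paraphrase.  The benchmark's default problem size (200 pairs, 64-dim hash
embeddings) keeps a full panel run in the low seconds while leaving ~180
pairs after the filter.

## Numerical and degenerate-input policy

- All-zero embedding vectors quantize to an empty document; emptiness is
  policed where sentences are assembled (`DegenerateDocumentError`), so
  callers can attribute the failure to a pair id.
- Empty sentences, unknown dictionary ids, zero distributions, schema
  and row errors, and undefined correlations each raise a distinct
  exception type; batch scoring converts per-pair failures into logged
  row exclusions.
- Topic distributions are validated to sum to 1 within 10⁻⁸ and be
  non-negative; cosines are clamped to [0, 1].
- Every stochastic component (hash backend, HDP jitter, generator) is
  seeded explicitly; there is no hidden global random state.

## Known limitations

- The pair-corpus HDP sees exactly two documents; its absolute score
  scale depends on the embedding backend and quantization settings, so
  scores are comparable within a configuration (`config_digest` stamps
  each score) but not across configurations.
- Long sentences (> 13 tokens) are excluded, not handled.
- The hash backend mimics subword geometry but not distributional
  semantics: synonyms without shared character n-grams are unrelated
  under it; validating semantic (rather than lexical) similarity requires
  the pretrained backend.
- Morphological segmentation requires an external analyzer; token counts
  (hence the filter boundary) depend on the analyzer and dictionary
  version used.
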