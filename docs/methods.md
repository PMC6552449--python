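# Methods

## Model

The pipeline treats consumer-health-vocabulary mining as supervised metric
adaptation of an unsupervised word-embedding space.

**Pretraining.** An embedding matrix `E` (vocabulary size `v` × dimension
`e`) is trained on a tokenized message corpus by one of four method
families behind a uniform contract: skip-gram or CBOW with negative
sampling, GloVe (AdaGrad on the weighted least-squares objective over log
co-occurrences, final vectors the sum of the main and context matrices),
or a FastText-style variant (skip-gram whose input representation averages
the word vector with hashed character 3–5-gram bucket vectors).  The
trainers are implemented in-package as single-threaded numba kernels, so a
fixed seed reproduces matrices bit-for-bit.  Defaults: window 5, epochs 5,
5 negative samples, unigram^0.75 negative-sampling distribution, linear
learning-rate decay from 0.025 (SGNS) / AdaGrad at 0.05 with x_max 10
(GloVe, chosen for small co-occurrence counts).  `E` is frozen after
pretraining.

**Projection.** The adapted representation of a word with one-hot column
`M` is `P = S·E·M`, with `S` an `s × e` matrix, `s < e`, initialized
i.i.d. uniform on `[−a, a]`, `a = √(6/(s+e))` (a symmetric Glorot-style
range: "uniform" needs a scale, and this one keeps projected norms stable
across `s`).  One shared `S` projects both the professional and the
consumer side, which keeps similarity symmetric.  The default
`s = 0.4·e` rounded to a multiple of 10 (minimum 10): large enough to
preserve the unsupervised geometry that supervision then sharpens, small
enough to regularize; at `e = 50` this gives `s = 20`, and substantially
smaller `s` measurably hurt held-out retrieval in development.  When the
labeled set grows, `expand_projection` appends freshly initialized rows to
`S` while keeping the trained rows bit-identical.

**Supervision.** For query ω_v with labeled synonyms Syn(ω_v), desired
ranks rank\*(ω_r) = 1..k are assigned by corpus frequency (most frequent
synonym first, ties lexicographic).  Supervision runs bidirectionally by
default: consumer terms also act as queries of their professional
counterparts.  The monitoring ranking loss is
Σ |rank(ω_r) − rank\*(ω_r)| (a squared variant is available); since ranks
are not differentiable, training minimizes the surrogate
`(f(ω_v)[rank*] − cos_proj(ω_v, ω_r))²` where `f(ω_v)` is the descending
similarity list of the candidate pool.  The target value is
stop-gradiented and refreshed once per epoch — it moves as `S` moves, and
a per-epoch refresh keeps the cost at one pool projection per epoch while
remaining stable.  The squared difference is symmetric: a synonym sitting
*above* its desired slot is pulled down as well.

**Optimization.** Plain mini-batch SGD on `S` (batch 32), learning rate
0.5, 100 epochs.  The rate looks large, but surrogate residuals live on
the cosine scale (typically 1e-2…1e-1 here); rates near 1e-2 produce
updates too small to ever change a rank, while 0.5 converges in tens of
epochs and was stable across all generator seeds tried.  Divergence (NaN
in `S`) raises with advice to lower the rate.  The candidate pool during
training is the top-1000 most frequent tokens plus all seed-pair members,
special tokens excluded; similarity ties break by higher frequency then
lexicographic order, making every rank a strict total order and training
deterministic given the seed.

**Baselines.** `projection size 0` is a log-linear baseline: `S` is the
identity and only its diagonal trains — a bias-free reweighting of the raw
embedding features under the same surrogate.  `update_embeddings=True` is
the no-projection comparison: the embedding rows themselves are the
parameters (on a model-local copy; the pretrained `E` is never mutated).
Only labeled words receive updates there, so nothing transfers to held-out
concepts — the motivating argument for the projection, and the behaviour
the acceptance suite verifies.

**Retrieval and review.** Candidates are ranked by cosine in the adapted
space over the full vocabulary minus special tokens (the training-pool
restriction does not apply at inference).  `new_term_entropy` softmaxes a
consumer term's cosine similarities to all professional terms
(temperature 1 by default — the plainest reading; configurable) and
returns the Shannon entropy in nats: near 0 means the term aligns with one
existing concept, near log n means no good match exists and a new
professional term may be needed.  Review sheets are TSVs with a blank
decision column; accepted rows re-enter training via
`iterate_with_review`.

**Evaluation.** MRR uses the rank of the *first* relevant synonym per
query; a synonym absent from the returned list contributes 0 (standard
truncated-MRR convention).  Mean first-relevant rank is reported
separately — it is a different statistic and the two should not be
conflated.  The protocol sampler draws evaluation pairs without
replacement, reproducibly, and keeps them disjoint from training.  The
experiment harness sweeps methods × dimensions (before/after fine-tuning)
and projection sizes including the size-0 baseline.  The study helper
evaluates held-out pairs in both query directions: with 20 concepts and a
70/30 concept-level split, professional-only evaluation has just 6 queries
and MRR becomes too coarsely quantized to measure improvement.

## Preprocessing

URLs (scheme:// or www. prefixes) become a shared `URL` token; tokens with
corpus frequency strictly below `min_count` (default 30) become `UNKNOW`.
Both special tokens are always in the vocabulary and never returned as
candidates.  Professional-term selection keeps terms with frequency
strictly above `min_freq` (default 1000).  Tokenization is an injected
interface (whitespace by default); multi-token terms are merged to
underscore-joined single tokens by a pre-pass, since the pair machinery
treats terms as single vocabulary units.

## Synthetic data: what it emulates and what it does not

Each of `n_concepts` (20) concepts has one professional token, 
`synonyms_per_concept` (2) consumer tokens, and `context_size` (8) context
tokens drawn Zipf-weighted from a shared pool sized
`context_pool_frac` (0.5) × the total context demand — shared contexts
mirror symptom words serving several related diseases and keep distractors
heterogeneous.  Messages (5000 of length 12) emit one target token
(professional with probability 0.6, else a consumer variant) embedded in
draws from the concept's context set; every slot may be replaced by
Zipfian background noise (`noise_rate` 0.1), and consumer-variant messages
mix in additional background at `style_rate` 0.35 — lay posts are more
casual, and this plants a *systematic*, projection-correctable bias that
is the main source of supervised improvement.  `typo_rate` 0.05 of
consumer mentions appear as single-symbol-substituted variants (extra gold
synonyms); `orphan_rate` 0.1 of consumer slots become orphans whose
dedicated contexts overlap no concept's.  Defaults are sized so a full
generate→embed→fine-tune→evaluate run takes seconds on one CPU.

The generator does **not** model natural-language morphology, polysemy,
thread structure, segmentation errors, or real terminology content.
Passing tests therefore show that the machinery behaves as specified under
the structural assumptions the method makes — not that any particular MRR
level will be attained on a real forum crawl, where context overlap,
frequency profiles and annotation quality differ.

## Numerical choices and degenerate inputs

Cosine of a zero vector raises (`degenerate vector`); out-of-vocabulary
lookups raise naming the token.  Ranking tie-breaks are frequency-then-
lexicographic everywhere (training pool and retrieval), so equal
similarities never make results run-order dependent.  Vector files use the
word2vec text format with 8 significant digits (round-trip differences
< 1e-6 relative); checkpoints store `S` at full precision (17 significant
digits) so save/load is exact.  The uniform-initialization bound, the
per-epoch target refresh, and the sentinel that parks the query itself at
the tail of its own candidate list are all deterministic functions of the
seed, which is what makes two identically-seeded end-to-end runs
byte-identical.

## Open design points resolved here

* The architecture sketch around the projection mentions an additional
  hidden layer and a separate target-side projection without sizes or
  equations; this implementation uses the single shared linear projection
  that the formula `P = S·E·M` actually defines.  A separate consumer-side
  projection would break similarity symmetry and doubles parameters with
  ~60 training pairs; it was not implemented.
* Frequency thresholds ("less than 30", "over 1000") are read as strict
  inequalities.
* The professional-term frequency filter applies per corpus.
* Entropy uses natural log; its softmax has no temperature rescaling by
  default.

## Known limitations

Training cost grows linearly with candidate-pool size per epoch; the
top-N pool is a deliberate approximation of full-vocabulary ranking.  The
surrogate plateaus when many distractors share near-identical similarity
values (the target value then sits inside a tie cluster and matching it
cannot reorder), which is the regime where rank-based supervision carries
no gradient information; heterogeneous corpora avoid it, perfectly
exchangeable distractors do not.  GloVe co-occurrence counting is a pure
Python pass and is the slowest pretraining path at large vocabularies.
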