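# Methods

## Problem and approach

Two papers cited together in the reference list of a third paper
(*co-cited*) are, on average, more similar than two random papers from the
same field. `cociteembed` uses that signal as free supervision for learning
document embeddings: a citing paper with `N` references contributes
`C(N, 2)` positive abstract pairs, so even small corpora yield large
contrastive training sets. The package implements the full pipeline —
dataset construction, mixture-of-experts (MoE) extension of a dense
bidirectional encoder, contrastive training, and a threshold-free
cosine-similarity evaluation — together with a seeded synthetic corpus
generator and a trainable fixture encoder so that every stage can be
exercised end to end on one CPU.

## Dataset construction

`pairs_from_event` enumerates the `C(N, 2)` canonical unordered pairs of an
event's reference list; `aggregate` merges events into distinct pairs whose
*multiplicity* counts the distinct citing papers that co-cite them.
Preferential sampling (`sample_pairs`) draws without replacement with
selection weight proportional to multiplicity (exponential-key weighted
sampling); the literature states the preference but not the weighting
function, and weight-proportional-to-multiplicity is the simplest monotone
choice. Pairs are split 99:1 into train/eval after exact unordered-pair
deduplication, so the partition cannot leak. Evaluation negatives pair
same-domain papers that were never co-cited and are both cited at least 15
times (configurable floor); positives and negatives are balanced, so a
trivial classifier scores F1 = 2/3 at best (predict-all-positive) and 0.5
accuracy.

Negatives default to same-domain because the evaluation is per-domain;
cross-domain negatives are available via `same_domain=False`.

## Encoder fixture

The fixture is a pre-normalisation residual transformer in numpy:

    X <- X + Attention(LN(X));  X <- X + MLP(LN(X))

single-head bidirectional attention with key masking, an
`sigma(h W1) W2` MLP with `I > d` (GeLU default, biases off), and explicit
reverse-mode gradients per layer (verified against central finite
differences to ~1e-6 relative error). Three deliberate fixture choices:

- **No positional encodings.** The synthetic abstracts are bags of topic
  and background tokens; position carries no information, so the encoder is
  permutation-equivariant by construction. A learned positional table would
  only add a shared component to every pooled vector, inflating all pairwise
  cosines without adding signal.
- **Skip-init.** The residual output projections `Wo` and `W2` are
  initialized at 0.1 x their Xavier scale, so at initialization the residual
  stream is dominated by the token embeddings. With fully Xavier-scaled
  branches the random attention/MLP features swamp the lexical signal and a
  short contrastive run reduces the loss mainly by shrinking logit scale
  rather than by restructuring the representation.
- **Width over depth.** The pipeline default is T=2 blocks at d=128,
  I=256. At d=32 the same recipe trains unreliably (seed-dependent); at
  d=128 five hundred steps recover the topic structure consistently.

Checkpoints are a `weights.npz` archive plus a JSON sidecar carrying the
config, vocabulary, special-token registry and (for MoE models) the routing
table.

## MoE extension

`extend(model, domains)` copies each layer's MLP into `E = len(domains)`
bit-identical experts, removes any learned router, and maps domain `k` to
expert `k` (sentence-wise: one expert index per sequence, applied at every
layer). One special token per domain is appended to the embedding matrix,
seeded from the `[CLS]` row, and replaces `[CLS]` at position 0 during
tokenization. Consequently the extended model is output-identical to the
source model before training, and a homogeneous forward pass touches
exactly the source model's parameters: `count_params` reports
`active_per_forward(extended) = total(source)` and
`total(extended) = total(source) + (E-1) * MLP + D * d`.

Unknown domains raise a routing error by default; a fallback expert is
strictly opt-in (`fallback_domain=`). Heterogeneous batches are executed by
grouping sequences per expert and running the expert MLPs sequentially —
correct first, with the same FLOP count as the dense model.

`apply_lora` attaches zero-initialized low-rank adapters
(`W + scale * A @ B`) to chosen attention projections, optionally freezing
the wrapped base weights, for domain-specific attention tuning on top of
the expert MLPs.

## Contrastive training

Documents are embedded by mean-pooling the last hidden state over unmasked
positions. For paired batches `B1, B2` (row i of each side is a co-cited
pair) the loss is a symmetrized cross-entropy over raw inter-batch dot
products,

    L(B1, B2) = L~(B1, B2) + L~(B2, B1)
    L~(A, B)  = sum_i H(softmax_j A_i . B_j, t_i),
    t_i = argmax_j (A_j . A_i + B_j . B_i)    (ties -> lowest index)

with hard targets from the intra-batch dot sums. No temperature and no
normalization are applied inside the loss; cosine similarity appears only
at evaluation. Every other row of the opposite batch acts as an implicit
negative under the assumption that a random in-batch pair is almost never
co-cited.

Training uses Adam (no weight decay), batches of b=16 pairs, a cosine
schedule with 10% linear warmup to 1e-4, seeded random switching of each
pair's side, validation F1max every 100 steps, and early stopping once 5
consecutive validations fail to improve strictly; the best-scoring
checkpoint is returned. Validation every 100 steps (rather than a sparser
cadence) gives five checkpoint-selection opportunities inside the 500-step
fixture budget. Batches are domain-homogeneous: pairs are grouped per
domain, shuffled within the domain, and batch order is shuffled across
domains. This makes every in-batch negative a same-domain document — the
discrimination evaluation actually measures — and keeps each step on a
single expert per layer, the regime in which forced routing has
dense-model throughput. Gradients from the two forward passes of a paired
batch are summed into one update. Parameters that receive no gradient in a
step (unrouted experts) are left byte-identical.

## Evaluation

Each labelled pair is scored by the cosine of its two embeddings. The panel
per evaluation set: **F1max** (maximum F1 over all observed-score
thresholds under the rule `score >= t`; ties resolve to the higher
threshold), the **precision** and **recall** at that optimal threshold, the
**threshold** itself, the positive/negative mean-cosine **ratio**
(undefined — reported as null — when the negative mean is non-positive),
and **ROC-AUC** computed as the normalized Mann-Whitney statistic with ties
counted 1/2. The macro row is the unweighted mean over domains. The TF-IDF
baseline fits scikit-learn's `TfidfVectorizer` per domain with at most
4,096 features (smoothed idf `ln((1+n)/(1+df)) + 1`, L2-normalised rows).

## Synthetic corpus

The generator emulates the statistical shape the method assumes, not real
text. Vocabulary: 20% shared pool plus disjoint per-domain sub-vocabularies.
Each topic inside a domain is a random half-subset of the domain
sub-vocabulary — topics overlap the way related research threads share a
field's lexicon. An abstract draws `topic_token_fraction` (default 0.6) of
its tokens from its topic profile and the rest from the domain-plus-shared
background. Citation events cite `refs_per_event` distinct papers of a
single topic, so co-cited pairs share a topic profile by construction;
`times_cited` is uniform on the configured range, independent of
co-citation structure, so the negative-pair citation floor is exercised
orthogonally. Defaults: 5 domains x 200 papers, vocabulary 500, 8 topics
per domain, 40-token abstracts, 40 citing events per topic with 4
references each, citation counts U{0..40}.

The overlapping-topic design is deliberate: raw lexical cosine then
separates co-cited pairs only moderately (the TF-IDF baseline lands around
0.8 F1max, untrained encoders near the 2/3 floor), while the structure
remains fully learnable, so contrastive training shows a large, measurable
gain. What the generator does **not** model: real citation-count
distributions (heavy-tailed in practice), cross-topic citation events,
MeSH-style vocabulary structure, document length variation, or natural
language word order — so passing tests demonstrate the machinery recovers
planted co-citation structure, not performance on real literature.

## Numerical choices and degenerate inputs

- Equivalence-at-birth tolerance 1e-6 elementwise (observed 0; the expert
  code path reuses the dense arithmetic on grouped rows).
- LayerNorm epsilon 1e-5, non-affine; attention mask fill -1e30 (underflows
  to exactly zero probability after the max-subtracted softmax).
- F1max candidate thresholds are the distinct observed scores — exhaustive
  for the `>=` rule on a finite sample; a coarser grid could only lose.
- All-masked pooling, zero vectors in cosine, single-class metric inputs,
  empty splits, unregistered domains and oversampling requests raise typed
  errors rather than returning sentinel values.
- Every random choice flows from an explicit seed; the pipeline derives
  per-stage child seeds from one global seed via SHA-256 substreams.

## Known limitations

- The fixture encoder is single-head, shallow, and trains from random
  initialization; it demonstrates the pipeline's mechanics, not the
  behaviour of large pretrained encoders (no wrapper for external
  checkpoints ships).
- Reported fixture metrics are stochastic across seeds (roughly +-0.03
  F1max at the default evaluation-set size of ~130 pairs).
- Per-token routing, learned routers, load-balancing losses and expert
  merging are intentionally out of scope.
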