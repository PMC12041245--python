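# cociteembed

Discriminative document embeddings from co-citation supervision, with a
mixture-of-experts (MoE) extension of dense bidirectional encoders.

## The problem

Generic sentence-similarity models blur the distinctions inside niche
scientific literatures: two abstracts from the same subfield look alike to
a general-purpose encoder even when specialists would never confuse them.
`cociteembed` targets that gap using a supervision signal that citation
graphs give away for free: two papers cited together in a third paper
(*co-cited*) are treated as a positive pair. A citing paper with `N`
references yields `N(N-1)/2` such pairs, so small corpora produce large
contrastive training sets.

The package is for researchers and engineers building embedding models or
retrieval systems over domain-structured document collections. It provides:

- **Pair construction** — co-citation enumeration, multiplicity-weighted
  preferential sampling, a 99:1 train/eval split with deduplication, and
  balanced evaluation sets whose negatives pair well-cited (≥ 15 citations)
  never-co-cited papers.
- **MoE extension** — every MLP of a pretrained-style encoder is copied
  into one expert per domain; the learned router is removed and replaced by
  forced sentence-wise routing on the input's domain label, announced to the
  attention layers by a per-domain special token seeded from `[CLS]`. The
  extended model is output-identical to its source until trained, and a
  homogeneous forward pass activates exactly the source model's parameters.
- **Contrastive training** — mean-pooled embeddings, a
  multiple-negatives-ranking loss variant over raw inter-batch dot products
  `L(B1,B2) = Σ_i H(softmax_j B1_i·B2_j, t_i) + (B1 ↔ B2)` with targets
  `t_i = argmax_j (A_j·A_i + B_j·B_i)`, cosine learning-rate schedule with
  warmup, and early stopping on evaluation F1max with patience 5.
- **Evaluation** — cosine-similarity binary classification of co-citation,
  reporting F1max (max F1 over all thresholds), precision/recall at the
  optimal threshold, positive/negative mean-cosine ratio, and ROC-AUC, per
  domain and macro-averaged; plus a per-domain TF-IDF baseline (4,096
  features).
- **Synthetic corpus + fixture encoder** — a seeded generator whose
  co-cited abstracts share topic-token profiles, and a small trainable
  numpy transformer, so the entire pipeline runs end to end on one CPU with
  no downloads.

## Worked example

```python
from cociteembed import (SyntheticConfig, generate_corpus,
                         generate_fixture_encoder, extend, aggregate,
                         split_and_dedup, build_negatives, build_eval_set,
                         TrainConfig, fit, evaluate, count_params)
from cociteembed.synthetic import encoder_config_for, vocab_words

syn = SyntheticConfig(seed=11)                      # 5 domains x 200 papers
records, events = generate_corpus(syn)
recmap = {r.paper_id: r for r in records}

pairs = aggregate(events)                           # 6,663 distinct pairs
split = split_and_dedup(pairs, ratio=0.01, seed=3)  # 6,596 train / 67 eval
negs = build_negatives(records, {p.key for p in pairs}, 15,
                       n=len(split.eval_positives), seed=4)
eval_pairs = build_eval_set(split.eval_positives, negs)

base = generate_fixture_encoder(encoder_config_for(syn), seed=7,
                                vocab=vocab_words(syn.vocab_size))
moe = extend(base, syn.domain_labels)               # 5 experts per layer
print(count_params(moe))                            # total vs active

before = evaluate(moe, eval_pairs, recmap).macro.f1_max
trained, history = fit(moe, split.train, recmap, eval_pairs,
                       TrainConfig(seed=5))
after = evaluate(trained, eval_pairs, recmap).macro.f1_max
print(f"macro F1max {before:.3f} -> {after:.3f}")
```

Prints (seeds as above):

```
ParamCount(total=851328, active_per_forward=326400)
macro F1max 0.731 -> 0.980
```

The parameter count shows the point of forced routing: the five-expert
model stores 851k parameters but each forward pass touches exactly the
326k of the un-extended encoder. The F1max jump shows contrastive training
recovering the planted co-citation structure that the untrained encoder
(near the 2/3 balanced-class floor) cannot see.

The same run from the shell:

```bash
cociteembed run --out runs/demo --seed 11
cociteembed report runs/demo
```

`report` renders the six-column metric panel (F1max, precision, recall,
threshold, ratio, ROC-AUC) per domain and macro, for the trained model,
the untrained model and the TF-IDF baseline. Individual stages are also
exposed as `simulate`, `build-pairs`, `extend`, `train` and `evaluate`.

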