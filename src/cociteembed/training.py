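"""Contrastive training: mean pooling, the MNR-loss variant, batching, fitting.

Two paired mini-batches of abstracts are embedded separately; row ``i`` of
each side is a co-cited pair, and every other row of the opposite side acts
as an implicit negative. The loss is a symmetrized cross-entropy over raw
inter-batch dot-product logits ``Z[i, j] = A_i . B_j`` with hard targets
``t_i = argmax_j (A_j . A_i + B_j . B_i)`` taken from the intra-batch dot
products (ties to the lowest index). No temperature and no normalization are
applied inside the loss; cosine similarity appears only at evaluation.

Training uses a cosine learning-rate schedule with linear warmup (peak
1e-4 by default), batches of 16 pairs with seeded random side switching,
periodic validation on held-out F1max, and early stopping once a patience
of 5 consecutive non-improvements is exceeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import collate
from .errors import ArgumentError, ConfigError, DataError, InputError

__all__ = [
    "TrainConfig", "PairedBatch", "mean_pool", "mean_pool_backward",
    "mnr_loss", "mnr_loss_and_grad", "lr_at", "assemble_batches",
    "epoch_batches", "Adam", "EarlyStopper", "fit",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    ``batch_size`` is pairs per batch (each step embeds ``2 * batch_size``
    abstracts); ``base_lr`` the warmup peak; validation runs every
    ``eval_every`` steps and training halts after ``patience`` consecutive
    validations without strict F1max improvement.
    """

    batch_size: int = 16
    base_lr: float = 1e-4
    warmup_fraction: float = 0.1
    max_steps: int = 500
    eval_every: int = 100
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ConfigError("batch_size must be >= 2 (the loss needs in-batch negatives)")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.max_steps < 1 or self.eval_every < 1:
            raise ConfigError("max_steps and eval_every must be >= 1")
        if not (0.0 <= self.warmup_fraction < 1.0):
            raise ConfigError("warmup_fraction must be in [0, 1)")
        if self.base_lr <= 0:
            raise ConfigError("base_lr must be positive")


@dataclass
class PairedBatch:
    """Texts (and shared domain labels) for the two sides of one step."""

    texts_a: list
    texts_b: list
    domains: list


# ---------------------------------------------------------------------------
# pooling


def mean_pool(hidden: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean of hidden states over unmasked positions only.

    ``hidden``: ``(L, d)`` or ``(B, L, d)``; ``mask`` matches without the
    feature axis. An all-masked sequence is an input error.
    """
    hidden = np.asarray(hidden, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    single = hidden.ndim == 2
    if single:
        hidden, mask = hidden[None], mask[None]
    counts = mask.sum(axis=1)
    if np.any(counts == 0):
        raise InputError("cannot mean-pool a fully masked sequence")
    pooled = (hidden * mask[:, :, None]).sum(axis=1) / counts[:, None]
    return pooled[0] if single else pooled


def mean_pool_backward(d_pooled: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Gradient of :func:`mean_pool` w.r.t. the hidden states."""
    mask = np.asarray(mask, dtype=np.float64)
    counts = mask.sum(axis=1)
    return d_pooled[:, None, :] * (mask / counts[:, None])[:, :, None]


# ---------------------------------------------------------------------------
# the MNR-loss variant


def _ce_half(A: np.ndarray, B: np.ndarray):
    """One directed half: logits A_i.B_j, targets argmax_j(A_j.A_i + B_j.B_i)."""
    logits = A @ B.T
    intra = A @ A.T + B @ B.T
    targets = np.argmax(intra, axis=1)  # ties resolve to the lowest index
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    p = e / e.sum(axis=1, keepdims=True)
    rows = np.arange(len(A))
    loss = float(-np.log(p[rows, targets]).sum())
    dlogits = p.copy()
    dlogits[rows, targets] -= 1.0
    return loss, dlogits @ B, dlogits.T @ A


def mnr_loss_and_grad(B1: np.ndarray, B2: np.ndarray):
    """Loss ``L~(B1,B2) + L~(B2,B1)`` and its gradients w.r.t. both sides."""
    B1 = np.asarray(B1, dtype=np.float64)
    B2 = np.asarray(B2, dtype=np.float64)
    if B1.shape != B2.shape or B1.ndim != 2:
        raise ArgumentError(f"paired batches must share shape (b, d); got "
                            f"{B1.shape} and {B2.shape}")
    if B1.shape[0] < 2:
        raise ArgumentError("batch size must be >= 2 for in-batch negatives")
    l1, dA1, dB1 = _ce_half(B1, B2)
    l2, dA2, dB2 = _ce_half(B2, B1)
    return l1 + l2, dA1 + dB2, dB1 + dA2


def mnr_loss(B1: np.ndarray, B2: np.ndarray) -> float:
    """Scalar value of the symmetrized MNR-variant loss."""
    return mnr_loss_and_grad(B1, B2)[0]


# ---------------------------------------------------------------------------
# schedule, optimizer, batching


def lr_at(step: int, config: TrainConfig) -> float:
    """Linear warmup to ``base_lr``, then cosine decay to zero at ``max_steps``."""
    if step < 0 or step > config.max_steps:
        raise ArgumentError(f"step {step} outside [0, {config.max_steps}]")
    warmup = int(round(config.warmup_fraction * config.max_steps))
    if warmup > 0 and step <= warmup:
        return config.base_lr * step / warmup
    if config.max_steps == warmup:
        return config.base_lr
    frac = (step - warmup) / (config.max_steps - warmup)
    return config.base_lr * 0.5 * (1.0 + np.cos(np.pi * frac))


class Adam(object):
    """Adam with per-parameter state; frozen names are never updated.

    Parameters that receive no gradient in a step (e.g. unrouted experts)
    are left untouched byte-for-byte.
    """

    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, frozen=()):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.frozen = set(frozen)
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, grads: dict, lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, g in grads.items():
            if name in self.frozen:
                continue
            m = self.m.get(name)
            if m is None:
                m = np.zeros_like(g)
                self.m[name] = m
                self.v[name] = np.zeros_like(g)
            v = self.v[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            self.params[name] -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def epoch_batches(pairs, records: dict, config: TrainConfig, rng) -> list:
    """One epoch of :class:`PairedBatch`: per-domain shuffles, coin-flip sides.

    Batches are domain-homogeneous: pairs are grouped by domain, each
    domain's pairs are shuffled, each pair's two abstracts are assigned to
    side 1 or side 2 by a fair seeded coin flip, and consecutive groups of
    ``batch_size`` become batches whose order is then shuffled across
    domains. Homogeneous batches make every in-batch negative a same-domain
    document — the discrimination the evaluation actually asks for — and
    keep each step on a single expert per layer, the configuration in which
    a forced-routing MoE has dense-model throughput. A trailing partial
    batch per domain is dropped (the loss geometry assumes a fixed ``b``).
    """
    by_domain: dict = {}
    for p in pairs:
        dom = p.domain
        if dom is None:
            if p.id_a not in records:
                raise DataError(f"pair references unknown record {p.id_a!r}")
            dom = records[p.id_a].domain
        by_domain.setdefault(dom, []).append(p)
    batches = []
    b = config.batch_size
    for dom in sorted(by_domain):
        dpairs = by_domain[dom]
        order = rng.permutation(len(dpairs))
        flips = rng.random(len(dpairs)) < 0.5
        for start in range(0, len(dpairs) - b + 1, b):
            ta, tb, doms = [], [], []
            for j in range(start, start + b):
                p = dpairs[order[j]]
                for pid in (p.id_a, p.id_b):
                    if pid not in records:
                        raise DataError(f"pair references unknown record {pid!r}")
                a, bb = records[p.id_a], records[p.id_b]
                if flips[j]:
                    a, bb = bb, a
                ta.append(a.abstract)
                tb.append(bb.abstract)
                doms.append(dom)
            batches.append(PairedBatch(ta, tb, doms))
    return [batches[i] for i in rng.permutation(len(batches))]


def assemble_batches(pairs, records: dict, config: TrainConfig, seed: int):
    """Endless stream of paired batches, re-shuffling each epoch. Seeded."""
    pairs = list(pairs)
    rng = np.random.default_rng(seed)
    first = epoch_batches(pairs, records, config, rng)
    if not first:
        raise ArgumentError(
            f"no domain holds {config.batch_size} pairs; cannot fill a batch"
        )
    yield from first
    while True:
        yield from epoch_batches(pairs, records, config, rng)


# ---------------------------------------------------------------------------
# the training loop


class EarlyStopper:
    """Patience rule on validation F1max: strict improvement resets the count;
    once ``patience`` consecutive non-improvements accumulate, stop."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.bad = 0

    def update(self, value: float) -> bool:
        """Record one validation; returns True when training should halt."""
        if value > self.best:
            self.best = value
            self.bad = 0
        else:
            self.bad += 1
        return self.bad >= self.patience


def training_step(model, batch: PairedBatch):
    """Forward both sides, pool, compute the loss, backprop both sides.

    Returns ``(loss, grads)`` with the two sides' parameter gradients summed
    into one update, as in a single combined backward pass.
    """
    is_moe = model.is_moe
    grads_total: dict = {}
    pooled = []
    caches = []
    for texts in (batch.texts_a, batch.texts_b):
        doms = batch.domains if is_moe else [None] * len(texts)
        seqs = [model.tokenize(t, d) for t, d in zip(texts, doms)]
        ids, mask = collate(seqs, model.registry.pad_id)
        experts = model.route(batch.domains) if is_moe else None
        X, cache = model.forward(ids, mask, experts=experts)
        pooled.append(mean_pool(X, mask))
        caches.append((cache, mask))
    loss, d1, d2 = mnr_loss_and_grad(pooled[0], pooled[1])
    for d_pooled, (cache, mask) in zip((d1, d2), caches):
        d_hidden = mean_pool_backward(d_pooled, mask)
        for name, g in model.backward(d_hidden, cache).items():
            if name in grads_total:
                grads_total[name] = grads_total[name] + g
            else:
                grads_total[name] = g
    return loss, grads_total


def _default_eval_fn(model, eval_pairs, records):
    from .metrics import pooled_f1max

    return pooled_f1max(model, eval_pairs, records)


def fit(model, train_pairs, records: dict, eval_pairs, config: TrainConfig,
        *, eval_fn=None):
    """Early-stopped contrastive fitting; returns ``(best_model, history)``.

    ``records`` maps paper id to :class:`~cociteembed.synthetic.PaperRecord`.
    Validation F1max is computed on ``eval_pairs`` every ``eval_every`` steps
    (embeddings recomputed fresh each time); the returned model carries the
    parameters of the best-scoring validation. ``history`` is a list of dicts
    ``{"step", "lr", "loss", "f1max"}`` (``f1max`` None between validations).
    ``eval_fn(model, eval_pairs, records) -> float`` may override the scorer.
    """
    if not eval_pairs:
        raise ConfigError("fit requires a non-empty labelled evaluation set")
    if eval_fn is None:
        eval_fn = _default_eval_fn
    model = model.copy()
    opt = Adam(model.params, frozen=model.frozen)
    stream = assemble_batches(train_pairs, records, config, config.seed)
    stopper = EarlyStopper(config.patience)
    best_params = {k: v.copy() for k, v in model.params.items()}
    history = []
    for step in range(1, config.max_steps + 1):
        batch = next(stream)
        loss, grads = training_step(model, batch)
        lr = lr_at(step, config)
        opt.step(grads, lr)
        entry = {"step": step, "lr": float(lr), "loss": float(loss), "f1max": None}
        if step % config.eval_every == 0 or step == config.max_steps:
            f1 = float(eval_fn(model, eval_pairs, records))
            entry["f1max"] = f1
            if f1 > stopper.best:
                best_params = {k: v.copy() for k, v in model.params.items()}
            halt = stopper.update(f1)
            history.append(entry)
            if halt:
                break
        else:
            history.append(entry)
    model.params = best_params
    return model, history
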