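"""Minimal bidirectional transformer encoder with explicit reverse-mode gradients.

The encoder contract is deliberately small: :func:`tokenize` turns text into a
:class:`TokenSequence`, and :meth:`Encoder.forward` maps a padded batch of
id/mask arrays to last hidden states of shape ``(B, L, d)``. Anything
honouring that contract can be extended into a mixture-of-experts model
(:mod:`cociteembed.moe`) and fine-tuned contrastively
(:mod:`cociteembed.training`).

The reference fixture implemented here is pure numpy. Each of the ``T``
transformer blocks is a pre-normalisation residual pair::

    X <- X + Attention(LN(X))
    X <- X + MLP(LN(X))

with single-head bidirectional attention and an
``sigma(h W1 [+ b1]) W2 [+ b2]`` MLP where the intermediate width ``I``
exceeds the hidden width ``d``. Gradients are hand-written vector-Jacobian
products, so the package trains without an autograd framework. Biases are
off by default, matching current encoder practice.

Two further fixture choices: there are no positional encodings — the
synthetic abstracts are bags of tokens, so position carries no signal and
the attention stack is deliberately permutation-equivariant — and the
residual output projections (``Wo``, ``W2``) are initialized at a reduced
scale (skip-init style), so the residual stream starts close to the raw
token embeddings and short contrastive runs can reshape it quickly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import erf

from .errors import ConfigError, InputError, RoutingError

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)
_LN_EPS = 1e-5
_MASK_FILL = -1e30

CLS_TOKEN = "[CLS]"
PAD_TOKEN = "[PAD]"


# ---------------------------------------------------------------------------
# configuration and tokenization


@dataclass(frozen=True)
class EncoderConfig:
    """Shape hyperparameters of a fixture encoder.

    ``n_blocks`` (T), ``d_model`` (d), ``d_ff`` (I, the MLP intermediate
    width, required > d), ``vocab_size`` (v, including special tokens),
    ``max_len``, the nonlinearity and whether MLP biases are used.
    """

    n_blocks: int
    d_model: int
    d_ff: int
    vocab_size: int
    max_len: int = 128
    activation: str = "gelu"
    use_biases: bool = False

    def __post_init__(self) -> None:
        for name in ("n_blocks", "d_model", "d_ff", "vocab_size", "max_len"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.d_ff <= self.d_model:
            raise ConfigError(
                f"d_ff must exceed d_model (got I={self.d_ff} <= d={self.d_model})"
            )
        if self.activation not in ("relu", "gelu"):
            raise ConfigError(f"activation must be 'relu' or 'gelu', got {self.activation!r}")


@dataclass
class TokenRegistry:
    """Special-token bookkeeping: [CLS], [PAD] and per-domain tokens.

    Domain tokens are appended to the embedding matrix by the MoE extension;
    an un-extended model has an empty ``domain_tokens`` map and always places
    [CLS] at position 0.
    """

    specials: dict = field(default_factory=lambda: {CLS_TOKEN: 0, PAD_TOKEN: 1})
    domain_tokens: dict = field(default_factory=dict)

    @property
    def cls_id(self) -> int:
        return self.specials[CLS_TOKEN]

    @property
    def pad_id(self) -> int:
        return self.specials[PAD_TOKEN]

    @property
    def n_specials(self) -> int:
        return len(self.specials)

    def token_for_domain(self, domain) -> int:
        """Id placed at position 0: the domain token, or [CLS] for the sentinel."""
        if domain is None or domain == "CLS":
            return self.cls_id
        if domain not in self.domain_tokens:
            raise RoutingError(
                f"domain {domain!r} has no registered token "
                f"(registered: {sorted(self.domain_tokens)})"
            )
        return self.domain_tokens[domain]


@dataclass
class TokenSequence:
    """Integer token ids plus a binary mask (1 = real position, 0 = padding)."""

    ids: np.ndarray
    mask: np.ndarray

    def __len__(self) -> int:
        return int(len(self.ids))


class WordTokenizer:
    """Whitespace tokenizer over a fixed word list (fixture use only).

    Word k of the vocabulary maps to id ``n_specials + k`` so special-token
    ids stay stable when domain tokens are later appended at the top end of
    the embedding matrix.
    """

    def __init__(self, vocab, registry: TokenRegistry):
        self.vocab = list(vocab)
        self.registry = registry
        offset = registry.n_specials
        self.word_to_id = {w: offset + k for k, w in enumerate(self.vocab)}

    def encode_words(self, text: str):
        try:
            return [self.word_to_id[w] for w in text.split()]
        except KeyError as exc:
            raise InputError(f"token {exc.args[0]!r} not in fixture vocabulary") from None


def tokenize(text: str, domain, tokenizer: WordTokenizer, max_len: int) -> TokenSequence:
    """Tokenize ``text`` with the domain token (or [CLS]) at position 0.

    Truncates to ``max_len``; the mask marks every kept position as real.
    Unregistered domains raise :class:`RoutingError`.
    """
    head = tokenizer.registry.token_for_domain(domain)
    ids = [head] + tokenizer.encode_words(text)
    ids = ids[:max_len]
    return TokenSequence(
        ids=np.asarray(ids, dtype=np.int64),
        mask=np.ones(len(ids), dtype=np.float64),
    )


def collate(sequences, pad_id: int):
    """Pad a list of :class:`TokenSequence` to a common length.

    Returns ``(ids, mask)`` arrays of shape ``(B, L_max)``.
    """
    if not sequences:
        raise InputError("cannot collate an empty batch")
    L = max(len(s) for s in sequences)
    ids = np.full((len(sequences), L), pad_id, dtype=np.int64)
    mask = np.zeros((len(sequences), L), dtype=np.float64)
    for i, s in enumerate(sequences):
        ids[i, : len(s)] = s.ids
        mask[i, : len(s)] = s.mask
    return ids, mask


# ---------------------------------------------------------------------------
# layer math (forward + vector-Jacobian products)


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    return 0.5 * x * (1.0 + erf(x / _SQRT2))  # exact GeLU


def _act_grad(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (x > 0.0).astype(x.dtype)
    Phi = 0.5 * (1.0 + erf(x / _SQRT2))
    phi = np.exp(-0.5 * x * x) * _INV_SQRT_2PI
    return Phi + x * phi


def _layernorm_fwd(x: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    y = xc * inv
    return y, (y, inv)

def _layernorm_bwd(dy: np.ndarray, cache):
    y, inv = cache
    return inv * (
        dy
        - dy.mean(axis=-1, keepdims=True)
        - y * (dy * y).mean(axis=-1, keepdims=True)
    )


def _softmax_lastaxis(s: np.ndarray) -> np.ndarray:
    m = s.max(axis=-1, keepdims=True)
    e = np.exp(s - m)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# the encoder


class Encoder:
    """Fixture bidirectional transformer encoder (numpy, trainable).

    Parameters live in a flat ``name -> ndarray`` dict:

    - ``W_e`` (v, d) token embedding matrix
    - ``blocks.{i}.attn.{Wq,Wk,Wv,Wo}`` (d, d)
    - ``blocks.{i}.mlp.W1`` (d, I), ``blocks.{i}.mlp.W2`` (I, d)
      (+ ``b1``/``b2`` when biases are enabled)

    ``frozen`` names are skipped by the optimizer; ``lora_scales`` marks
    attention projections that carry low-rank adapters
    (``<name>.lora_A`` / ``<name>.lora_B`` params).
    """

    is_moe = False

    def __init__(self, config: EncoderConfig, params: dict, registry: TokenRegistry, vocab):
        self.config = config
        self.params = params
        self.registry = registry
        self.vocab = list(vocab)
        self.tokenizer = WordTokenizer(self.vocab, registry)
        self.frozen: set = set()
        self.lora_scales: dict = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def random_init(cls, config: EncoderConfig, seed: int, vocab=None,
                    registry: TokenRegistry | None = None) -> "Encoder":
        """Randomly initialized encoder, deterministic given ``seed``.

        Input projections use scale ``1/sqrt(fan_in)`` (Xavier-like); the
        residual output projections ``Wo``/``W2`` are damped by a further
        0.1 (skip-init); embeddings use a 0.05 scale; biases start at zero.
        """
        registry = registry if registry is not None else TokenRegistry()
        if vocab is None:
            vocab = [f"w{k}" for k in range(config.vocab_size - registry.n_specials)]
        if registry.n_specials + len(vocab) + len(registry.domain_tokens) != config.vocab_size:
            raise ConfigError(
                f"vocab_size {config.vocab_size} does not match "
                f"{registry.n_specials} specials + {len(vocab)} words "
                f"+ {len(registry.domain_tokens)} domain tokens"
            )
        rng = np.random.default_rng(seed)
        d, I = config.d_model, config.d_ff
        w_scale = 1.0 / np.sqrt(d)
        out_damp = 0.1  # skip-init: residual branches start small
        params: dict = {
            "W_e": rng.normal(0.0, 0.05, (config.vocab_size, d)),
        }
        for i in range(config.n_blocks):
            for nm in ("Wq", "Wk", "Wv"):
                params[f"blocks.{i}.attn.{nm}"] = rng.normal(0.0, w_scale, (d, d))
            params[f"blocks.{i}.attn.Wo"] = rng.normal(0.0, out_damp * w_scale, (d, d))
            params[f"blocks.{i}.mlp.W1"] = rng.normal(0.0, w_scale, (d, I))
            params[f"blocks.{i}.mlp.W2"] = rng.normal(
                0.0, out_damp / np.sqrt(I), (I, d))
            if config.use_biases:
                params[f"blocks.{i}.mlp.b1"] = np.zeros(I)
                params[f"blocks.{i}.mlp.b2"] = np.zeros(d)
        return cls(config, params, registry, vocab)

    def copy(self) -> "Encoder":
        new = object.__new__(type(self))
        new.__dict__.update(self.__dict__)
        new.params = {k: v.copy() for k, v in self.params.items()}
        new.frozen = set(self.frozen)
        new.lora_scales = dict(self.lora_scales)
        return new

    # -- parameter bookkeeping ----------------------------------------------

    def mlp_param_names(self, block: int, expert=None):
        base = f"blocks.{block}.mlp"
        names = [f"{base}.W1", f"{base}.W2"]
        if self.config.use_biases:
            names += [f"{base}.b1", f"{base}.b2"]
        return names

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- projections with optional LoRA --------------------------------------

    def _proj(self, name: str):
        """Effective projection weight: base plus any low-rank adapter."""
        W = self.params[name]
        a = name + ".lora_A"
        if a in self.params:
            W = W + self.lora_scales[name] * (self.params[a] @ self.params[name + ".lora_B"])
        return W

    def _proj_grad(self, name: str, dW: np.ndarray, grads: dict) -> None:
        a = name + ".lora_A"
        if a in self.params:
            s = self.lora_scales[name]
            A, B = self.params[a], self.params[name + ".lora_B"]
            _accum(grads, a, s * (dW @ B.T))
            _accum(grads, name + ".lora_B", s * (A.T @ dW))
            if name not in self.frozen:
                _accum(grads, name, dW)
        else:
            _accum(grads, name, dW)

    # -- forward -------------------------------------------------------------

    def forward(self, ids: np.ndarray, mask: np.ndarray, experts=None):
        """Last hidden states for a padded batch.

        ``ids``/``mask``: ``(B, L)``. Returns ``(X, cache)`` with ``X`` of
        shape ``(B, L, d)``; the cache feeds :meth:`backward`. ``experts``
        is unused for the dense encoder (see :class:`~cociteembed.moe.MoEEncoder`).
        """
        ids = np.asarray(ids)
        mask = np.asarray(mask, dtype=np.float64)
        if ids.ndim != 2:
            raise InputError(f"ids must be 2-D (batch, length), got shape {ids.shape}")
        if ids.min() < 0 or ids.max() >= self.config.vocab_size:
            raise InputError(
                f"token id out of vocabulary [0, {self.config.vocab_size})"
            )
        B, L = ids.shape
        if L > self.config.max_len:
            raise InputError(f"sequence length {L} exceeds max_len {self.config.max_len}")
        X = self.params["W_e"][ids]
        block_caches = []
        for i in range(self.config.n_blocks):
            h, ln1 = _layernorm_fwd(X)
            a, attn_cache = self._attn_fwd(i, h, mask)
            X = X + a
            h2, ln2 = _layernorm_fwd(X)
            m, mlp_cache = self._mlp_fwd(i, h2, experts)
            X = X + m
            block_caches.append((ln1, attn_cache, ln2, mlp_cache))
        cache = {"ids": ids, "mask": mask, "experts": experts,
                 "blocks": block_caches, "L": L}
        return X, cache

    def backward(self, dX: np.ndarray, cache) -> dict:
        """Parameter gradients for an upstream gradient ``dX`` on the output."""
        grads: dict = {}
        dX = np.asarray(dX, dtype=np.float64)
        for i in reversed(range(self.config.n_blocks)):
            ln1, attn_cache, ln2, mlp_cache = cache["blocks"][i]
            dh2 = self._mlp_bwd(i, dX, mlp_cache, grads)
            dX = dX + _layernorm_bwd(dh2, ln2)
            dh = self._attn_bwd(i, dX, attn_cache, grads)
            dX = dX + _layernorm_bwd(dh, ln1)
        dWe = np.zeros_like(self.params["W_e"])
        np.add.at(dWe, cache["ids"], dX)
        grads["W_e"] = dWe
        return grads

    # attention sublayer

    def _attn_fwd(self, i: int, h: np.ndarray, mask: np.ndarray):
        names = [f"blocks.{i}.attn.{nm}" for nm in ("Wq", "Wk", "Wv", "Wo")]
        Wq, Wk, Wv, Wo = (self._proj(n) for n in names)
        Q, K, V = h @ Wq, h @ Wk, h @ Wv
        scale = 1.0 / np.sqrt(self.config.d_model)
        S = np.einsum("bld,bmd->blm", Q, K) * scale
        S = np.where(mask[:, None, :] > 0, S, _MASK_FILL)
        P = _softmax_lastaxis(S)
        ctx = np.einsum("blm,bmd->bld", P, V)
        out = ctx @ Wo
        return out, (h, Q, K, V, P, ctx, scale, names)

    def _attn_bwd(self, i: int, dout: np.ndarray, cache, grads: dict) -> np.ndarray:
        h, Q, K, V, P, ctx, scale, names = cache
        Wq, Wk, Wv, Wo = (self._proj(n) for n in names)
        dctx = dout @ Wo.T
        self._proj_grad(names[3], np.einsum("bli,blj->ij", ctx, dout), grads)
        dP = np.einsum("bld,bmd->blm", dctx, V)
        dV = np.einsum("blm,bld->bmd", P, dctx)
        dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
        dS = dS * scale
        dQ = np.einsum("blm,bmd->bld", dS, K)
        dK = np.einsum("blm,bld->bmd", dS, Q)
        dh = dQ @ Wq.T + dK @ Wk.T + dV @ Wv.T
        self._proj_grad(names[0], np.einsum("bli,blj->ij", h, dQ), grads)
        self._proj_grad(names[1], np.einsum("bli,blj->ij", h, dK), grads)
        self._proj_grad(names[2], np.einsum("bli,blj->ij", h, dV), grads)
        return dh

    # MLP sublayer (dense; the MoE subclass overrides the two hooks below)

    def _mlp_fwd(self, i: int, h: np.ndarray, experts):
        return self._mlp_apply(self.mlp_param_names(i), h)

    def _mlp_bwd(self, i: int, dout: np.ndarray, cache, grads: dict) -> np.ndarray:
        return self._mlp_apply_bwd(dout, cache, grads)

    def _mlp_apply(self, names, h: np.ndarray):
        W1, W2 = self.params[names[0]], self.params[names[1]]
        z = h @ W1
        if self.config.use_biases:
            z = z + self.params[names[2]]
        a = _act(z, self.config.activation)
        out = a @ W2
        if self.config.use_biases:
            out = out + self.params[names[3]]
        return out, (h, z, a, names)

    def _mlp_apply_bwd(self, dout: np.ndarray, cache, grads: dict) -> np.ndarray:
        h, z, a, names = cache
        W1, W2 = self.params[names[0]], self.params[names[1]]
        flat = lambda x: x.reshape(-1, x.shape[-1])
        _accum(grads, names[1], flat(a).T @ flat(dout))
        da = dout @ W2.T
        dz = da * _act_grad(z, self.config.activation)
        _accum(grads, names[0], flat(h).T @ flat(dz))
        if self.config.use_biases:
            axes = tuple(range(dout.ndim - 1))
            _accum(grads, names[3], dout.sum(axis=axes))
            _accum(grads, names[2], dz.sum(axis=axes))
        return dz @ W1.T

    # -- inference conveniences ----------------------------------------------

    def tokenize(self, text: str, domain=None) -> TokenSequence:
        return tokenize(text, domain, self.tokenizer, self.config.max_len)

    def encode(self, texts, domains=None) -> np.ndarray:
        """Mean-pooled document embeddings, shape ``(n, d)`` (no gradients).

        ``domains`` may be None (dense models: [CLS] at position 0), a single
        label, or one label per text.
        """
        from .training import mean_pool  # local import to avoid a cycle

        if isinstance(domains, str) or domains is None:
            domains = [domains] * len(texts)
        if len(domains) != len(texts):
            raise InputError("domains must match texts in length")
        seqs = [self.tokenize(t, dom) for t, dom in zip(texts, domains)]
        ids, mask = collate(seqs, self.registry.pad_id)
        X, _ = self.forward(ids, mask, experts=self._experts_for(domains))
        return mean_pool(X, mask)

    def _experts_for(self, domains):
        return None


def _accum(grads: dict, name: str, g: np.ndarray) -> None:
    if name in grads:
        grads[name] = grads[name] + g
    else:
        grads[name] = g


# ---------------------------------------------------------------------------
# checkpoint I/O (.npz weights + JSON sidecar)


def save_checkpoint(model: Encoder, path) -> None:
    """Write ``weights.npz`` and ``config.json`` into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **model.params)
    sidecar = {
        "kind": "moe" if model.is_moe else "dense",
        "config": asdict(model.config),
        "specials": model.registry.specials,
        "domain_tokens": model.registry.domain_tokens,
        "vocab": model.vocab,
        "frozen": sorted(model.frozen),
        "lora_scales": model.lora_scales,
    }
    if model.is_moe:
        sidecar["routing_table"] = model.routing_table
        sidecar["n_experts"] = model.n_experts
    (path / "config.json").write_text(json.dumps(sidecar))


def load_checkpoint(path) -> Encoder:
    """Load a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    sidecar = json.loads((path / "config.json").read_text())
    with np.load(path / "weights.npz") as zf:
        params = {k: zf[k].copy() for k in zf.files}
    config = EncoderConfig(**sidecar["config"])
    registry = TokenRegistry(
        specials=dict(sidecar["specials"]),
        domain_tokens=dict(sidecar["domain_tokens"]),
    )
    if sidecar["kind"] == "moe":
        from .moe import MoEEncoder

        model: Encoder = MoEEncoder(
            config, params, registry, sidecar["vocab"],
            routing_table=dict(sidecar["routing_table"]),
            n_experts=int(sidecar["n_experts"]),
        )
    else:
        model = Encoder(config, params, registry, sidecar["vocab"])
    model.frozen = set(sidecar.get("frozen", []))
    model.lora_scales = dict(sidecar.get("lora_scales", {}))
    return model
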