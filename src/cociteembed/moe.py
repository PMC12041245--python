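"""Mixture-of-experts extension of a dense encoder with forced domain routing.

The "upcycling" surgery copies every MLP sublayer of a pretrained dense
encoder into ``E`` bit-identical experts (one per domain), removes any
learned router, and installs a fixed routing table: every sequence is routed
sentence-wise — one expert index per sequence, applied at every layer —
according to its declared domain. A new special token per domain is appended
to the token embedding matrix, seeded from the [CLS] row, and replaces [CLS]
at position 0 during tokenization.

Because routing is forced and sentence-wise, a homogeneous forward pass
touches exactly the parameters of the original dense model: the extension
adds capacity without adding active compute.
"""

from __future__ import annotations

from dataclasses import replace
from typing import NamedTuple

import numpy as np

from .encoder import Encoder, TokenRegistry, CLS_TOKEN
from .errors import ArgumentError, RoutingError, SurgeryError


class MoEEncoder(Encoder):
    """Encoder with per-layer expert banks and a domain -> expert routing table.

    Parameter layout is the dense one except that each layer's MLP lives at
    ``blocks.{i}.experts.{e}.{W1,W2[,b1,b2]}`` for ``e`` in ``[0, E)``.
    """

    is_moe = True

    def __init__(self, config, params, registry, vocab, *, routing_table, n_experts):
        super().__init__(config, params, registry, vocab)
        self.routing_table = dict(routing_table)
        self.n_experts = int(n_experts)

    def mlp_param_names(self, block: int, expert=None):
        if expert is None:
            raise ArgumentError("MoE encoder needs an expert index for MLP parameters")
        base = f"blocks.{block}.experts.{expert}"
        names = [f"{base}.W1", f"{base}.W2"]
        if self.config.use_biases:
            names += [f"{base}.b1", f"{base}.b2"]
        return names

    # -- routing -------------------------------------------------------------

    def route(self, domains) -> np.ndarray:
        return route(domains, self.routing_table)

    def _experts_for(self, domains):
        return self.route(domains)

    # -- expert-grouped MLP sublayer -----------------------------------------

    def _mlp_fwd(self, i: int, h: np.ndarray, experts):
        if experts is None:
            raise RoutingError("MoE forward requires one expert index per sequence")
        experts = np.asarray(experts)
        if experts.shape != (h.shape[0],):
            raise ArgumentError(
                f"expert assignment shape {experts.shape} != batch ({h.shape[0]},)"
            )
        if experts.min() < 0 or experts.max() >= self.n_experts:
            raise RoutingError("expert index out of range")
        out = np.empty_like(h)
        groups = []
        for e in np.unique(experts):
            sel = np.flatnonzero(experts == e)
            sub, sub_cache = self._mlp_apply(self.mlp_param_names(i, int(e)), h[sel])
            out[sel] = sub
            groups.append((sel, sub_cache))
        return out, groups

    def _mlp_bwd(self, i: int, dout: np.ndarray, cache, grads: dict) -> np.ndarray:
        dh = np.empty_like(dout)
        for sel, sub_cache in cache:
            dh[sel] = self._mlp_apply_bwd(dout[sel], sub_cache, grads)
        return dh


def route(domains, table) -> np.ndarray:
    """Expert index per sequence, straight from the routing table.

    Unregistered labels raise :class:`RoutingError`; there is deliberately no
    fallback expert unless one was opted into at extension time via
    ``fallback_domain`` (which registers the unknown label's lookup under a
    designated domain).
    """
    out = np.empty(len(domains), dtype=np.int64)
    for k, dom in enumerate(domains):
        if dom not in table:
            raise RoutingError(
                f"domain {dom!r} is not routable (registered: {sorted(table)})"
            )
        out[k] = table[dom]
    return out


def extend(model: Encoder, domains, *, fallback_domain: str | None = None) -> MoEEncoder:
    """Copy each MLP into one expert per domain and install forced routing.

    The returned model has ``E = len(domains)`` experts per layer, all
    bit-identical to the source MLP; domain token rows appended to ``W_e``,
    each a copy of the [CLS] row; and routing ``domains[k] -> expert k``.
    Attention and every other non-MLP weight is shared, unchanged.

    ``fallback_domain``: opt-in out-of-domain behaviour — inputs labelled
    with an unknown domain are NOT accepted by default; passing one of the
    ``domains`` here routes the sentinel label ``"*"`` to that domain's
    expert and token.
    """
    domains = list(domains)
    if not domains:
        raise SurgeryError("cannot extend with an empty domain list")
    if len(set(domains)) != len(domains):
        raise SurgeryError(f"duplicate domain labels in {domains}")
    if model.is_moe:
        raise SurgeryError("model is already mixture-of-experts extended")
    if CLS_TOKEN not in model.registry.specials:
        raise SurgeryError("source model has no [CLS] row to seed domain tokens from")
    if fallback_domain is not None and fallback_domain not in domains:
        raise SurgeryError(f"fallback domain {fallback_domain!r} not in {domains}")

    v = model.config.vocab_size
    D = len(domains)
    params: dict = {}
    for name, w in model.params.items():
        if ".mlp." in name:
            continue
        params[name] = w.copy()
    cls_row = model.params["W_e"][model.registry.cls_id]
    params["W_e"] = np.vstack([model.params["W_e"], np.tile(cls_row, (D, 1))])

    for i in range(model.config.n_blocks):
        for src in model.mlp_param_names(i):
            suffix = src.rsplit(".", 1)[1]
            for e in range(D):
                params[f"blocks.{i}.experts.{e}.{suffix}"] = model.params[src].copy()

    registry = TokenRegistry(
        specials=dict(model.registry.specials),
        domain_tokens={dom: v + k for k, dom in enumerate(domains)},
    )
    routing = {dom: k for k, dom in enumerate(domains)}
    if fallback_domain is not None:
        routing["*"] = routing[fallback_domain]
        registry.domain_tokens["*"] = registry.domain_tokens[fallback_domain]

    config = replace(model.config, vocab_size=v + D)
    moe = MoEEncoder(config, params, registry, model.vocab,
                     routing_table=routing, n_experts=D)
    moe.frozen = set(model.frozen)
    moe.lora_scales = dict(model.lora_scales)
    return moe


class ParamCount(NamedTuple):
    total: int
    active_per_forward: int


def count_params(model: Encoder) -> ParamCount:
    """Total stored parameters vs parameters touched by one homogeneous forward.

    For a dense encoder the two are equal. For an extended model the active
    count enumerates: all shared (non-expert) parameters, ONE expert bank per
    layer, and the original-vocabulary rows of ``W_e`` — the domain token row
    stands in for the [CLS] row, so the active count equals the source
    model's total exactly.
    """
    total = model.n_params()
    if not model.is_moe:
        return ParamCount(total, total)
    d = model.config.d_model
    D = len({v for k, v in model.registry.domain_tokens.items() if k != "*"})
    active = 0
    for name, w in model.params.items():
        if ".experts." in name:
            continue
        if name == "W_e":
            active += (model.config.vocab_size - D) * d  # original rows; domain row <-> [CLS]
        else:
            active += w.size
    for i in range(model.config.n_blocks):
        active += sum(model.params[n].size for n in model.mlp_param_names(i, 0))
    return ParamCount(int(total), int(active))


def apply_lora(model: Encoder, targets=("Wq", "Wv"), *, rank: int, scale: float = 1.0,
               seed: int = 0, freeze_base: bool = True) -> Encoder:
    """Attach low-rank adapters ``W + scale * A @ B`` to attention projections.

    ``A`` (d x rank) is small-random, ``B`` (rank x d) zero, so the adapted
    forward initially equals the un-adapted one. With ``freeze_base`` the
    wrapped projections are marked frozen so optimization touches only the
    adapters. Modifies ``model`` in place and returns it.
    """
    valid = {"Wq", "Wk", "Wv", "Wo"}
    targets = list(targets)
    unknown = set(targets) - valid
    if unknown:
        raise ArgumentError(f"unknown attention target group(s) {sorted(unknown)}")
    if not targets:
        raise ArgumentError("no target groups given")
    if rank < 1:
        raise ArgumentError(f"rank must be >= 1, got {rank}")
    rng = np.random.default_rng(seed)
    d = model.config.d_model
    for i in range(model.config.n_blocks):
        for t in targets:
            name = f"blocks.{i}.attn.{t}"
            if name + ".lora_A" in model.params:
                raise ArgumentError(f"{name} already carries an adapter")
            model.params[name + ".lora_A"] = rng.normal(0.0, 0.02, (d, rank))
            model.params[name + ".lora_B"] = np.zeros((rank, d))
            model.lora_scales[name] = float(scale)
            if freeze_base:
                model.frozen.add(name)
    return model
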