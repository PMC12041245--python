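"""Pooling, the MNR-loss variant, schedule, batching and the fit loop."""

import numpy as np
import pytest

from cociteembed.errors import ArgumentError, ConfigError, DataError, InputError
from cociteembed.moe import extend
from cociteembed.pairs import CoCitationPair, EvalPair
from cociteembed.synthetic import PaperRecord
from cociteembed.training import (Adam, EarlyStopper, PairedBatch, TrainConfig,
                                  assemble_batches, epoch_batches, fit, lr_at,
                                  mean_pool, mnr_loss, mnr_loss_and_grad,
                                  training_step)


class TestMeanPool:
    def test_plain_mean(self):
        assert np.allclose(mean_pool(np.array([[2., 4.], [6., 8.]]),
                                     np.array([1., 1.])), [4., 6.])

    def test_padding_is_excluded(self):
        hidden = np.array([[2., 4.], [6., 8.], [0., 0.]])
        assert np.allclose(mean_pool(hidden, np.array([1., 1., 0.])), [4., 6.])

    def test_all_masked_is_an_input_error(self):
        with pytest.raises(InputError):
            mean_pool(np.ones((3, 2)), np.zeros(3))


class TestMnrLoss:
    def test_orthonormal_identity_batches_closed_form(self):
        """b=2 identity rows: aligned targets, per-row CE log(1+e^-1),
        total 4*log(1+e^-1)."""
        eye = np.eye(2)
        expected = 4.0 * np.log(1.0 + np.exp(-1.0))
        assert abs(mnr_loss(eye, eye) - expected) <= 1e-9

    @pytest.mark.parametrize("b", [2, 4, 7])
    def test_constant_batches_give_uniform_softmax(self, b):
        u = np.zeros((b, 3))
        u[:, 0] = 1.0
        assert abs(mnr_loss(u, u) - 2 * b * np.log(b)) <= 1e-9

    def test_argument_swap_symmetry(self, rng):
        B1, B2 = rng.normal(size=(2, 5, 4))
        assert mnr_loss(B1, B2) == pytest.approx(mnr_loss(B2, B1), abs=1e-12)

    def test_joint_row_permutation_invariance(self, rng):
        B1, B2 = rng.normal(size=(2, 6, 4))
        perm = rng.permutation(6)
        assert abs(mnr_loss(B1, B2) - mnr_loss(B1[perm], B2[perm])) <= 1e-9

    def test_strengthening_an_aligned_pair_never_increases_loss(self):
        """Diagonal construction: raising B1_i . B2_i (all other dot products
        fixed at zero) must not increase the loss."""
        b = 4
        B1 = np.eye(b)
        scales = np.array([1.0, 0.8, 1.2, 0.9])
        losses = []
        for boost in (0.0, 0.5, 1.0, 2.0):
            B2 = np.diag(scales + np.array([boost, 0, 0, 0]))
            losses.append(mnr_loss(B1, B2))
        assert all(l2 <= l1 + 1e-12 for l1, l2 in zip(losses, losses[1:]))

    def test_small_batch_is_an_argument_error(self):
        with pytest.raises(ArgumentError):
            mnr_loss(np.ones((1, 3)), np.ones((1, 3)))

    def test_gradients_match_finite_differences(self, rng):
        B1, B2 = rng.normal(size=(2, 3, 4))
        loss, d1, d2 = mnr_loss_and_grad(B1, B2)
        eps = 1e-6
        for M, dM in ((B1, d1), (B2, d2)):
            for _ in range(6):
                i, j = rng.integers(0, 3), rng.integers(0, 4)
                orig = M[i, j]
                M[i, j] = orig + eps
                lp = mnr_loss(B1, B2)
                M[i, j] = orig - eps
                lm = mnr_loss(B1, B2)
                M[i, j] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(dM[i, j], abs=1e-5)


class TestLrSchedule:
    CFG = TrainConfig(max_steps=1000, warmup_fraction=0.1)

    def test_ramp_starts_at_zero(self):
        assert lr_at(0, self.CFG) == 0.0

    def test_peak_at_warmup_end(self):
        assert lr_at(100, self.CFG) == pytest.approx(1e-4)

    def test_cosine_floor_at_max_steps(self):
        assert lr_at(1000, self.CFG) <= 1e-7

    def test_ramp_is_linear_and_decay_monotone(self):
        ramp = [lr_at(s, self.CFG) for s in range(0, 101, 10)]
        assert np.allclose(np.diff(ramp), ramp[1] - ramp[0])
        decay = [lr_at(s, self.CFG) for s in range(100, 1001, 50)]
        assert all(b <= a for a, b in zip(decay, decay[1:]))


def _toy_pairs_and_records(n_pairs, domain="d0"):
    # a-side abstracts start with w0, b-side with w1, so side swaps are
    # observable; remaining words stay within the w0..w4 toy vocabulary.
    records, pairs = {}, []
    for i in range(n_pairs):
        a, b = f"{domain}_a{i:05d}", f"{domain}_b{i:05d}"
        records[a] = PaperRecord(a, domain, f"w0 w{2 + i % 3}", 10)
        records[b] = PaperRecord(b, domain, f"w1 w{2 + (i + 1) % 3}", 10)
        pairs.append(CoCitationPair(a, b, domain=domain))
    return pairs, records


class TestAssembleBatches:
    def test_32_pairs_give_two_batches_per_epoch(self):
        pairs, records = _toy_pairs_and_records(32)
        cfg = TrainConfig(batch_size=16)
        batches = epoch_batches(pairs, records, cfg, np.random.default_rng(0))
        assert len(batches) == 2
        assert all(len(b.texts_a) == 16 for b in batches)

    def test_batches_are_domain_homogeneous(self):
        pairs, records = _toy_pairs_and_records(20, "d0")
        p2, r2 = _toy_pairs_and_records(20, "d1")
        pairs, records = pairs + p2, {**records, **r2}
        cfg = TrainConfig(batch_size=8)
        for b in epoch_batches(pairs, records, cfg, np.random.default_rng(1)):
            assert len(set(b.domains)) == 1

    def test_same_seed_gives_identical_streams(self):
        pairs, records = _toy_pairs_and_records(40)
        cfg = TrainConfig(batch_size=8)
        s1 = assemble_batches(pairs, records, cfg, seed=5)
        s2 = assemble_batches(pairs, records, cfg, seed=5)
        for _ in range(12):
            b1, b2 = next(s1), next(s2)
            assert b1.texts_a == b2.texts_a and b1.texts_b == b2.texts_b

    def test_side_swap_frequency_is_half(self):
        pairs, records = _toy_pairs_and_records(10_000)
        cfg = TrainConfig(batch_size=10_000)
        (batch,) = epoch_batches(pairs, records, cfg, np.random.default_rng(3))
        swapped = sum(1 for t in batch.texts_a if t.startswith("w1"))
        assert abs(swapped / 10_000 - 0.5) < 0.02

    def test_missing_record_is_a_data_error(self):
        pairs, records = _toy_pairs_and_records(8)
        records.pop(pairs[0].id_a)
        cfg = TrainConfig(batch_size=8)
        with pytest.raises(DataError):
            epoch_batches(pairs, records, cfg, np.random.default_rng(0))

    def test_underfilled_domains_are_an_argument_error(self):
        pairs, records = _toy_pairs_and_records(4)
        gen = assemble_batches(pairs, records, TrainConfig(batch_size=16), seed=0)
        with pytest.raises(ArgumentError):
            next(gen)


class TestEarlyStopping:
    def test_patience_rule_on_scripted_sequence(self):
        """0.5 then six 0.6s: improvement at the 2nd validation, halt at the
        5th consecutive non-improvement (7th validation), best 0.6."""
        stopper = EarlyStopper(patience=5)
        outcomes = [stopper.update(v) for v in [0.5, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6]]
        assert outcomes == [False, False, False, False, False, False, True]
        assert stopper.best == 0.6

    def test_monotone_improvement_never_halts(self):
        stopper = EarlyStopper(patience=5)
        assert not any(stopper.update(v) for v in np.linspace(0.1, 0.9, 30))

    def test_fit_halts_exactly_per_the_patience_rule(self):
        pairs, records = _toy_pairs_and_records(16)
        eval_pairs = [EvalPair(pairs[0].id_a, pairs[0].id_b, 1),
                      EvalPair(pairs[0].id_a, pairs[1].id_b, 0)]
        scripted = iter([0.5, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.7, 0.7])
        from cociteembed.encoder import Encoder, EncoderConfig
        model = Encoder.random_init(
            EncoderConfig(n_blocks=1, d_model=4, d_ff=8, vocab_size=7, max_len=8),
            seed=0, vocab=[f"w{i}" for i in range(5)])
        cfg = TrainConfig(batch_size=16, max_steps=20, eval_every=1, patience=5)
        _, history = fit(model, pairs, records, eval_pairs, cfg,
                         eval_fn=lambda *_: next(scripted))
        vals = [h["f1max"] for h in history if h["f1max"] is not None]
        assert vals == [0.5, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6]  # halted, 0.7 never seen

    def test_empty_eval_set_is_a_config_error(self):
        pairs, records = _toy_pairs_and_records(16)
        with pytest.raises(ConfigError):
            fit(None, pairs, records, [], TrainConfig())


class TestFitMechanics:
    def test_one_step_on_homogeneous_batch_leaves_other_experts_byte_identical(
            self, tiny_encoder):
        moe = extend(tiny_encoder, ["d0", "d1", "d2"])
        pairs, records = _toy_pairs_and_records(8, "d1")
        texts_a = [records[p.id_a].abstract for p in pairs]
        texts_b = [records[p.id_b].abstract for p in pairs]
        before = {k: v.tobytes() for k, v in moe.params.items()}
        opt = Adam(moe.params)
        _, grads = training_step(moe, PairedBatch(texts_a, texts_b, ["d1"] * 8))
        opt.step(grads, 1e-3)
        routed = moe.routing_table["d1"]
        for name, raw in before.items():
            if ".experts." in name:
                e = int(name.split(".experts.")[1].split(".")[0])
                if e == routed:
                    assert moe.params[name].tobytes() != raw
                else:
                    assert moe.params[name].tobytes() == raw
        assert moe.params["W_e"].tobytes() != before["W_e"]

    def test_fit_returns_the_best_validation_checkpoint(self, tiny_encoder):
        from cociteembed.metrics import pooled_f1max
        moe = extend(tiny_encoder, ["d0"])
        pairs, records = _toy_pairs_and_records(8, "d0")
        eval_pairs = ([EvalPair(p.id_a, p.id_b, 1) for p in pairs[:4]]
                      + [EvalPair(pairs[i].id_a, pairs[i + 1].id_b, 0)
                         for i in range(4)])
        cfg = TrainConfig(batch_size=8, max_steps=12, eval_every=3, patience=5,
                          base_lr=1e-2, seed=0)
        best, history = fit(moe, pairs, records, eval_pairs, cfg)
        recorded = max(h["f1max"] for h in history if h["f1max"] is not None)
        assert pooled_f1max(best, eval_pairs, records) == pytest.approx(recorded)


@pytest.mark.parametrize("bad", [
    dict(batch_size=1), dict(patience=0), dict(max_steps=0),
    dict(warmup_fraction=1.0), dict(base_lr=0.0),
])
def test_invalid_train_config_is_rejected(bad):
    with pytest.raises(ConfigError):
        TrainConfig(**bad)
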