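"""Metric panel oracles: F1max sweep, Mann-Whitney AUC, ratio, TF-IDF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cociteembed.errors import (ArgumentError, DataError, InputError,
                                UndefinedRatioError)
from cociteembed.metrics import (cosine, evaluate, f1_max, metric_panel,
                                 pooled_f1max, roc_auc, score_pairs,
                                 similarity_ratio, tfidf_baseline)
from cociteembed.pairs import EvalPair
from cociteembed.synthetic import PaperRecord


class TestCosine:
    def test_identical_vectors_score_one(self, rng):
        v = rng.normal(size=8)
        assert cosine(v, v) == pytest.approx(1.0)

    def test_opposite_vectors_score_minus_one(self, rng):
        v = rng.normal(size=8)
        assert cosine(v, -v) == pytest.approx(-1.0)

    def test_orthogonal_vectors_score_zero(self):
        assert cosine([1.0, 0.0], [0.0, 2.0]) == pytest.approx(0.0)

    def test_zero_vector_is_an_input_error(self):
        with pytest.raises(InputError):
            cosine([0.0, 0.0], [1.0, 0.0])


def _brute_force_f1max(scores, labels):
    """Independent O(n^2) sweep over distinct thresholds, rule score >= t.

    F1 via the single-division form 2*tp / (pred_pos + n_pos) so that
    mathematically equal values compare equal and the tie rule is exact.
    """
    best = (-1.0, None, None, None)
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * tp / (tp + fp + tp + fn)
        if f1 > best[0]:  # strict: ties keep the earlier (higher) threshold
            best = (f1, t, prec, rec)
    return best


class TestF1Max:
    def test_perfect_separation_gives_one(self):
        f1, *_ = f1_max([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert f1 == 1.0

    def test_interleaved_example_exhaustively_checked(self):
        """scores [.9,.8,.2,.1], labels [1,0,1,0]: best threshold 0.2 with
        precision 2/3, recall 1, F1 = 0.8 (verified by the 4-threshold sweep)."""
        f1, thr, prec, rec = f1_max([0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0])
        assert (f1, thr) == (pytest.approx(0.8), 0.2)
        assert prec == pytest.approx(2 / 3) and rec == 1.0

    def test_one_low_negative_among_positives_still_separates(self):
        f1, *_ = f1_max([0.5, 0.4, 0.3, 0.05], [1, 1, 1, 0])
        assert f1 == 1.0

    def test_single_class_is_an_argument_error(self):
        with pytest.raises(ArgumentError):
            f1_max([0.1, 0.9], [1, 1])

    def test_matches_brute_force_sweep_on_random_instances(self, rng):
        for _ in range(300):
            scores = np.round(rng.normal(size=50), 2)  # rounding forces ties
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                continue
            f1, thr, prec, rec = f1_max(scores, labels)
            bf1, bthr, bprec, brec = _brute_force_f1max(scores, labels)
            assert f1 == pytest.approx(bf1, abs=1e-12)
            assert thr == bthr
            assert (prec, rec) == (pytest.approx(bprec), pytest.approx(brec))

    def test_dominates_any_fixed_threshold(self, rng):
        for _ in range(50):
            scores = rng.normal(size=50)
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                continue
            f1, *_ = f1_max(scores, labels)
            for t in np.linspace(-2, 2, 11):
                pred = scores >= t
                tp = np.sum(pred & (labels == 1))
                denom = pred.sum() + labels.sum()
                fixed = 2 * tp / denom if denom else 0.0
                assert f1 >= fixed - 1e-12


def _brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([0.3] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_interleaved_example(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0]) == 0.75

    def test_matches_pairwise_oracle_and_is_rank_invariant(self, rng):
        for _ in range(100):
            scores = np.round(rng.normal(size=40), 1)
            labels = rng.integers(0, 2, 40)
            if labels.min() == labels.max():
                continue
            auc = roc_auc(scores, labels)
            assert auc == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)
            for transform in (np.exp, np.arctan, lambda x: x ** 3):
                assert roc_auc(transform(scores), labels) == pytest.approx(
                    auc, abs=1e-12)


class TestSimilarityRatio:
    def test_direct_means(self):
        assert similarity_ratio([0.9, 0.7, 0.5, 0.3], [1, 1, 0, 0]) == \
            pytest.approx(2.0)

    def test_identical_score_multisets_give_one(self):
        assert similarity_ratio([0.4, 0.2, 0.4, 0.2], [1, 1, 0, 0]) == \
            pytest.approx(1.0)

    def test_nonpositive_negative_mean_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            similarity_ratio([0.9, 0.5, -0.5], [1, 1, 0])
        assert metric_panel([0.9, 0.5, -0.5], [1, 1, 0]).ratio is None


@given(st.integers(0, 2 ** 32 - 1))
@settings(max_examples=25, deadline=None)
def test_auc_equals_mann_whitney_for_any_seed(seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(size=30), 1)
    labels = rng.integers(0, 2, 30)
    if labels.min() == labels.max():
        return
    assert roc_auc(scores, labels) == pytest.approx(
        _brute_force_auc(scores, labels), abs=1e-12)


def _two_domain_fixture():
    records = {}
    emb = {}
    pairs = []
    rng = np.random.default_rng(0)
    for dom, sep in (("dA", 4.0), ("dB", 0.5)):
        for i in range(12):
            pid = f"{dom}_p{i}"
            records[pid] = PaperRecord(pid, dom, "t0 t1", 20)
            center = np.zeros(4)
            center[0] = sep if i % 2 == 0 else -sep
            emb[pid] = center + rng.normal(0, 1, 4)
        for i in range(0, 12, 4):
            pairs.append(EvalPair(f"{dom}_p{i}", f"{dom}_p{i + 2}", 1))
            pairs.append(EvalPair(f"{dom}_p{i}", f"{dom}_p{i + 1}", 0))
    return records, emb, pairs


class TestEvaluate:
    def test_macro_is_the_unweighted_domain_mean(self):
        records, emb, pairs = _two_domain_fixture()
        report = evaluate(emb, pairs, records)
        assert set(report.per_domain) == {"dA", "dB"}
        expected = np.mean([report.per_domain["dA"].f1_max,
                            report.per_domain["dB"].f1_max])
        assert report.macro.f1_max == pytest.approx(expected)

    def test_domain_order_does_not_change_the_report(self):
        records, emb, pairs = _two_domain_fixture()
        a = evaluate(emb, pairs, records).to_dict()
        b = evaluate(emb, list(reversed(pairs)), records).to_dict()
        assert a == b

    def test_missing_embedding_is_a_data_error(self):
        records, emb, pairs = _two_domain_fixture()
        emb.pop(pairs[0].id_a)
        with pytest.raises(DataError):
            evaluate(emb, pairs, records)

    def test_report_serializes_all_six_columns(self):
        records, emb, pairs = _two_domain_fixture()
        d = evaluate(emb, pairs, records).to_dict()
        for panel in list(d["per_domain"].values()) + [d["macro"]]:
            assert set(panel) == {"f1_max", "precision", "recall", "threshold",
                                  "ratio", "roc_auc"}


class TestTfidfBaseline:
    def test_identical_documents_have_cosine_one(self):
        records = [PaperRecord("a", "d0", "t1 t2 t3", 5),
                   PaperRecord("b", "d0", "t1 t2 t3", 5),
                   PaperRecord("c", "d0", "t9 t8", 5)]
        emb = tfidf_baseline(records)
        assert cosine(emb["a"], emb["b"]) == pytest.approx(1.0)

    def test_token_disjoint_documents_have_cosine_zero(self):
        records = [PaperRecord("a", "d0", "t1 t2", 5),
                   PaperRecord("b", "d0", "t3 t4", 5)]
        emb = tfidf_baseline(records)
        assert cosine(emb["a"], emb["b"]) == pytest.approx(0.0)

    def test_three_document_vectors_match_hand_computation(self):
        """Smoothed idf: idf(t) = ln((1+n)/(1+df)) + 1, rows L2-normalised."""
        records = [PaperRecord("a", "d0", "ta tb", 5),
                   PaperRecord("b", "d0", "ta tc", 5),
                   PaperRecord("c", "d0", "ta td td", 5)]
        emb = tfidf_baseline(records)
        idf_common = np.log(4 / 4) + 1          # df = 3
        idf_rare = np.log(4 / 2) + 1            # df = 1
        vec_a = np.array([1 * idf_common, 1 * idf_rare])   # (ta, tb)
        vec_a = vec_a / np.linalg.norm(vec_a)
        got = emb["a"]
        got = got[np.abs(got) > 1e-12]
        assert np.allclose(np.sort(got), np.sort(vec_a))
        vec_c = np.array([1 * idf_common, 2 * idf_rare])   # (ta, 2 x td)
        vec_c = vec_c / np.linalg.norm(vec_c)
        got_c = emb["c"]
        got_c = got_c[np.abs(got_c) > 1e-12]
        assert np.allclose(np.sort(got_c), np.sort(vec_c))

    def test_domains_are_fit_separately(self):
        records = [PaperRecord("a", "d0", "t1 t2", 5),
                   PaperRecord("b", "d1", "t1 t2 t3 t4", 5)]
        emb = tfidf_baseline(records)
        assert emb["a"].shape != emb["b"].shape  # per-domain vocabularies

    def test_empty_corpus_is_a_data_error(self):
        with pytest.raises(DataError):
            tfidf_baseline([])


def test_score_pairs_and_pooled_f1max_consistency():
    records, emb, pairs = _two_domain_fixture()
    s = score_pairs(emb, pairs)
    assert len(s.scores) == len(pairs)
    assert f1_max(s.scores, s.labels)[0] >= 0.5
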