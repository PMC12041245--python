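"""Cosine-similarity binary evaluation: F1max panel, ROC-AUC, ratio, TF-IDF.

Each abstract pair gets a cosine similarity in [-1, 1]; thresholding the
similarity classifies the pair as co-cited or not. Because a fixed threshold
would favour some models arbitrarily, the headline metric is F1max — the
maximum F1 over all thresholds, taken from the precision-recall sweep —
reported together with the precision and recall attained at that optimal
threshold, the ROC-AUC, and the positive/negative mean-cosine ratio (the
average discriminative power of a model).

The TF-IDF baseline vectorizes each domain's abstracts independently
(vocabulary capped at 4,096 features) using scikit-learn's smoothed idf,
``idf(t) = ln((1 + n) / (1 + df(t))) + 1``, with L2-normalised rows.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.feature_extraction.text import TfidfVectorizer

from .errors import ArgumentError, DataError, InputError, UndefinedRatioError


@dataclass
class ScoredPairSet:
    """Cosine scores with binary labels for one evaluation set."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ArgumentError("scores and labels must be equal-length 1-D arrays")
        if not np.isin(self.labels, (0, 1)).all():
            raise ArgumentError("labels must be binary")

    def require_both_classes(self) -> None:
        if self.labels.min() == self.labels.max():
            raise ArgumentError("threshold metrics need both classes present")


@dataclass
class DomainMetrics:
    """The six-column metric panel for one evaluation set."""

    f1_max: float
    precision: float
    recall: float
    threshold: float
    ratio: float | None
    roc_auc: float


@dataclass
class EvalReport:
    """Per-domain panels plus their unweighted macro average."""

    per_domain: dict
    macro: DomainMetrics

    def to_dict(self) -> dict:
        return {
            "per_domain": {d: asdict(m) for d, m in self.per_domain.items()},
            "macro": asdict(self.macro),
        }


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Standard cosine similarity; zero vectors are an input error."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise InputError("cosine similarity of a zero vector is undefined")
    return float(u @ v / (nu * nv))


def f1_max(scores, labels):
    """Maximum F1 over all observed-score thresholds, rule ``score >= t``.

    Returns ``(f1, threshold, precision, recall)``; ties on F1 resolve to
    the higher threshold. Candidate thresholds are the distinct scores,
    which is exhaustive for the ``>=`` decision rule on a finite sample.
    """
    s = ScoredPairSet(np.asarray(scores), np.asarray(labels))
    s.require_both_classes()
    order = np.argsort(-s.scores, kind="stable")
    sc, lb = s.scores[order], s.labels[order].astype(np.float64)
    tp = np.cumsum(lb)
    fp = np.cumsum(1.0 - lb)
    n_pos = tp[-1]
    # last row of each distinct-score block = metrics for threshold sc[i]
    boundary = np.ones(len(sc), dtype=bool)
    boundary[:-1] = sc[:-1] != sc[1:]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # single division so mathematically equal F1 values (e.g. 2/3 vs 4/6)
    # yield bit-identical floats and the tie rule is exact
    f1 = 2.0 * tp / (tp + fp + n_pos)
    f1 = np.where(boundary, f1, -1.0)  # only threshold-attainable rows compete
    best = int(np.argmax(f1))  # first max = highest threshold (scores sorted desc)
    return (float(f1[best]), float(sc[best]),
            float(precision[best]), float(recall[best]))


def roc_auc(scores, labels) -> float:
    """ROC-AUC as the normalized Mann-Whitney statistic, ties counted 1/2."""
    s = ScoredPairSet(np.asarray(scores), np.asarray(labels))
    s.require_both_classes()
    ranks = rankdata(s.scores)  # average ranks handle ties as 1/2
    pos = s.labels == 1
    n_pos = int(pos.sum())
    n_neg = len(s.labels) - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def similarity_ratio(scores, labels) -> float:
    """Mean positive cosine divided by mean negative cosine.

    A non-positive negative mean makes the ratio meaningless as a
    separability measure; that condition raises
    :class:`UndefinedRatioError` rather than returning a signed number.
    """
    s = ScoredPairSet(np.asarray(scores), np.asarray(labels))
    s.require_both_classes()
    mean_pos = float(s.scores[s.labels == 1].mean())
    mean_neg = float(s.scores[s.labels == 0].mean())
    if mean_neg <= 0.0:
        raise UndefinedRatioError(
            f"negative-class mean cosine is {mean_neg:.6g}; ratio undefined"
        )
    return mean_pos / mean_neg


def metric_panel(scores, labels) -> DomainMetrics:
    """The full six-column panel for one scored set."""
    f1, thr, prec, rec = f1_max(scores, labels)
    try:
        ratio = similarity_ratio(scores, labels)
    except UndefinedRatioError:
        ratio = None
    return DomainMetrics(f1_max=f1, precision=prec, recall=rec, threshold=thr,
                         ratio=ratio, roc_auc=roc_auc(scores, labels))


# ---------------------------------------------------------------------------
# embedding + evaluation drivers


def embed_records(model, paper_ids, records: dict, batch_size: int = 128) -> dict:
    """Embed the given papers with the model; dict ``paper_id -> d-vector``.

    MoE models tokenize with each paper's domain token and route to the
    matching expert; dense models use [CLS].
    """
    ids = list(paper_ids)
    missing = [i for i in ids if i not in records]
    if missing:
        raise DataError(f"no record for paper id(s) {missing[:5]!r}")
    out = {}
    for start in range(0, len(ids), batch_size):
        chunk = ids[start:start + batch_size]
        texts = [records[i].abstract for i in chunk]
        doms = [records[i].domain for i in chunk] if model.is_moe else None
        vecs = model.encode(texts, doms)
        for pid, v in zip(chunk, vecs):
            out[pid] = v
    return out


def score_pairs(embeddings: dict, eval_pairs) -> ScoredPairSet:
    """Cosine score per labelled pair from an id -> vector table."""
    scores, labels = [], []
    for p in eval_pairs:
        for pid in (p.id_a, p.id_b):
            if pid not in embeddings:
                raise DataError(f"no embedding for paper id {pid!r}")
        scores.append(cosine(embeddings[p.id_a], embeddings[p.id_b]))
        labels.append(p.label)
    return ScoredPairSet(np.asarray(scores), np.asarray(labels))


def _unique_ids(eval_pairs):
    seen = []
    seen_set = set()
    for p in eval_pairs:
        for pid in (p.id_a, p.id_b):
            if pid not in seen_set:
                seen_set.add(pid)
                seen.append(pid)
    return seen


def pooled_f1max(model, eval_pairs, records: dict) -> float:
    """Single F1max over the whole evaluation set (the early-stopping signal)."""
    emb = embed_records(model, _unique_ids(eval_pairs), records)
    s = score_pairs(emb, eval_pairs)
    return f1_max(s.scores, s.labels)[0]


def evaluate(model_or_embeddings, eval_pairs, records: dict) -> EvalReport:
    """Per-domain metric panels plus the unweighted macro average.

    ``model_or_embeddings`` is either an encoder (embeddings computed fresh)
    or a precomputed ``paper_id -> vector`` mapping (e.g. the TF-IDF
    baseline). Pairs are grouped by the domain of their records; the macro
    row averages the per-domain panels with equal weight (ratio averaged
    over the domains where it is defined, None if nowhere defined).
    """
    if isinstance(model_or_embeddings, dict):
        embeddings = model_or_embeddings
    else:
        embeddings = embed_records(model_or_embeddings, _unique_ids(eval_pairs), records)
    by_domain: dict = {}
    for p in eval_pairs:
        if p.id_a not in records:
            raise DataError(f"no record for paper id {p.id_a!r}")
        by_domain.setdefault(records[p.id_a].domain, []).append(p)
    per_domain = {}
    for dom in sorted(by_domain):
        s = score_pairs(embeddings, by_domain[dom])
        per_domain[dom] = metric_panel(s.scores, s.labels)
    fields = ("f1_max", "precision", "recall", "threshold", "roc_auc")
    macro_vals = {f: float(np.mean([getattr(m, f) for m in per_domain.values()]))
                  for f in fields}
    ratios = [m.ratio for m in per_domain.values() if m.ratio is not None]
    macro = DomainMetrics(ratio=float(np.mean(ratios)) if ratios else None,
                          **macro_vals)
    return EvalReport(per_domain=per_domain, macro=macro)


# ---------------------------------------------------------------------------
# TF-IDF baseline


def tfidf_baseline(records, max_features: int = 4096) -> dict:
    """Per-domain TF-IDF embeddings; dict ``paper_id -> dense vector``.

    The vectorizer is fit on each domain separately (an abstract is only
    comparable within its domain, matching per-domain evaluation sets), with
    the vocabulary capped at the ``max_features`` most frequent terms.
    """
    by_domain: dict = {}
    for r in records:
        by_domain.setdefault(r.domain, []).append(r)
    if not by_domain:
        raise DataError("empty corpus")
    out: dict = {}
    for dom, recs in by_domain.items():
        texts = [r.abstract for r in recs]
        if not any(t.strip() for t in texts):
            raise DataError(f"domain {dom!r} has no usable abstract text")
        vec = TfidfVectorizer(max_features=max_features, lowercase=False,
                              token_pattern=r"(?u)\S+")
        X = vec.fit_transform(texts).toarray()
        for r, row in zip(recs, X):
            out[r.paper_id] = row
    return out
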