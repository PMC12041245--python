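"""Co-citation pair construction: combinatorics, sampling, splits, negatives.

A citing paper whose reference list holds ``N`` papers contributes
``C(N, 2)`` unordered co-citation pairs. Pairs are stored canonically
(``id_a < id_b``) with a multiplicity — the number of distinct citing papers
that co-cite the two members — which drives preferential sampling. Training
and evaluation positives come from a seeded 99:1 split after deduplication;
evaluation negatives pair well-cited papers (citation-count floor, default
15) that were never co-cited, yielding balanced binary classes.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError, DataError, InfeasibleError


@dataclass(frozen=True)
class CoCitationPair:
    """Canonical unordered pair of paper ids (``id_a < id_b``)."""

    id_a: str
    id_b: str
    multiplicity: int = 1
    domain: str | None = None

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise DataError(f"pair not canonical: {self.id_a!r} >= {self.id_b!r}")
        if self.multiplicity < 1:
            raise DataError(f"multiplicity must be >= 1, got {self.multiplicity}")

    @classmethod
    def canonical(cls, a: str, b: str, multiplicity: int = 1, domain=None):
        if a == b:
            raise DataError(f"self-pair {a!r}")
        lo, hi = (a, b) if a < b else (b, a)
        return cls(lo, hi, multiplicity, domain)

    @property
    def key(self):
        return (self.id_a, self.id_b)


@dataclass(frozen=True)
class EvalPair:
    """Labelled evaluation pair: 1 = co-cited, 0 = negative."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise DataError(f"label must be 0 or 1, got {self.label}")


@dataclass
class SplitResult:
    """Train/eval partition of distinct pairs at the requested eval share."""

    train: list
    eval_positives: list
    ratio: float
    n_duplicates_removed: int = 0


def pairs_from_event(event) -> set:
    """All ``C(N, 2)`` canonical pairs from one citation event.

    Duplicate cited ids are malformed input; fewer than two references
    yield the empty set.
    """
    ids = list(event.cited_ids)
    if len(set(ids)) != len(ids):
        raise DataError(f"event {event.citing_id!r} has duplicate cited ids")
    return {
        CoCitationPair.canonical(a, b, domain=event.domain)
        for a, b in itertools.combinations(ids, 2)
    }


def aggregate(events) -> list:
    """Merge events into distinct pairs with co-citation multiplicities.

    The multiplicity of a pair is the number of distinct citing papers whose
    reference list contains both members. Output is sorted by pair key, so
    aggregation is insensitive to event order.
    """
    events = list(events)
    if not events:
        raise ArgumentError("aggregate needs at least one citation event")
    citing: dict = {}
    domains: dict = {}
    for ev in events:
        for p in pairs_from_event(ev):
            citing.setdefault(p.key, set()).add(ev.citing_id)
            domains.setdefault(p.key, p.domain)
    return [
        CoCitationPair(a, b, multiplicity=len(citing[(a, b)]), domain=domains[(a, b)])
        for a, b in sorted(citing)
    ]


def sample_pairs(pairs, n: int, seed: int) -> list:
    """Preferential sampling without replacement, weight proportional to multiplicity.

    Uses exponential-key (Efraimidis–Spirakis) weighted reservoir order: the
    chance the first draw is pair ``p`` equals ``w_p / sum(w)``. Deterministic
    given ``seed``.
    """
    pairs = list(pairs)
    if n > len(pairs):
        raise ArgumentError(f"cannot sample {n} from {len(pairs)} distinct pairs")
    if n < 0:
        raise ArgumentError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    w = np.array([p.multiplicity for p in pairs], dtype=np.float64)
    keys = rng.random(len(pairs)) ** (1.0 / w)
    order = np.argsort(-keys, kind="stable")
    return [pairs[i] for i in order[:n]]


def split_and_dedup(pairs, ratio: float = 0.01, seed: int = 0) -> SplitResult:
    """Random train/eval partition at eval share ``ratio``, after deduplication.

    Duplicate pairs (same unordered key) are removed keeping the first
    occurrence; the partition is then disjoint by construction, and any eval
    pair that would collide with a train pair is dropped from eval.
    """
    pairs = list(pairs)
    if not pairs:
        raise ArgumentError("cannot split an empty pair list")
    if not (0.0 < ratio < 1.0):
        raise ArgumentError(f"ratio must be in (0, 1), got {ratio}")
    seen: set = set()
    distinct = []
    for p in pairs:
        if p.key not in seen:
            seen.add(p.key)
            distinct.append(p)
    n_dup = len(pairs) - len(distinct)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(distinct))
    n_eval = int(round(len(distinct) * ratio))
    eval_idx = set(order[:n_eval].tolist())
    train = [distinct[i] for i in sorted(set(range(len(distinct))) - eval_idx)]
    train_keys = {p.key for p in train}
    eval_pos = [distinct[i] for i in sorted(eval_idx) if distinct[i].key not in train_keys]
    return SplitResult(train=train, eval_positives=eval_pos, ratio=ratio,
                       n_duplicates_removed=n_dup)


def build_negatives(records, cocited, min_citations: int = 15, *, n: int,
                    seed: int = 0, same_domain: bool = True) -> list:
    """Sample ``n`` never-co-cited pairs of well-cited papers as negatives.

    Both members must have ``times_cited >= min_citations`` and the pair must
    not appear in ``cocited`` (a set of canonical key tuples). By default
    negatives are drawn within a domain, mirroring per-domain evaluation
    sets; ``same_domain=False`` allows cross-domain negatives. Raises
    :class:`InfeasibleError` naming the shortfall when fewer than ``n``
    eligible pairs exist.
    """
    cocited = {tuple(k) for k in cocited}
    eligible = [r for r in records if r.times_cited >= min_citations]
    if same_domain:
        groups: dict = {}
        for r in eligible:
            groups.setdefault(r.domain, []).append(r.paper_id)
    else:
        groups = {"*": [r.paper_id for r in eligible]}
    groups = {d: ids for d, ids in groups.items() if len(ids) >= 2}

    def _n_available(ids) -> int:
        idset = set(ids)
        excluded = sum(1 for a, b in cocited if a in idset and b in idset)
        return len(ids) * (len(ids) - 1) // 2 - excluded

    avail = {d: _n_available(ids) for d, ids in groups.items()}
    total_avail = sum(avail.values())
    if total_avail < n:
        raise InfeasibleError(
            f"need {n} negative pairs but only {total_avail} eligible pairs exist "
            f"(citation floor {min_citations}, {len(eligible)} eligible papers)"
        )

    rng = np.random.default_rng(seed)
    doms = sorted(groups)
    weights = np.array([avail[d] for d in doms], dtype=np.float64)
    weights = weights / weights.sum()
    chosen: set = set()
    out = []
    max_tries = 1000 * n + 1000
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:  # pragma: no cover - guarded by the count check above
            raise InfeasibleError(f"negative sampling stalled after {tries} draws")
        d = doms[int(rng.choice(len(doms), p=weights))]
        ids = groups[d]
        i, j = rng.choice(len(ids), size=2, replace=False)
        a, b = ids[int(i)], ids[int(j)]
        key = (a, b) if a < b else (b, a)
        if key in cocited or key in chosen:
            continue
        chosen.add(key)
        out.append(EvalPair(key[0], key[1], label=0))
    return out


def build_eval_set(positives, negatives) -> list:
    """Balanced labelled evaluation set from split positives and negatives."""
    pos = [EvalPair(p.id_a, p.id_b, label=1) for p in positives]
    return pos + list(negatives)


# ---------------------------------------------------------------------------
# CSV I/O


def write_pairs_csv(pairs, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id_a", "id_b", "multiplicity", "domain"])
        for p in pairs:
            w.writerow([p.id_a, p.id_b, p.multiplicity, p.domain or ""])


def read_pairs_csv(path):
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(CoCitationPair(row["id_a"], row["id_b"],
                                      multiplicity=int(row["multiplicity"]),
                                      domain=row["domain"] or None))
    return out


def write_eval_csv(eval_pairs, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id_a", "id_b", "label"])
        for p in eval_pairs:
            w.writerow([p.id_a, p.id_b, p.label])


def read_eval_csv(path):
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(EvalPair(row["id_a"], row["id_b"], label=int(row["label"])))
    return out
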