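"""Seeded synthetic corpora with co-citation structure, plus fixture encoders.

The generator emulates the statistical shape the method assumes about real
bibliometric data, without mimicking English or any real vocabulary:

- the token vocabulary splits into a pool shared by all domains plus one
  disjoint sub-vocabulary per domain (a field's own lexicon);
- each topic inside a domain is a concentrated frequency profile — a random
  half-subset of the domain sub-vocabulary — so topics of one domain overlap
  lexically the way related research threads do;
- an abstract from a topic draws ``topic_token_fraction`` of its tokens from
  the topic profile and the rest from the domain-plus-shared background;
- each citation event cites ``refs_per_event`` distinct papers from a single
  topic, so co-cited papers share a topic profile by construction and are
  measurably more similar than random same-domain papers;
- ``times_cited`` is sampled independently of the co-citation structure so
  the citation-count floor used for negative pairs is exercised orthogonally.

Abstracts are integer token sequences rendered to text (``"t17 t42 ..."``)
by a deterministic detokenizer, so the same corpus serves the fixture
word tokenizer and the TF-IDF baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .encoder import Encoder, EncoderConfig, TokenRegistry
from .errors import ConfigError


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic corpus.

    Defaults are the fixture-scale conditions the package is exercised
    under: 5 domains of 200 papers over a 500-token vocabulary, 8 topics
    per domain, 40-token abstracts with 60% topic tokens, 40 citing events
    per topic citing 4 papers each, citation counts uniform on {0..40}.
    """

    n_domains: int = 5
    papers_per_domain: int = 200
    topics_per_domain: int = 8
    vocab_size: int = 500
    abstract_length: int = 40
    topic_token_fraction: float = 0.6
    n_citing_events_per_topic: int = 40
    refs_per_event: int = 4
    citation_count_range: tuple = (0, 40)
    seed: int = 0
    shared_vocab_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_domains", "papers_per_domain", "topics_per_domain",
                     "vocab_size", "abstract_length", "n_citing_events_per_topic"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not (0.0 < self.topic_token_fraction <= 1.0):
            raise ConfigError(
                f"topic_token_fraction must be in (0, 1], got {self.topic_token_fraction}"
            )
        if not (0.0 <= self.shared_vocab_fraction < 1.0):
            raise ConfigError("shared_vocab_fraction must be in [0, 1)")
        if self.refs_per_event < 2:
            raise ConfigError(
                f"refs_per_event must be >= 2 to produce pairs, got {self.refs_per_event}"
            )
        lo, hi = self.citation_count_range
        if lo < 0 or hi < lo:
            raise ConfigError(f"bad citation_count_range {self.citation_count_range}")
        if self.papers_per_topic < self.refs_per_event:
            raise ConfigError(
                f"each topic holds ~{self.papers_per_topic} papers, fewer than "
                f"refs_per_event={self.refs_per_event}"
            )
        n_domain_vocab = self.vocab_size - self.n_shared_tokens
        if n_domain_vocab < self.n_domains * self.topics_per_domain:
            raise ConfigError("vocabulary too small for the requested domain/topic split")

    @property
    def n_shared_tokens(self) -> int:
        return int(round(self.vocab_size * self.shared_vocab_fraction))

    @property
    def papers_per_topic(self) -> int:
        return self.papers_per_domain // self.topics_per_domain

    @property
    def domain_labels(self):
        return [f"domain{k}" for k in range(self.n_domains)]


@dataclass(frozen=True)
class PaperRecord:
    """One document: id, domain label, abstract text, times-cited count."""

    paper_id: str
    domain: str
    abstract: str
    times_cited: int


@dataclass
class CitationEvent:
    """A citing paper's reference list: the source of C(N, 2) co-citation pairs."""

    citing_id: str
    cited_ids: list
    domain: str


def detokenize(token_indices) -> str:
    """Deterministic rendering of vocabulary indices to text tokens."""
    return " ".join(f"t{int(i)}" for i in token_indices)


def vocab_words(vocab_size: int):
    """The global fixture word list matching :func:`detokenize`."""
    return [f"t{i}" for i in range(vocab_size)]


def generate_corpus(config: SyntheticConfig):
    """Generate ``(records, events)`` deterministically from ``config.seed``.

    Every cited id refers to a generated record; each event cites
    ``refs_per_event`` distinct papers of a single topic.
    """
    rng = np.random.default_rng(config.seed)
    n_shared = config.n_shared_tokens
    shared = np.arange(n_shared)
    domain_block_size = (config.vocab_size - n_shared) // config.n_domains

    records: list = []
    events: list = []
    topic_fraction = config.topic_token_fraction
    n_topic_tokens = int(round(config.abstract_length * topic_fraction))
    lo, hi = config.citation_count_range

    for k, domain in enumerate(config.domain_labels):
        block = np.arange(n_shared + k * domain_block_size,
                          n_shared + (k + 1) * domain_block_size)
        background = np.concatenate([shared, block])
        topic_profile_size = max(1, domain_block_size // 2)
        topic_members: list = []
        # papers, topic by topic (round-robin remainder goes to early topics)
        counts = [config.papers_per_topic] * config.topics_per_domain
        for r in range(config.papers_per_domain - sum(counts)):
            counts[r % config.topics_per_domain] += 1
        idx = 0
        for t in range(config.topics_per_domain):
            profile = rng.choice(block, size=topic_profile_size, replace=False)
            members = []
            for _ in range(counts[t]):
                pid = f"{domain}_p{idx}"
                idx += 1
                tok = np.empty(config.abstract_length, dtype=np.int64)
                tok[:n_topic_tokens] = rng.choice(profile, size=n_topic_tokens)
                tok[n_topic_tokens:] = rng.choice(
                    background, size=config.abstract_length - n_topic_tokens
                )
                rng.shuffle(tok)
                records.append(PaperRecord(
                    paper_id=pid,
                    domain=domain,
                    abstract=detokenize(tok),
                    times_cited=int(rng.integers(lo, hi + 1)),
                ))
                members.append(pid)
            topic_members.append(members)
        # citation events: each cites refs_per_event distinct papers of one topic
        for t in range(config.topics_per_domain):
            members = topic_members[t]
            for j in range(config.n_citing_events_per_topic):
                cited = rng.choice(len(members), size=config.refs_per_event,
                                   replace=False)
                events.append(CitationEvent(
                    citing_id=f"{domain}_t{t}_c{j}",
                    cited_ids=[members[c] for c in sorted(cited)],
                    domain=domain,
                ))
    return records, events


def generate_fixture_encoder(encoder_config: EncoderConfig, seed: int,
                             vocab=None) -> Encoder:
    """Randomly initialized fixture encoder, deterministic given ``seed``.

    ``vocab`` defaults to the word list implied by the config's vocabulary
    size minus the two special tokens; pass :func:`vocab_words` output to
    align the encoder with a generated corpus.
    """
    registry = TokenRegistry()
    if vocab is None:
        vocab = vocab_words(encoder_config.vocab_size - registry.n_specials)
    return Encoder.random_init(encoder_config, seed, vocab=vocab, registry=registry)


def encoder_config_for(config: SyntheticConfig, *, n_blocks: int = 2,
                       d_model: int = 128, d_ff: int = 256,
                       max_len: int = 64) -> EncoderConfig:
    """Encoder shapes sized to a synthetic corpus (vocab + 2 specials)."""
    return EncoderConfig(
        n_blocks=n_blocks, d_model=d_model, d_ff=d_ff,
        vocab_size=config.vocab_size + 2,
        max_len=max(max_len, config.abstract_length + 1),
    )


# ---------------------------------------------------------------------------
# JSONL I/O


def write_records_jsonl(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(asdict(r)) + "\n")


def read_records_jsonl(path):
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(PaperRecord(**json.loads(line)))
    return records


def write_events_jsonl(events, path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps({"citing_id": e.citing_id,
                                 "cited_ids": list(e.cited_ids),
                                 "domain": e.domain}) + "\n")


def read_events_jsonl(path):
    events = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                events.append(CitationEvent(d["citing_id"], list(d["cited_ids"]),
                                            d["domain"]))
    return events
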