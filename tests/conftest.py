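"""Shared fixtures: a small seeded corpus and tiny encoders.

Everything is generated programmatically at test time; nothing is read from
disk except round-trip tests that write into tmp_path.
"""

import numpy as np
import pytest

from cociteembed.encoder import Encoder, EncoderConfig
from cociteembed.synthetic import SyntheticConfig, generate_corpus


SMALL_SYN = SyntheticConfig(
    n_domains=3, papers_per_domain=48, topics_per_domain=4, vocab_size=150,
    abstract_length=30, n_citing_events_per_topic=12, refs_per_event=3,
    citation_count_range=(0, 40), seed=123,
)


@pytest.fixture(scope="session")
def small_syn():
    return SMALL_SYN


@pytest.fixture(scope="session")
def small_corpus(small_syn):
    records, events = generate_corpus(small_syn)
    return records, events


@pytest.fixture(scope="session")
def small_records_map(small_corpus):
    records, _ = small_corpus
    return {r.paper_id: r for r in records}


@pytest.fixture()
def tiny_config():
    return EncoderConfig(n_blocks=2, d_model=8, d_ff=16, vocab_size=30, max_len=16)


@pytest.fixture()
def tiny_encoder(tiny_config):
    return Encoder.random_init(tiny_config, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
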