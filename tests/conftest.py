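import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from chvmine.corpus_io import Corpus, build_vocabulary
from chvmine.embeddings import train_embeddings
from chvmine.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_gen():
    """A compact generated corpus for unit tests (fast to embed)."""
    cfg = GeneratorConfig(
        n_concepts=10,
        synonyms_per_concept=2,
        vocab_size=260,
        n_messages=1500,
        seed=7,
    )
    corpus, pairs, terms = generate_corpus(cfg)
    return cfg, corpus, pairs, terms


@pytest.fixture(scope="session")
def small_embedding(small_gen):
    _cfg, corpus, _pairs, _terms = small_gen
    vocab = build_vocabulary(corpus)
    emb = train_embeddings(
        corpus, method="word2vec_skipgram", dim=24, epochs=3, seed=7, vocab=vocab
    )
    return emb


@pytest.fixture()
def toy_corpus():
    return Corpus(
        messages=[
            ["a", "b", "a", "c"],
            ["b", "a", "d", "http://x.y/z"],
            ["c", "a", "b", "www.example.com"],
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
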