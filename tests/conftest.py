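import numpy as np
import pytest
from hypothesis import settings

from mfdsc.corpus_io import Corpus, Document
from mfdsc.synthetic import SynthSpec, generate

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def tiny_corpus() -> Corpus:
    docs = (
        Document("d0", ("liver", "pain", "night")),
        Document("d1", ("diet", "after", "surgery")),
        Document("d2", ("liver", "surgery", "risk", "liver")),
    )
    return Corpus(documents=docs)


@pytest.fixture
def labeled_corpus() -> Corpus:
    docs = (
        Document("d0", ("a", "b", "a"), label=0),
        Document("d1", ("a", "c"), label=0),
        Document("d2", ("x", "y"), label=1),
        Document("d3", ("y", "z", "x"), label=1),
    )
    return Corpus(documents=docs, has_labels=True)


@pytest.fixture(scope="session")
def separable_corpus() -> Corpus:
    """3 clusters with pairwise disjoint vocabularies; 60 docs."""
    return generate(SynthSpec(K=3, docs_per_cluster=20, vocab_size_per_cluster=30,
                              shared_vocab_size=0, doc_len_range=(5, 15),
                              overlap=0.0, seed=71))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
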