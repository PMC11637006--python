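"""The frozen cross-document supervision signal: LDA document-topic vectors.

A latent Dirichlet allocation model is fitted once on the corpus bag-of-words
before encoder training and never updated; each document's posterior topic
mixture T (a probability simplex vector) then serves as the target of the
topic KL loss.  The working assumption is a one-to-one correspondence between
document clusters and topics, so the topic count defaults to the cluster
count K downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation

from .corpus_io import ConfigurationError, Corpus, Vocabulary, build_vocabulary

EPS = 1e-12


@dataclass
class TopicModel:
    """A fitted LDA model plus the vocabulary it was fitted over."""

    lda: LatentDirichletAllocation
    vocab: Vocabulary
    r_topics: int


def _bow_matrix(corpus: Corpus, vocab: Vocabulary) -> np.ndarray:
    idx = vocab.index_of
    X = np.zeros((len(corpus), len(vocab)))
    for i, doc in enumerate(corpus):
        for t in doc.tokens:
            j = idx.get(t)
            if j is not None:
                X[i, j] += 1.0
    return X


def fit_topic_model(corpus: Corpus, r_topics: int, seed: int = 0,
                    passes: int = 30, vocab: Vocabulary | None = None) -> TopicModel:
    """Fit LDA with `r_topics` topics on the corpus bag-of-words.

    Symmetric Dirichlet priors of 1/r_topics are used for both the
    document-topic and topic-word distributions; deterministic given `seed`
    (batch variational inference).
    """
    if len(corpus) == 0:
        raise ConfigurationError("cannot fit a topic model on an empty corpus")
    if r_topics < 2:
        raise ConfigurationError("r_topics must be >= 2")
    if vocab is None:
        vocab = build_vocabulary(corpus, min_doc_freq=1)
    if r_topics > len(vocab):
        raise ConfigurationError(
            f"r_topics={r_topics} exceeds vocabulary size {len(vocab)}")
    lda = LatentDirichletAllocation(
        n_components=r_topics,
        doc_topic_prior=1.0 / r_topics,
        topic_word_prior=1.0 / r_topics,
        learning_method="batch",
        max_iter=passes,
        random_state=seed,
    )
    lda.fit(_bow_matrix(corpus, vocab))
    return TopicModel(lda=lda, vocab=vocab, r_topics=r_topics)


def document_topic_distribution(model: TopicModel, corpus: Corpus) -> np.ndarray:
    """Posterior topic mixture per document: an (n_docs, r_topics) simplex matrix.

    Rows are floored at a small epsilon and renormalized so the KL divergence
    against them is always finite; documents with no in-vocabulary word at all
    get the uniform distribution.
    """
    X = _bow_matrix(corpus, model.vocab)
    T = model.lda.transform(X)
    empty = X.sum(axis=1) == 0
    if empty.any():
        T[empty] = 1.0 / model.r_topics
    T = np.maximum(T, EPS)
    T /= T.sum(axis=1, keepdims=True)
    return T
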