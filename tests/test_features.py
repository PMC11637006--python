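"""Embeddings, TF-IDF weights and the weighted fusion FW."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mfdsc.corpus_io import Corpus, Document, build_vocabulary
from mfdsc.features import (EmbeddingFormatError, compute_tfidf, fuse,
                            load_embeddings, save_embeddings, subword_ngrams,
                            train_embeddings)


# -- subword n-grams --------------------------------------------------------

def test_subword_ngrams_definition():
    assert subword_ngrams("ab", 2) == ["<a", "ab", "b>"]
    assert subword_ngrams("x", 2) == ["<x", "x>"]


def test_three_unit_token_yields_four_bigram_pieces():
    # a token of 3 units splits into 4 marked bigrams
    assert len(subword_ngrams("abc", 2)) == 4


@given(st.text(alphabet="abcdef", min_size=1, max_size=10),
       st.integers(1, 4))
def test_ngram_pieces_reassemble_marked_word(word, n):
    pieces = subword_ngrams(word, n)
    marked = "<" + word + ">"
    if n > len(marked):
        assert pieces == []
    else:
        assert len(pieces) == len(marked) - n + 1
        assert all(pieces[i][1:] == pieces[i + 1][:-1]
                   for i in range(len(pieces) - 1))


# -- TF-IDF -----------------------------------------------------------------

def tfidf_bruteforce(corpus, variant="smooth"):
    """Independent recomputation: counts and the formula, nothing shared."""
    N = len(corpus)
    df = Counter()
    for doc in corpus:
        for w in set(doc.tokens):
            df[w] += 1
    out = []
    for doc in corpus:
        tf = Counter(doc.tokens)
        row = []
        for w in doc.tokens:
            if variant == "smooth":
                idf = np.log((1 + N) / (1 + df[w])) + 1
            else:
                idf = np.log(N / df[w])
            row.append(tf[w] * idf)
        out.append(np.array(row))
    return out


def test_ubiquitous_word_weight_is_one():
    docs = tuple(Document(f"d{i}", ("common", f"u{i}")) for i in range(5))
    corpus = Corpus(documents=docs)
    w = compute_tfidf(corpus, build_vocabulary(corpus))
    for i in range(5):
        assert w[i][0] == pytest.approx(1.0)   # 1 * (ln(6/6) + 1)


def test_tfidf_derived_value():
    # N=4 docs, word "w" in one doc with tf 2 -> 2 * (ln(5/2) + 1)
    docs = (Document("d0", ("w", "w", "a")), Document("d1", ("b",)),
            Document("d2", ("c",)), Document("d3", ("d",)))
    corpus = Corpus(documents=docs)
    w = compute_tfidf(corpus, build_vocabulary(corpus))
    assert w[0][0] == pytest.approx(2 * (np.log(5 / 2) + 1))
    assert w[0][1] == w[0][0]                  # same word, same weight per position


def test_unknown_word_weight_zero(tiny_corpus):
    vocab = build_vocabulary(tiny_corpus, min_doc_freq=2)   # only liver, surgery
    w = compute_tfidf(tiny_corpus, vocab)
    assert w[0][1] == 0.0                      # "pain" filtered from vocab


@pytest.mark.parametrize("variant", ["smooth", "raw"])
@pytest.mark.parametrize("seed", range(5))
def test_tfidf_matches_bruteforce(variant, seed):
    r = np.random.default_rng(seed)
    words = [f"w{i}" for i in range(12)]
    docs = tuple(Document(f"d{i}", tuple(r.choice(words, size=r.integers(1, 9))))
                 for i in range(10))
    corpus = Corpus(documents=docs)
    got = compute_tfidf(corpus, build_vocabulary(corpus), variant)
    expect = tfidf_bruteforce(corpus, variant)
    for g, e in zip(got.rows, expect):
        np.testing.assert_allclose(g, e, atol=1e-12)


# -- fusion -----------------------------------------------------------------

def test_fuse_forced_arithmetic():
    from mfdsc.features import EmbeddingTable
    table = EmbeddingTable(dim=2, vectors={"a": np.array([2.0, 3.0])})
    doc = Document("d0", ("a",))
    fw = fuse(doc, table, np.array([0.5]))
    np.testing.assert_allclose(fw, [[1.0, 1.5]])


def test_fuse_identity_zero_and_shape(tiny_corpus):
    from mfdsc.features import EmbeddingTable
    r = np.random.default_rng(0)
    vocab = build_vocabulary(tiny_corpus)
    table = EmbeddingTable(dim=4, vectors={w: r.normal(size=4) for w in vocab.words})
    doc = tiny_corpus[2]
    unweighted = fuse(doc, table, np.ones(len(doc)))
    np.testing.assert_allclose(unweighted,
                               np.stack([table.vector_of(t) for t in doc.tokens]))
    zeroed = fuse(doc, table, np.zeros(len(doc)))
    assert not zeroed.any()
    assert unweighted.shape == (len(doc), 4)


@given(st.floats(-10, 10, allow_nan=False), st.integers(0, 10))
def test_fuse_linearity(c, seed):
    from mfdsc.features import EmbeddingTable
    r = np.random.default_rng(seed)
    k = int(r.integers(1, 6))
    words = [f"w{i}" for i in range(k)]
    table = EmbeddingTable(dim=3, vectors={w: r.normal(size=3) for w in words})
    doc = Document("d0", tuple(words))
    w0 = r.normal(size=k)
    np.testing.assert_allclose(fuse(doc, table, c * w0), c * fuse(doc, table, w0),
                               atol=1e-9)


# -- embedding training and I/O --------------------------------------------

def test_train_embeddings_deterministic_and_shaped(separable_corpus):
    t1 = train_embeddings(separable_corpus, dim=16, epochs=1, seed=1703)
    t2 = train_embeddings(separable_corpus, dim=16, epochs=1, seed=1703)
    assert t1.words == t2.words
    for w in t1.words:
        np.testing.assert_array_equal(t1.vector_of(w), t2.vector_of(w))
        assert t1.vector_of(w).shape == (16,)


def test_cooccurring_words_are_similar():
    r = np.random.default_rng(9)
    # themed filler groups give every word a distinctive context distribution
    themes = [[f"t{g}w{i}" for i in range(5)] for g in range(4)]
    docs = []
    for i in range(200):
        toks = list(r.choice(themes[i % 4], size=6))
        if i % 2 == 0:
            pos = int(r.integers(0, 5))
            toks[pos:pos] = ["qq", "zz"]      # always adjacent pair
        docs.append(Document(f"d{i}", tuple(toks)))
    table = train_embeddings(Corpus(documents=tuple(docs)), dim=16, epochs=8,
                             seed=3, window=2)

    def cos(a, b):
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

    sims = [cos(table.vector_of(a), table.vector_of(b))
            for a, b in itertools.combinations(table.words, 2)]
    assert cos(table.vector_of("qq"), table.vector_of("zz")) > np.median(sims)


def test_subword_mode_embeds_unseen_words(separable_corpus):
    table = train_embeddings(separable_corpus, dim=8, epochs=1, seed=0,
                             subword_n=3)
    oov = table.vector_of("c0w0XX")           # shares pieces with cluster-0 words
    assert oov.shape == (8,)
    assert oov.any()
    # a word sharing no known pieces gets the zero vector
    assert not table.vector_of("QQQQ").any()
    # in-table words equal the sum of their piece vectors
    w = table.words[0]
    expect = sum(table.ngram_vectors[g] for g in subword_ngrams(w, 3))
    np.testing.assert_allclose(table.vectors[w], expect, atol=1e-12)


def test_embedding_roundtrip(tmp_path, separable_corpus):
    table = train_embeddings(separable_corpus, dim=5, epochs=1, seed=4)
    save_embeddings(table, tmp_path / "vec.txt")
    loaded = load_embeddings(tmp_path / "vec.txt")
    assert loaded.dim == 5
    assert set(loaded.words) == set(table.words)
    for w in table.words:
        np.testing.assert_array_equal(loaded.vector_of(w), table.vector_of(w))


def test_load_embeddings_parses_and_validates(tmp_path):
    good = tmp_path / "g.txt"
    good.write_text("2 3\na 1 0 0\nb 0 1 0\n")
    table = load_embeddings(good)
    assert table.dim == 3 and len(table.words) == 2
    bad = tmp_path / "b.txt"
    bad.write_text("1 3\na 1 0\n")
    with pytest.raises(EmbeddingFormatError, match="line 2"):
        load_embeddings(bad)
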