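"""Lexical feature construction: word embeddings, TF-IDF weights, fusion.

A document of k tokens becomes a k x T_emb matrix of word vectors; each row
is then scaled by that word's TF-IDF weight in the document, yielding the
weighted feature matrix FW that the encoder consumes.  Down-weighting
uninformative words this way is what lets very short texts keep a usable
topical signal.

Embeddings come from a compact skip-gram-with-negative-sampling trainer with
optional character-n-gram (subword) composition, so words unseen at training
time still receive a vector from their character pieces.  The trainer is
seeded and single-threaded: the same corpus and seed always give the same
table.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_io import Corpus, Document, Vocabulary

logger = logging.getLogger(__name__)

BOW_MARK = "<"
EOW_MARK = ">"


class EmbeddingFormatError(ValueError):
    """Malformed plain-text vector file."""


def subword_ngrams(word: str, n: int) -> list[str]:
    """All contiguous length-n pieces of the boundary-marked word.

    The word is wrapped as ``<word>`` before slicing, so pieces at the start
    and end are distinguishable from word-internal ones: ``("ab", 2)`` gives
    ``["<a", "ab", "b>"]``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not word:
        raise ValueError("word must be non-empty")
    marked = BOW_MARK + word + EOW_MARK
    return [marked[i:i + n] for i in range(len(marked) - n + 1)]


@dataclass
class EmbeddingTable:
    """word -> T_emb vector, with optional subword composition for OOV words.

    With `subword_n` set, every word's vector — in-table or not — is the sum
    of its known n-gram vectors (the zero vector when none are known), so the
    table extends naturally beyond its training vocabulary.
    """

    dim: int
    vectors: dict[str, np.ndarray]
    subword_n: int | None = None
    ngram_vectors: dict[str, np.ndarray] | None = None

    def vector_of(self, word: str) -> np.ndarray:
        if word in self.vectors:
            return self.vectors[word]
        if self.subword_n is not None and self.ngram_vectors is not None:
            v = np.zeros(self.dim)
            for g in subword_ngrams(word, self.subword_n):
                if g in self.ngram_vectors:
                    v = v + self.ngram_vectors[g]
            return v
        return np.zeros(self.dim)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    @property
    def words(self) -> list[str]:
        return list(self.vectors)


def train_embeddings(corpus: Corpus, dim: int = 100, subword_n: int | None = None,
                     window: int = 5, epochs: int = 5, seed: int = 0,
                     negative: int = 5, lr: float = 0.05,
                     min_count: int = 1) -> EmbeddingTable:
    """Train skip-gram-with-negative-sampling vectors on the corpus.

    With `subword_n` set, each word is represented as the sum of its marked
    character-n-gram vectors (the n-grams are the trained parameters); without
    it, plain per-word input vectors are trained.  Context vectors are
    per-word in both modes.  Negative contexts are drawn from the unigram
    distribution raised to 3/4.  Degenerate corpora (shorter than the window,
    single-word) train on whatever pairs exist rather than failing.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(seed)

    counts: Counter[str] = Counter()
    for doc in corpus:
        counts.update(doc.tokens)
    words = sorted((w for w, c in counts.items() if c >= min_count),
                   key=lambda w: (-counts[w], w))
    if not words:
        raise ValueError("no words above min_count")
    w2i = {w: i for i, w in enumerate(words)}
    V = len(words)

    # input representations: per-word, or shared n-gram pieces
    if subword_n is None:
        grams_of = [[i] for i in range(V)]
        n_in = V
    else:
        gram_index: dict[str, int] = {}
        grams_of = []
        for w in words:
            ids = []
            for g in subword_ngrams(w, subword_n):
                ids.append(gram_index.setdefault(g, len(gram_index)))
            grams_of.append(ids)
        n_in = len(gram_index)

    scale = 0.5 / dim
    W_in = rng.uniform(-scale, scale, size=(n_in, dim))
    W_out = np.zeros((V, dim))

    freq = np.array([counts[w] for w in words], dtype=np.float64)
    noise = freq ** 0.75
    noise /= noise.sum()

    docs_idx = [[w2i[t] for t in doc.tokens if t in w2i] for doc in corpus]
    total_pos = sum(max(len(d) - 1, 0) for d in docs_idx) * epochs or 1
    seen = 0
    lr_min = 1e-4
    for _ in range(epochs):
        for d in docs_idx:
            for t, wi in enumerate(d):
                cur_lr = max(lr * (1.0 - seen / total_pos), lr_min)
                seen += 1
                win = int(rng.integers(1, window + 1))
                lo, hi = max(0, t - win), min(len(d), t + win + 1)
                gids = grams_of[wi]
                v = W_in[gids].sum(axis=0)
                dv = np.zeros(dim)
                touched = False
                for c in range(lo, hi):
                    if c == t:
                        continue
                    targets = [d[c]] + list(rng.choice(V, size=negative, p=noise))
                    labels = [1.0] + [0.0] * negative
                    for tgt, lab in zip(targets, labels):
                        u = W_out[tgt]
                        g = 1.0 / (1.0 + np.exp(-v @ u)) - lab
                        dv += g * u
                        W_out[tgt] = u - cur_lr * g * v
                        touched = True
                if touched:
                    W_in[gids] -= cur_lr * dv
    vectors = {w: W_in[grams_of[i]].sum(axis=0) for i, w in enumerate(words)}
    ngram_vectors = None
    if subword_n is not None:
        ngram_vectors = {g: W_in[i].copy() for g, i in gram_index.items()}
    return EmbeddingTable(dim=dim, vectors=vectors, subword_n=subword_n,
                          ngram_vectors=ngram_vectors)


def save_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write the table in the plain-text word2vec format (lossless floats)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for w, v in table.vectors.items():
            fh.write(w + " " + " ".join(np.format_float_scientific(x, unique=True)
                                        for x in v) + "\n")


def load_embeddings(path: str | Path) -> EmbeddingTable:
    """Read a plain-text word2vec file: header "count dim", then one word per line."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError(f"{path}: line 1: header must be 'count dim'")
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError as e:
            raise EmbeddingFormatError(f"{path}: line 1: non-integer header") from e
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise EmbeddingFormatError(
                    f"{path}: line {lineno}: expected {dim + 1} fields, got {len(parts)}")
            word = parts[0]
            if word in vectors:
                logger.warning("duplicate word %r at line %d: last occurrence wins",
                               word, lineno)
            vectors[word] = np.array([float(x) for x in parts[1:]])
    if len(vectors) != count:
        logger.warning("%s: header declared %d words, found %d", path, count, len(vectors))
    return EmbeddingTable(dim=dim, vectors=vectors)


@dataclass(frozen=True)
class DocTermWeights:
    """Per-document, per-position TF-IDF weights aligned to the corpus order.

    Every occurrence of a word in one document carries that word's single
    tf-idf value; words outside the vocabulary weigh 0.
    """

    rows: tuple[np.ndarray, ...]
    variant: str = "smooth"

    def __getitem__(self, i: int) -> np.ndarray:
        return self.rows[i]

    def __len__(self) -> int:
        return len(self.rows)


def _idf(vocab: Vocabulary, variant: str) -> dict[str, float]:
    N = vocab.total_docs
    if variant == "smooth":
        return {w: np.log((1.0 + N) / (1.0 + df)) + 1.0
                for w, df in vocab.doc_freq.items()}
    if variant == "raw":
        return {w: np.log(N / df) for w, df in vocab.doc_freq.items()}
    raise ValueError(f"unknown tf-idf variant {variant!r}")


def compute_tfidf(corpus: Corpus, vocab: Vocabulary,
                  variant: str = "smooth") -> DocTermWeights:
    """tf(w, d) x idf(w) at every token position.

    tf is the raw count of the word in the document; idf defaults to the
    smoothed form ln((1+N)/(1+df)) + 1, which keeps corpus-wide words at a
    small positive weight instead of zeroing their feature rows entirely
    (the "raw" variant ln(N/df) is available for comparison).  No
    per-document normalization is applied.
    """
    idf = _idf(vocab, variant)
    rows = []
    for doc in corpus:
        tf = Counter(doc.tokens)
        rows.append(np.array([tf[t] * idf.get(t, 0.0) for t in doc.tokens]))
    return DocTermWeights(rows=tuple(rows), variant=variant)


def fuse(doc: Document, table: EmbeddingTable, weights: np.ndarray) -> np.ndarray:
    """FW: row i = tfidf_i * embedding(w_i); shape (k, T_emb)."""
    k = len(doc)
    if weights.shape != (k,):
        raise ValueError(f"weights shape {weights.shape} != ({k},)")
    fw = np.empty((k, table.dim))
    for i, t in enumerate(doc.tokens):
        fw[i] = weights[i] * table.vector_of(t)
    return fw


def fuse_corpus(corpus: Corpus, table: EmbeddingTable,
                weights: DocTermWeights) -> list[np.ndarray]:
    """FW matrices for every document, in corpus order."""
    return [fuse(doc, table, weights[i]) for i, doc in enumerate(corpus)]
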