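"""Reading, validating and holding tokenized short-text corpora.

The on-disk exchange format is deliberately minimal: one document per line,
tokens separated by single spaces (UTF-8), with an optional parallel label
file holding one base-10 integer per line.  Inputs are assumed to be
pre-tokenized; no segmentation is performed here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)


class CorpusError(ValueError):
    """Malformed corpus input (empty file, bad label, misaligned files)."""


class ConfigurationError(ValueError):
    """A configuration that cannot produce a valid run."""


@dataclass(frozen=True)
class Document:
    """One short text: an id, its token sequence and an optional class label."""

    doc_id: str
    tokens: tuple[str, ...]
    label: int | None = None

    def __post_init__(self):
        if len(self.tokens) == 0:
            raise CorpusError(f"document {self.doc_id!r} has no tokens")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of documents, optionally all labeled."""

    documents: tuple[Document, ...]
    has_labels: bool = False

    def __post_init__(self):
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise CorpusError("duplicate doc_ids in corpus")
        if self.has_labels and any(d.label is None for d in self.documents):
            raise CorpusError("has_labels=True but some documents carry no label")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]

    def labels(self) -> list[int]:
        if not self.has_labels:
            raise CorpusError("corpus carries no labels")
        return [d.label for d in self.documents]  # type: ignore[misc]


@dataclass(frozen=True)
class Vocabulary:
    """Retained words with document frequencies over a corpus of N documents."""

    words: tuple[str, ...]
    doc_freq: dict[str, int] = field(hash=False)
    total_docs: int = 0

    def __post_init__(self):
        for w in self.words:
            df = self.doc_freq[w]
            if not 1 <= df <= self.total_docs:
                raise CorpusError(f"doc_freq({w!r})={df} outside [1, {self.total_docs}]")

    @property
    def index_of(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.words)}

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.doc_freq


def load_corpus(tokens_path: str | Path,
                labels_path: str | Path | None = None,
                min_tokens: int = 1,
                lowercase: bool = False) -> Corpus:
    """Load a corpus from a token file and an optional aligned label file.

    Documents with fewer than `min_tokens` tokens (including blank lines) are
    dropped; the drop count is logged.  When a label file is given its line
    count must match the token file exactly — labels stay aligned to the
    surviving documents.
    """
    tokens_path = Path(tokens_path)
    lines = tokens_path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise CorpusError(f"empty corpus file: {tokens_path}")

    labels: list[int] | None = None
    if labels_path is not None:
        label_lines = Path(labels_path).read_text(encoding="utf-8").splitlines()
        if len(label_lines) != len(lines):
            raise CorpusError(
                f"label file has {len(label_lines)} lines but token file has "
                f"{len(lines)}: files are misaligned")
        try:
            labels = [int(s.strip()) for s in label_lines]
        except ValueError as e:
            raise CorpusError(f"non-integer label in {labels_path}: {e}") from e
        if any(lab < 0 for lab in labels):
            raise CorpusError("labels must be non-negative integers")

    docs: list[Document] = []
    dropped = 0
    for i, line in enumerate(lines):
        toks = line.split()
        if lowercase:
            toks = [t.lower() for t in toks]
        if len(toks) < max(min_tokens, 1):
            dropped += 1
            continue
        docs.append(Document(doc_id=f"d{i:06d}", tokens=tuple(toks),
                             label=None if labels is None else labels[i]))
    if dropped:
        logger.info("dropped %d documents with fewer than %d tokens", dropped, min_tokens)
    if not docs:
        raise CorpusError("corpus is empty after filtering")
    return Corpus(documents=tuple(docs), has_labels=labels is not None)


def save_corpus(corpus: Corpus, tokens_path: str | Path,
                labels_path: str | Path | None = None) -> None:
    """Write the one-document-per-line token file (and label file if asked)."""
    Path(tokens_path).write_text(
        "\n".join(" ".join(d.tokens) for d in corpus) + "\n", encoding="utf-8")
    if labels_path is not None:
        if not corpus.has_labels:
            raise CorpusError("cannot write labels: corpus carries none")
        Path(labels_path).write_text(
            "\n".join(str(d.label) for d in corpus) + "\n", encoding="utf-8")


def build_vocabulary(corpus: Corpus, min_doc_freq: int = 1) -> Vocabulary:
    """Count document frequencies and retain words seen in >= min_doc_freq docs.

    Word order is (descending document frequency, then lexicographic), which
    makes the vocabulary — and everything indexed by it — deterministic.
    """
    if len(corpus) == 0:
        raise CorpusError("cannot build a vocabulary from an empty corpus")
    if min_doc_freq < 1:
        raise ConfigurationError("min_doc_freq must be >= 1")
    df: Counter[str] = Counter()
    for doc in corpus:
        df.update(set(doc.tokens))
    kept = {w: c for w, c in df.items() if c >= min_doc_freq}
    if not kept:
        raise ConfigurationError(
            f"vocabulary empty after min_doc_freq={min_doc_freq} filtering")
    words = tuple(sorted(kept, key=lambda w: (-kept[w], w)))
    return Vocabulary(words=words, doc_freq=kept, total_docs=len(corpus))
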