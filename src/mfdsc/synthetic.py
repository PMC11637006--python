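"""Synthetic labeled short-text corpora with controllable topic structure.

Each of K clusters owns a private vocabulary with a Zipf-shaped word
distribution (natural-language-like frequency skew); a shared vocabulary pool
is mixed in with probability `overlap`, which is the single dial controlling
cluster separability: overlap 0 with an empty shared pool gives pairwise
disjoint cluster vocabularies, overlap 1 makes every cluster draw from the
same pool and the labels carry no lexical signal at all.

Token strings are synthetic (cluster-tagged integers rendered as words); the
generator emulates the short, sparse regime of medical Q&A questions — 5 to
30 tokens per document — without shipping any real vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .corpus_io import ConfigurationError, Corpus, Document


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic corpus draw."""

    K: int = 3
    docs_per_cluster: int = 100
    vocab_size_per_cluster: int = 50
    shared_vocab_size: int = 50
    doc_len_range: tuple[int, int] = (5, 30)
    overlap: float = 0.0
    zipf_exponent: float = 1.1
    seed: int = 0

    def validate(self) -> None:
        if self.K < 1 or self.docs_per_cluster < 1 or self.vocab_size_per_cluster < 1:
            raise ConfigurationError("K, docs_per_cluster, vocab_size_per_cluster must be >= 1")
        if not 0.0 <= self.overlap <= 1.0:
            raise ConfigurationError("overlap must lie in [0, 1]")
        if self.overlap > 0.0 and self.shared_vocab_size < 1:
            raise ConfigurationError("overlap > 0 requires a non-empty shared pool")
        lo, hi = self.doc_len_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("doc_len_range must satisfy 1 <= min <= max")


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    p = 1.0 / np.arange(1, size + 1, dtype=np.float64) ** exponent
    return p / p.sum()


def generate(spec: SynthSpec) -> Corpus:
    """Draw a labeled corpus of K * docs_per_cluster short documents."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cluster_words = [np.array([f"c{c}w{i}" for i in range(spec.vocab_size_per_cluster)])
                     for c in range(spec.K)]
    shared_words = np.array([f"sw{i}" for i in range(spec.shared_vocab_size)]) \
        if spec.shared_vocab_size else np.array([], dtype=object)
    p_cluster = _zipf_probs(spec.vocab_size_per_cluster, spec.zipf_exponent)
    p_shared = (_zipf_probs(spec.shared_vocab_size, spec.zipf_exponent)
                if spec.shared_vocab_size else None)

    lo, hi = spec.doc_len_range
    docs: list[Document] = []
    for c in range(spec.K):
        for j in range(spec.docs_per_cluster):
            k = int(rng.integers(lo, hi + 1))
            from_shared = rng.random(k) < spec.overlap
            n_shared = int(from_shared.sum())
            toks = np.empty(k, dtype=object)
            if n_shared:
                toks[from_shared] = rng.choice(shared_words, size=n_shared, p=p_shared)
            if k - n_shared:
                toks[~from_shared] = rng.choice(cluster_words[c], size=k - n_shared,
                                                p=p_cluster)
            docs.append(Document(doc_id=f"s{c:02d}_{j:05d}",
                                 tokens=tuple(toks.tolist()), label=c))
    return Corpus(documents=tuple(docs), has_labels=True)


def difficulty_sweep(base: SynthSpec, overlaps: list[float]) -> list[tuple[float, Corpus]]:
    """One corpus per overlap value; corpus i uses seed base.seed + i."""
    if sorted(overlaps) != list(overlaps):
        raise ConfigurationError("overlaps must be sorted ascending")
    out = []
    for i, ov in enumerate(overlaps):
        spec = replace(base, overlap=ov, seed=base.seed + i,
                       shared_vocab_size=max(base.shared_vocab_size, 1 if ov > 0 else 0))
        out.append((ov, generate(spec)))
    return out
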