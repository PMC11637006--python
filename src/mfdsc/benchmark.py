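"""The reduced-scale synthetic benchmark used for validation.

A 3-cluster corpus of 100 documents per cluster (5-30 tokens each) is
generated at a chosen vocabulary overlap; the full pipeline — skip-gram
embeddings, TF-IDF weighting, LDA target, double-target training — and the
TF-IDF + K-means baseline are run on it, and all four clustering indicators
are computed against the generating labels.

The network dimensions are scaled down from the reference setting
(16-dim embeddings, 32-dim BiGRU state, 16-dim representation, 8 epochs,
batch 16) so a full run takes seconds on one CPU while preserving every
structural element of the method.  Seeds fan out from one base seed with
the same offsets the CLI uses.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .corpus_io import build_vocabulary
from .features import compute_tfidf, train_embeddings
from .metrics import evaluate
from .synthetic import SynthSpec, generate
from .topic_target import document_topic_distribution, fit_topic_model
from .training import (AblationFlags, TrainingConfig, baseline_tfidf_kmeans,
                       predict_clusters, train)

__all__ = ["small_spec", "small_config", "run_benchmark"]


def small_spec(overlap: float, seed: int) -> SynthSpec:
    """The benchmark corpus: K=3, 100 docs/cluster, 50-word cluster pools."""
    return SynthSpec(K=3, docs_per_cluster=100, vocab_size_per_cluster=50,
                     shared_vocab_size=50 if overlap > 0 else 0,
                     doc_len_range=(5, 30), overlap=overlap, seed=seed)


def small_config(seed: int, ablation: AblationFlags | None = None) -> TrainingConfig:
    """Scaled-down training configuration for ~300-document corpora."""
    return TrainingConfig(K=3, batch_size=16, epochs=8, hidden_units=16,
                          attn_dim=16, attn_hops=1, proj_dim=16, r_rep=16,
                          head_dim=16, seed=seed,
                          ablation=ablation or AblationFlags())


def run_benchmark(overlap: float, seed: int,
                  ablation: AblationFlags | None = None,
                  emb_epochs: int = 10, emb_dim: int = 16) -> dict:
    """One full pipeline + baseline run; returns the indicator values.

    Returns a dict with 'mfdsc' and 'baseline' MetricsReport dicts, plus
    the trace of the training run.
    """
    corpus = generate(small_spec(overlap, seed))
    gold = corpus.labels()
    vocab = build_vocabulary(corpus)
    weights = compute_tfidf(corpus, vocab)
    table = train_embeddings(corpus, dim=emb_dim, epochs=emb_epochs,
                             seed=seed + 1)
    tm = fit_topic_model(corpus, r_topics=3, seed=seed + 2, vocab=vocab)
    T = document_topic_distribution(tm, corpus)
    config = small_config(seed + 3, ablation)
    model = train(corpus, table, weights, T, config, vocab=vocab)
    pred = predict_clusters(model, corpus, seed=seed + 4)
    base = baseline_tfidf_kmeans(corpus, vocab, K=3, seed=seed + 4)
    return {
        "overlap": overlap,
        "seed": seed,
        "n": len(corpus),
        "mfdsc": evaluate(gold, pred).as_dict(),
        "baseline": evaluate(gold, base).as_dict(),
        "trace": model.trace,
        "pred": [int(x) for x in pred],
        "baseline_pred": [int(x) for x in base],
    }


def median_nmi(results: list[dict], which: str = "mfdsc") -> float:
    return float(np.median([r[which]["nmi"] for r in results]))
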