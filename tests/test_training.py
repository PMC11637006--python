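"""Losses, schedules, batch K-means and the training loop's contracts."""

import numpy as np
import pytest

from mfdsc.corpus_io import ConfigurationError, build_vocabulary
from mfdsc.features import compute_tfidf, train_embeddings
from mfdsc.metrics import nmi
from mfdsc.topic_target import document_topic_distribution, fit_topic_model
from mfdsc.training import (AblationFlags, BatchClustering, TrainingConfig,
                            alpha_schedule, baseline_tfidf_kmeans,
                            batch_kmeans, cluster_loss, joint_loss,
                            predict_clusters, topic_loss, train)


# -- alpha schedule ---------------------------------------------------------

def test_alpha_schedule_ramp_and_clamp():
    assert alpha_schedule(0, 10, 0.3) == 0.0
    assert alpha_schedule(10, 10, 0.3) == pytest.approx(0.3)
    assert alpha_schedule(20, 10, 0.3) == pytest.approx(0.3)   # clamped
    assert alpha_schedule(5, 10, 0.3) == pytest.approx(0.15)
    with pytest.raises(ValueError):
        alpha_schedule(1, 0, 0.3)


# -- batch K-means ----------------------------------------------------------

def test_batch_kmeans_separated_points():
    pts = np.array([[0.0, 0.0]] * 5 + [[10.0, 10.0]] * 5)
    bc = batch_kmeans(pts, K=2, seed=0)
    assert sorted(bc.centroids.tolist()) == [[0.0, 0.0], [10.0, 10.0]]
    assert len(set(bc.assignment[:5])) == 1
    assert bc.assignment[0] != bc.assignment[5]


def test_batch_kmeans_k_equals_m():
    pts = np.random.default_rng(0).normal(size=(4, 3))
    bc = batch_kmeans(pts, K=4, seed=1)
    assert cluster_loss(pts, bc) == pytest.approx(0.0, abs=1e-12)


def test_batch_kmeans_matches_lloyd_oracle_with_shared_init():
    r = np.random.default_rng(5)
    pts = r.normal(size=(20, 2))
    init = pts[[0, 7]].copy()
    bc = batch_kmeans(pts, K=2, seed=0, init=init)

    # independent Lloyd loop from the same initial centroids
    c = init.copy()
    for _ in range(100):
        d2 = ((pts[:, None] - c[None]) ** 2).sum(axis=2)
        a = d2.argmin(axis=1)
        new = np.array([pts[a == k].mean(axis=0) for k in range(2)])
        if np.allclose(new, c):
            break
        c = new
    wcss_oracle = ((pts - c[a]) ** 2).sum()
    assert cluster_loss(pts, bc) == pytest.approx(wcss_oracle, abs=1e-9)


def test_batch_kmeans_rejects_small_batch():
    with pytest.raises(ValueError):
        batch_kmeans(np.zeros((2, 3)), K=3, seed=0)


# -- losses -----------------------------------------------------------------

def test_cluster_loss_examples():
    feats = np.array([[0.0], [2.0]])
    bc = BatchClustering(centroids=np.array([[1.0]]), assignment=np.array([0, 0]))
    assert cluster_loss(feats, bc) == pytest.approx(2.0)
    at_centroid = BatchClustering(centroids=np.array([[0.0], [2.0]]),
                                  assignment=np.array([0, 1]))
    assert cluster_loss(feats, at_centroid) == pytest.approx(0.0)


def test_cluster_loss_matches_bruteforce():
    r = np.random.default_rng(2)
    feats = r.normal(size=(10, 4))
    bc = batch_kmeans(feats, K=3, seed=3)
    expect = sum(((feats[i] - bc.centroids[bc.assignment[i]]) ** 2).sum()
                 for i in range(10))
    assert cluster_loss(feats, bc) == pytest.approx(expect, abs=1e-9)
    literal = sum(((feats[i] - bc.centroids[k]) ** 2).sum()
                  for i in range(10) for k in range(3))
    assert cluster_loss(feats, bc, literal_sum=True) == pytest.approx(literal, abs=1e-9)


def test_topic_loss_identities():
    T = np.array([[0.2, 0.8], [0.5, 0.5]])
    assert topic_loss(T, T) == pytest.approx(0.0, abs=1e-12)
    assert topic_loss(np.array([[1.0, 0.0]]),
                      np.array([[0.5, 0.5]])) == pytest.approx(np.log(2))
    with pytest.raises(ValueError):
        topic_loss(T, T[:, :1])


def test_topic_loss_nonnegative_on_random_simplex_pairs():
    r = np.random.default_rng(4)
    for _ in range(1000):
        t = r.dirichlet(np.ones(4), size=3)
        d = r.dirichlet(np.ones(4), size=3)
        assert topic_loss(t, d) >= -1e-12


def test_joint_loss_arithmetic():
    assert joint_loss(2.0, 0.5, 0.3) == pytest.approx(1.1)
    assert joint_loss(123.0, 0.5, 0.0) == 0.5
    # linear in the cluster term
    assert joint_loss(4.0, 1.0, 0.25) - joint_loss(2.0, 1.0, 0.25) \
        == pytest.approx(0.25 * 2.0)


# -- training loop ----------------------------------------------------------

@pytest.fixture(scope="module")
def small_run(separable_corpus):
    corpus = separable_corpus
    vocab = build_vocabulary(corpus)
    weights = compute_tfidf(corpus, vocab)
    table = train_embeddings(corpus, dim=8, epochs=2, seed=1)
    T = document_topic_distribution(fit_topic_model(corpus, 3, seed=2, vocab=vocab),
                                    corpus)
    return corpus, vocab, weights, table, T


def small_cfg(**kw):
    base = dict(K=3, batch_size=16, epochs=2, hidden_units=4, attn_dim=4,
                proj_dim=4, r_rep=4, head_dim=4, seed=5)
    base.update(kw)
    return TrainingConfig(**base)


def test_train_is_deterministic(small_run):
    corpus, vocab, weights, table, T = small_run
    m1 = train(corpus, table, weights, T, small_cfg(), vocab=vocab)
    m2 = train(corpus, table, weights, T, small_cfg(), vocab=vocab)
    assert m1.trace == m2.trace
    p1 = predict_clusters(m1, corpus, seed=9)
    p2 = predict_clusters(m2, corpus, seed=9)
    np.testing.assert_array_equal(p1, p2)
    assert len(p1) == len(corpus)


def test_loss_composition_and_alpha_trace(small_run):
    corpus, vocab, weights, table, T = small_run
    cfg = small_cfg(epochs=4, t_ramp=2, alpha_max=0.3)
    model = train(corpus, table, weights, T, cfg, vocab=vocab)
    alphas = [r["alpha"] for r in model.trace]
    assert all(a2 >= a1 for a1, a2 in zip(alphas, alphas[1:]))
    assert max(alphas) <= 0.3
    epochs_seen = {r["epoch"]: r["alpha"] for r in model.trace}
    assert epochs_seen[0] == 0.0
    assert epochs_seen[2] == pytest.approx(0.3)     # t = t_ramp
    assert epochs_seen[3] == pytest.approx(0.3)     # clamped beyond the ramp
    for r in model.trace:
        assert r["l_train"] == pytest.approx(
            r["alpha"] * r["l_cluster"] + r["l_topic"], abs=1e-9)


def test_cluster_loss_disabled_reduces_to_topic_loss(small_run):
    corpus, vocab, weights, table, T = small_run
    cfg = small_cfg(ablation=AblationFlags(use_cluster_loss=False))
    model = train(corpus, table, weights, T, cfg, vocab=vocab)
    for r in model.trace:
        assert r["l_train"] == pytest.approx(r["l_topic"], abs=1e-12)
        assert r["l_cluster"] == 0.0


def test_both_losses_disabled_rejected(small_run):
    corpus, vocab, weights, table, T = small_run
    cfg = small_cfg(ablation=AblationFlags(use_topic_loss=False,
                                           use_cluster_loss=False))
    with pytest.raises(ConfigurationError, match="nothing to optimize"):
        train(corpus, table, weights, T, cfg, vocab=vocab)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        TrainingConfig(K=1).validate()
    with pytest.raises(ConfigurationError):
        TrainingConfig(alpha_max=1.5).validate()
    with pytest.raises(ConfigurationError):
        TrainingConfig(K=12, batch_size=8).validate()


# -- baseline and prediction ------------------------------------------------

def test_baseline_separates_disjoint_vocabularies(separable_corpus):
    vocab = build_vocabulary(separable_corpus)
    pred = baseline_tfidf_kmeans(separable_corpus, vocab, K=3, seed=0)
    assert nmi(separable_corpus.labels(), pred) >= 0.95
    np.testing.assert_array_equal(
        pred, baseline_tfidf_kmeans(separable_corpus, vocab, K=3, seed=0))


def test_predict_rejects_tiny_corpus(small_run):
    corpus, vocab, weights, table, T = small_run
    model = train(corpus, table, weights, T, small_cfg(), vocab=vocab)
    from mfdsc.corpus_io import Corpus
    tiny = Corpus(documents=corpus.documents[:2])
    with pytest.raises(ValueError):
        predict_clusters(model, tiny)
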