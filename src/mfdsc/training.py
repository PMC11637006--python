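"""Double-target self-supervised training and cluster prediction.

Each batch of encoded text representations is pulled simultaneously toward
two targets: the frozen LDA document-topic distribution (a KL-divergence
topic loss on the encoder's topic posterior) and the batch's own K-means
centroids (a squared-distance clustering loss on the representations).  The
joint objective is L_train = alpha * L_cluster + L_topic, with alpha ramped
linearly from 0 to alpha_max over training (the "climbing" schedule) so the
clustering pull only kicks in once the representations are informative.
Centroids are recomputed fresh every batch and detached from the gradient.

Final corpus-level labels come from a seeded multi-restart K-means over all
encoded documents.  The module also provides the classical TF-IDF
bag-of-words + K-means baseline for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.cluster import KMeans

from .autodiff import Tensor
from .corpus_io import ConfigurationError, Corpus, Vocabulary
from .encoder import (EncoderConfig, EncoderParams, encode_batch, init_params,
                      params_as_tensors)
from .features import DocTermWeights, EmbeddingTable, compute_tfidf, fuse_corpus

logger = logging.getLogger(__name__)

D_FLOOR = 1e-12


@dataclass
class AblationFlags:
    """Switches that remove one ingredient at a time (feature or target)."""

    use_tfidf: bool = True           # False: all token weights become 1
    use_embeddings: bool = True      # False: seeded random vectors replace trained ones
    use_topic_loss: bool = True
    use_cluster_loss: bool = True


@dataclass
class TrainingConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference setting: 12 clusters, batch 256, 32 epochs,
    AdamW at 1e-3 with linear decay, alpha ramped to 0.3 over the full run,
    512-dim BiGRU state and a 64-dim text representation.
    """

    K: int = 12
    r_topics: int | None = None      # None -> K (cluster-topic correspondence)
    batch_size: int = 256
    epochs: int = 32
    learning_rate: float = 1e-3
    lr_linear_decay: bool = True
    alpha_max: float = 0.3
    t_ramp: int | None = None        # None -> epochs (ramp spans the whole run)
    seed: int = 0
    optimizer: str = "adamw"         # or "sgd"
    weight_decay: float = 0.01
    reduction: str = "sum"           # both losses use the same reduction
    literal_cluster_sum: bool = False  # sum distance to ALL centroids, not assigned
    hidden_units: int = 256
    attn_dim: int = 64
    attn_hops: int = 1
    proj_dim: int = 64
    r_rep: int = 64
    head_dim: int = 64
    ablation: AblationFlags = field(default_factory=AblationFlags)

    def validate(self) -> None:
        if not 0.0 <= self.alpha_max <= 1.0:
            raise ConfigurationError("alpha_max must lie in [0, 1]")
        if self.K < 2:
            raise ConfigurationError("K must be >= 2")
        if self.batch_size < self.K:
            raise ConfigurationError("batch_size must be >= K to support K centroids")
        if not (self.ablation.use_topic_loss or self.ablation.use_cluster_loss):
            raise ConfigurationError(
                "both losses disabled: nothing to optimize")
        if self.optimizer not in ("adamw", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.reduction not in ("sum", "mean"):
            raise ConfigurationError(f"unknown reduction {self.reduction!r}")

    @property
    def effective_r_topics(self) -> int:
        return self.K if self.r_topics is None else self.r_topics

    @property
    def effective_t_ramp(self) -> int:
        return self.epochs if self.t_ramp is None else self.t_ramp


@dataclass
class BatchClustering:
    """K centroids and the nearest-centroid assignment of a feature batch."""

    centroids: np.ndarray            # (K, r_rep)
    assignment: np.ndarray           # (m,) centroid index per sample


@dataclass
class TrainedModel:
    """Everything needed to encode and cluster new documents."""

    params: EncoderParams
    config: TrainingConfig
    table: EmbeddingTable
    vocab: Vocabulary
    topic_target: np.ndarray         # frozen document-topic matrix of the training corpus
    centroids: np.ndarray | None     # final global centroids
    trace: list[dict]                # per-step loss/alpha/lr records


# ---------------------------------------------------------------------------
# the individual loss pieces (plain-numpy surface)
# ---------------------------------------------------------------------------

def alpha_schedule(t: int, t_ramp: int, alpha_max: float) -> float:
    """Linear climb: alpha = (t / t_ramp) * alpha_max, clamped at alpha_max."""
    if t_ramp < 1:
        raise ValueError("t_ramp must be >= 1")
    if t < 0:
        raise ValueError("epoch index must be >= 0")
    return min(t / t_ramp, 1.0) * alpha_max


def batch_kmeans(features: np.ndarray, K: int, seed: int,
                 init: np.ndarray | str = "k-means++") -> BatchClustering:
    """Seeded Lloyd's K-means on one batch; assignment is nearest-centroid."""
    m = features.shape[0]
    if m < K:
        raise ValueError(f"batch of {m} samples cannot support {K} centroids")
    km = KMeans(n_clusters=K, init=init, n_init=1, max_iter=100,
                random_state=seed)
    km.fit(features)
    centroids = km.cluster_centers_
    d2 = ((features[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return BatchClustering(centroids=centroids, assignment=d2.argmin(axis=1))


def cluster_loss(features: np.ndarray, bc: BatchClustering,
                 literal_sum: bool = False, reduction: str = "sum") -> float:
    """Squared distance of each sample to its assigned centroid (summed).

    `literal_sum` switches to summing the distance to every centroid for
    every sample — the non-standard all-centroids reading, kept for
    comparison.
    """
    if bc.assignment.shape[0] != features.shape[0]:
        raise ValueError("assignment does not cover the batch")
    if literal_sum:
        d2 = ((features[:, None, :] - bc.centroids[None, :, :]) ** 2).sum()
    else:
        d2 = ((features - bc.centroids[bc.assignment]) ** 2).sum()
    return float(d2 / features.shape[0]) if reduction == "mean" else float(d2)


def topic_loss(T_batch: np.ndarray, D_batch: np.ndarray,
               reduction: str = "sum") -> float:
    """KL(T || D) summed over the batch, with 0*log(0/d) = 0 and d floored."""
    T_batch = np.asarray(T_batch, dtype=float)
    D_batch = np.asarray(D_batch, dtype=float)
    if T_batch.shape != D_batch.shape:
        raise ValueError(f"shape mismatch {T_batch.shape} vs {D_batch.shape}")
    D_safe = np.maximum(D_batch, D_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(T_batch > 0.0,
                         T_batch * (np.log(np.maximum(T_batch, D_FLOOR))
                                    - np.log(D_safe)),
                         0.0)
    total = float(terms.sum())
    return total / T_batch.shape[0] if reduction == "mean" else total


def joint_loss(lc: float, lt: float, alpha: float) -> float:
    """L_train = alpha * L_cluster + L_topic."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return alpha * lc + lt


# ---------------------------------------------------------------------------
# autodiff loss assembly
# ---------------------------------------------------------------------------

def _topic_loss_tensor(T_batch: np.ndarray, D: Tensor, reduction: str) -> Tensor:
    """KL(T || D) as a graph node; clipped entries stop gradient, matching
    the numpy surface exactly."""
    keep = (D.data > D_FLOOR).astype(float)
    D_safe = D * Tensor(keep) + Tensor((1.0 - keep) * D_FLOOR)
    T_const = Tensor(T_batch)
    const_part = float(np.sum(T_batch * np.log(np.maximum(T_batch, D_FLOOR))))
    loss = Tensor(const_part) + (-(T_const * D_safe.log()).sum())
    if reduction == "mean":
        loss = loss * (1.0 / T_batch.shape[0])
    return loss


def _cluster_loss_tensor(M: Tensor, bc: BatchClustering, literal_sum: bool,
                         reduction: str) -> Tensor:
    if literal_sum:
        total = None
        for k in range(bc.centroids.shape[0]):
            diff = M - Tensor(bc.centroids[k][None, :])
            term = (diff * diff).sum()
            total = term if total is None else total + term
        loss = total
    else:
        diff = M - Tensor(bc.centroids[bc.assignment])
        loss = (diff * diff).sum()
    if reduction == "mean":
        loss = loss * (1.0 / M.data.shape[0])
    return loss


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class _AdamW:
    """AdamW with decoupled weight decay (beta1=0.9, beta2=0.999)."""

    def __init__(self, pt: dict[str, Tensor], weight_decay: float = 0.01):
        self.pt = pt
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v.data) for k, v in pt.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in pt.items()}
        self.t = 0

    def step(self, lr: float, b1: float = 0.9, b2: float = 0.999,
             eps: float = 1e-8) -> None:
        self.t += 1
        for k, p in self.pt.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p.data = p.data - lr * (m_hat / (np.sqrt(v_hat) + eps)
                                    + self.wd * p.data)


class _SGD:
    def __init__(self, pt: dict[str, Tensor], weight_decay: float = 0.0):
        self.pt = pt
        self.wd = weight_decay

    def step(self, lr: float) -> None:
        for p in self.pt.values():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            p.data = p.data - lr * (g + self.wd * p.data)


# ---------------------------------------------------------------------------
# feature assembly honoring the ablation switches
# ---------------------------------------------------------------------------

def _random_table(vocab: Vocabulary, dim: int, seed: int) -> EmbeddingTable:
    """Seeded random vectors: keeps word identity, removes learned semantics."""
    rng = np.random.default_rng(seed)
    return EmbeddingTable(dim=dim,
                          vectors={w: rng.normal(size=dim) for w in vocab.words})


def build_features(corpus: Corpus, table: EmbeddingTable, vocab: Vocabulary,
                   config: TrainingConfig,
                   weights: DocTermWeights | None = None) -> list[np.ndarray]:
    """FW matrices for the corpus under the config's ablation switches."""
    if not config.ablation.use_embeddings:
        table = _random_table(vocab, table.dim, seed=config.seed + 77)
    if weights is None or not config.ablation.use_tfidf:
        if config.ablation.use_tfidf:
            weights = compute_tfidf(corpus, vocab)
        else:
            weights = DocTermWeights(
                rows=tuple(np.ones(len(d)) for d in corpus), variant="ones")
    return fuse_corpus(corpus, table, weights)


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def train(corpus: Corpus, table: EmbeddingTable, weights: DocTermWeights,
          T: np.ndarray, config: TrainingConfig,
          vocab: Vocabulary | None = None) -> TrainedModel:
    """Run the double-target loop and return the trained model.

    `T` is the frozen document-topic matrix aligned to `corpus`; `weights`
    the per-position TF-IDF values.  Per epoch the document order is
    reshuffled (seeded); per batch the representations are encoded, batch
    K-means centroids fitted on the detached features, and one optimizer
    step taken on alpha * L_cluster + L_topic.  The learning rate decays
    linearly to zero over the run when `lr_linear_decay` is set.
    """
    config.validate()
    if T.shape[0] != len(corpus):
        raise ConfigurationError("topic target rows do not match corpus size")
    if T.shape[1] != config.effective_r_topics:
        raise ConfigurationError(
            f"topic target has {T.shape[1]} topics, config expects "
            f"{config.effective_r_topics}")
    if vocab is None:
        from .corpus_io import build_vocabulary
        vocab = build_vocabulary(corpus, min_doc_freq=1)

    fw_all = build_features(corpus, table, vocab, config, weights=weights)
    enc_config = EncoderConfig(
        emb_dim=table.dim, hidden_units=config.hidden_units,
        attn_dim=config.attn_dim, attn_hops=config.attn_hops,
        proj_dim=config.proj_dim, r_rep=config.r_rep,
        head_dim=config.head_dim, r_topics=config.effective_r_topics)
    params = init_params(enc_config, seed=config.seed)
    pt = params_as_tensors(params)
    opt = _AdamW(pt, config.weight_decay) if config.optimizer == "adamw" \
        else _SGD(pt, config.weight_decay)

    n = len(corpus)
    rng = np.random.default_rng(config.seed)
    n_batches = max(1, int(np.ceil(n / config.batch_size)))
    total_steps = config.epochs * n_batches
    trace: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        alpha = alpha_schedule(epoch, config.effective_t_ramp, config.alpha_max)
        order = rng.permutation(n)
        for b in range(n_batches):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            if idx.size == 0:
                continue
            lr = config.learning_rate
            if config.lr_linear_decay:
                lr *= 1.0 - step / total_steps
            M, D = encode_batch([fw_all[i] for i in idx], pt, enc_config)

            loss = None
            lt_val = 0.0
            lc_val = 0.0
            if config.ablation.use_topic_loss:
                lt = _topic_loss_tensor(T[idx], D, config.reduction)
                lt_val = float(lt.data)
                loss = lt
            if config.ablation.use_cluster_loss:
                if idx.size < config.K:
                    logger.warning(
                        "batch of %d samples < K=%d: cluster loss skipped",
                        idx.size, config.K)
                else:
                    km_seed = int((config.seed * 100003 + step) % (2 ** 31))
                    bc = batch_kmeans(M.data, config.K, seed=km_seed)
                    lc = _cluster_loss_tensor(M, bc, config.literal_cluster_sum,
                                              config.reduction)
                    lc_val = float(lc.data)
                    scaled = lc * alpha
                    loss = scaled if loss is None else loss + scaled
            if loss is None:      # topic loss off and batch too small
                step += 1
                continue
            l_train = joint_loss(lc_val, lt_val, alpha) \
                if config.ablation.use_topic_loss or config.ablation.use_cluster_loss \
                else 0.0
            for p in pt.values():
                p.zero_grad()
            loss.backward()
            opt.step(lr)
            trace.append({"epoch": epoch, "step": step, "alpha": alpha,
                          "lr": lr, "l_cluster": lc_val, "l_topic": lt_val,
                          "l_train": float(loss.data)})
            assert abs(float(loss.data) - l_train) < 1e-6 * max(1.0, abs(l_train))
            step += 1
        logger.info("epoch %d: alpha=%.4f mean L_train=%.6f", epoch, alpha,
                    float(np.mean([r["l_train"] for r in trace[-n_batches:]])))

    params.set_arrays({k: v.data for k, v in pt.items()})
    model = TrainedModel(params=params, config=config, table=table,
                         vocab=vocab, topic_target=T, centroids=None,
                         trace=trace)
    feats = encode_corpus(model, corpus, fw_all=fw_all)
    km = KMeans(n_clusters=config.K, n_init=10, random_state=config.seed)
    km.fit(feats)
    model.centroids = km.cluster_centers_
    return model


def encode_corpus(model: TrainedModel, corpus: Corpus,
                  fw_all: list[np.ndarray] | None = None,
                  chunk: int = 256) -> np.ndarray:
    """Text representations M for every document (no gradients kept)."""
    if fw_all is None:
        fw_all = build_features(corpus, model.table, model.vocab, model.config)
    enc_config = model.params.config
    pt = {k: Tensor(v) for k, v in model.params.named_arrays().items()}
    outs = []
    for lo in range(0, len(fw_all), chunk):
        M, _ = encode_batch(fw_all[lo:lo + chunk], pt, enc_config)
        outs.append(M.data)
    return np.vstack(outs)


def predict_clusters(model: TrainedModel, corpus: Corpus,
                     K: int | None = None, seed: int = 0) -> np.ndarray:
    """Seeded 10-restart K-means over the encoded corpus; one label per doc."""
    K = model.config.K if K is None else K
    if len(corpus) < K:
        raise ValueError(f"corpus of {len(corpus)} documents cannot form {K} clusters")
    feats = encode_corpus(model, corpus)
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    return km.fit_predict(feats)


def baseline_tfidf_kmeans(corpus: Corpus, vocab: Vocabulary, K: int,
                          seed: int = 0, variant: str = "smooth") -> np.ndarray:
    """The classical baseline: TF-IDF bag-of-words vectors + K-means."""
    if len(corpus) < K:
        raise ValueError(f"corpus of {len(corpus)} documents cannot form {K} clusters")
    from .features import _idf
    idf = _idf(vocab, variant)
    idx = vocab.index_of
    X = np.zeros((len(corpus), len(vocab)))
    for i, doc in enumerate(corpus):
        for t in doc.tokens:
            j = idx.get(t)
            if j is not None:
                X[i, j] += 1.0
    for w, j in idx.items():
        X[:, j] *= idf[w]
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    return km.fit_predict(X)
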