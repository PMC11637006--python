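# Methods

`mfdsc` clusters short texts — the motivating case is medical Q&A questions
of a few dozen tokens — by learning a clustering-friendly representation
end-to-end against two self-supervised targets at once. This note records
the model, its assumptions, the numerical choices, and what the synthetic
validation does and does not establish.

## Model

**Text representation.** Each document of k tokens is mapped to a k × T_emb
matrix of word vectors (skip-gram with negative sampling; optional
character-n-gram composition so out-of-vocabulary words still embed as the
sum of their marked n-gram piece vectors). Each row i is scaled by the
token's TF-IDF weight in the document, giving the weighted feature matrix
FW. Very short texts have few informative words; the scaling suppresses the
uninformative ones rather than letting them dominate the average.

The TF-IDF variant is raw term count × smoothed inverse document frequency,

    tfidf(w, d) = tf(w, d) · ( ln((1 + N) / (1 + df(w))) + 1 ),

with no per-document normalization. The smoothing keeps corpus-wide words
at a small positive weight instead of zeroing their embedding rows
entirely; the unsmoothed form ln(N/df) is available behind
`variant="raw"`. A word occurring twice in one document carries the same
weight at both positions. Out-of-vocabulary words weigh 0 (their rows
vanish from FW), which is consistent with the down-weighting intent.

**Encoder.** A bidirectional GRU (u hidden units per direction, zero
initial states, no bias terms) reads FW in both directions; per-token
states are concatenated into H ∈ ℝ^{k×2u}. The gate equations are

    r_t = σ(W_r [h_{t−1}, x_t]),  z_t = σ(W_z [h_{t−1}, x_t]),
    h̃_t = tanh(W_h [r_t ⊙ h_{t−1}, x_t]),
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t .

Structured self-attention scores every position, Z = W₂·tanh(W₁·Hᵀ), and
softmax-normalizes **over the k token positions**, so each attention row is
a distribution over words; the weighted sum Ẑ = A·H is a fixed-length
summary regardless of k. The number of attention hops is configurable and
defaults to 1. A two-layer tanh projection turns Ẑ into the text
representation M ∈ ℝ^{r_rep}, and a separate two-layer ReLU + softmax head
turns M into a topic posterior D on the r_topics-simplex.

A per-token output gate (σ(W_o h_t)) sometimes written alongside the GRU
equations has no consumer in this architecture — attention reads H directly
— and is intentionally not implemented.

**Targets and loss.** Before training, an LDA topic model (batch
variational inference, symmetric Dirichlet priors 1/r_topics) is fitted
once on the corpus bag-of-words and frozen; its per-document posterior
topic mixture T is the cross-document target:

    L_topic = KL(T ‖ D) = Σ_i Σ_j t_ij ln(t_ij / d_ij).

Within each batch, K-means (k-means++ init, ≤ 100 Lloyd iterations) is run
on the detached representations; the clustering loss pulls each sample
toward its **assigned** centroid,

    L_cluster = Σ_i ‖x_i − c_{a(i)}‖²,

with centroids treated as constants. (The all-centroids sum, which would
pull every sample toward every centroid, is implemented behind
`literal_cluster_sum` for comparison; the assigned-centroid form is the
default because it is the reading under which the loss actually sharpens
cluster structure.) The joint objective is

    L_train = α(t) · L_cluster + L_topic,   α(t) = min(t/T_ramp, 1) · α_max,

with α climbing linearly (in epochs) from 0 to α_max = 0.3 and clamping
there; early representations are too unformed for the clustering pull to
help, so it is phased in. Both losses use the same reduction (sum over the
batch by default; mean available) so their balance is exactly as written.

Working assumption: document clusters and topics correspond one-to-one, so
r_topics defaults to K. All-out-of-vocabulary documents get the uniform
topic target; target rows are floored at 1e-12 and renormalized, and the
posterior is floored the same way inside the loss, so the KL is always
finite.

**Optimization.** AdamW (β = 0.9/0.999, decoupled weight decay 0.01) at
learning rate 1e-3 with linear decay to zero over the run; plain SGD is
available in config. Parameters are initialized from N(0, 0.02²), seeded.
Reference defaults: K = 12, batch 256, 32 epochs, 512-dim BiGRU state
(u = 256), 64-dim text representation, one attention hop.

**Prediction.** Final labels come from seeded K-means (10 restarts, best
inertia) over the encoded corpus. The baseline for comparison is the
classical pipeline: per-document TF-IDF bag-of-words vectors (same variant)
clustered by the same seeded K-means.

## Numerical core

No GPU framework is used: the encoder and the joint loss are differentiated
by a small in-package reverse-mode autodiff over float64 numpy arrays
(`mfdsc.autodiff`). Batches of variable-length documents are right-padded
and masked — pad positions are frozen out of both recurrences and masked
out of the attention softmax — and a test pins the batched path to the
per-document numpy forward to 1e-10. Gradients are verified against central
finite differences to 1e-4 relative error. Softmaxes subtract a
data-dependent constant shift (exact, by shift invariance) for stability.
Everything is single-threaded and seeded; identical runs are bit-identical.

## Evaluation

ACC is the best accuracy over one-to-one mappings between predicted
clusters and gold classes, found by optimal assignment on the contingency
table (rectangular tables are handled directly; ties in matched count are
broken toward the mapping with the larger summed per-pair F1 so the mapping
is invariant under relabeling). NMI uses the arithmetic-mean normalization.
ARI is the standard chance-corrected pair-count index. Because the
literature computes clustering F1 in more than one way, both are reported:
macro (unweighted per-class mean after the optimal mapping; the default)
and pairwise (precision/recall over same-cluster pairs).

## Synthetic benchmark

The generator draws K clusters of short documents (5–30 tokens) from
cluster-private vocabularies with Zipf-shaped frequencies (exponent 1.1 —
uniform word use would make TF-IDF uninformative and untestable); each
token is replaced, with probability `overlap`, by a draw from a shared
pool. Overlap 0 with an empty shared pool gives pairwise-disjoint
vocabularies; overlap 1 removes the lexical cluster signal entirely
(verified by a chi-square test on per-cluster unigram counts). Token
strings are synthetic; no real medical vocabulary is shipped.

The standard validation benchmark (`mfdsc.benchmark`) uses K = 3 clusters
× 100 documents, 50-word private pools, a 50-word shared pool, and a
scaled-down network — 16-dim embeddings (10 skip-gram epochs), u = 16
(32-dim BiGRU state), 16-dim representation, batch 16, 8 epochs — sized so
one full pipeline run takes seconds on a single CPU core. Batch size scales
with the corpus: 16 gives this 300-document corpus roughly the same
optimizer-step count per epoch that the reference batch of 256 gives a
~14k-document corpus.

On this benchmark (medians over seeds): at overlap 0 both the full pipeline
and the TF-IDF baseline recover the generating partition almost perfectly
(NMI ≥ 0.95); at overlap 0.5 the full pipeline tracks or exceeds the
baseline; disabling the topic loss lowers the median NMI, matching the
expected ablation direction. The acceptance script recomputes these
numbers; the test suite asserts them.

**What this does and does not show.** The generator produces exchangeable
bag-like documents: cluster identity is carried entirely by unigram
choice, word order is random, and there is no syntax, polysemy, or
label noise. Passing these tests demonstrates that the machinery is
correct and that the double-target training recovers known structure under
its own assumptions; it does not certify performance on real clinical text,
where topic–cluster correspondence is approximate and the lexical signal
is weaker.

## Degenerate inputs and edge rules

- Empty documents are rejected at load time; `min_tokens` drops short ones
  (logged).
- A batch smaller than K skips the cluster loss for that batch (logged);
  the topic loss still applies.
- Disabling both losses is a configuration error.
- Single-token documents work end-to-end (k = 1 attention is a point mass).
- K-means assignments are recomputed as exact nearest-centroid after
  fitting, so the assignment invariant holds even at the iteration cap.

## Known limitations

- The skip-gram trainer is a compact implementation aimed at corpora of
  10²–10⁵ tokens; it is a Python loop, not a vectorized production trainer.
- LDA quality gates the topic target: corpora where LDA finds no usable
  topics (very few documents, no lexical structure) give the method no
  cross-document signal beyond the cluster loss.
- The alpha ramp is counted in epochs; with very few epochs the cluster
  loss contributes only near the end of training.
- Determinism guarantees assume single-threaded execution.
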