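# mfdsc — double-target self-supervised clustering of short texts

Short texts — the motivating case is patient questions from a medical Q&A
community — are hard to cluster: a handful of tokens, sparse vocabulary,
little context. `mfdsc` implements MF-DSC, a method that learns a
clustering-friendly text representation end-to-end by combining multi-feature
fusion with two self-supervised targets:

1. **Fusion.** Per-word embeddings (skip-gram, optional character-n-gram
   subwords) are scaled row-wise by TF-IDF weights,
   `FW[i] = tfidf_i · a_i`, so uninformative words are suppressed before
   encoding.
2. **Encoder.** A bidirectional GRU produces per-token states
   `H ∈ ℝ^{k×2u}`; structured self-attention (softmax over token positions)
   and a two-layer projection give a fixed-length representation
   `M ∈ ℝ^{r_rep}`; a two-layer head gives a topic posterior `D`.
3. **Double target.** The joint loss is

       L_train = α(t) · L_cluster + L_topic

   where `L_topic = KL(T ‖ D)` against a frozen LDA document-topic
   distribution `T` (cross-document signal), `L_cluster` pulls each
   representation toward its within-batch K-means centroid, and
   `α(t) = min(t/T′, 1) · α_max` climbs linearly from 0 to α_max = 0.3.

Final labels come from seeded multi-restart K-means over the encoded
corpus, and are evaluated with ACC (optimal cluster-to-class mapping), NMI,
ARI and F1 (macro and pairwise). A classical TF-IDF + K-means baseline is
included. See `docs/methods.md` for the full model, assumptions and
numerical details — including the package's own reverse-mode autodiff core
that makes the whole network run on plain numpy.

## Worked example

Everything is testable without any dataset: the built-in generator draws K
topic-clusters of 5–30-token documents from Zipf-shaped cluster
vocabularies, with an `overlap` dial (probability a token comes from a
shared pool) controlling difficulty.

```python
from mfdsc.benchmark import run_benchmark

res = run_benchmark(overlap=0.5, seed=1)   # 3 clusters x 100 docs, half shared tokens
m, b = res["mfdsc"], res["baseline"]
print(f"MF-DSC    NMI={m['nmi']:.4f}  ARI={m['ari']:.4f}  ACC={m['acc']:.4f}  F1={m['f1']:.4f}")
print(f"baseline  NMI={b['nmi']:.4f}  ARI={b['ari']:.4f}  ACC={b['acc']:.4f}  F1={b['f1']:.4f}")
```

prints

```
MF-DSC    NMI=0.9488  ARI=0.9605  ACC=0.9867  F1=0.9867
baseline  NMI=0.9317  ARI=0.9503  ACC=0.9833  F1=0.9834
```

Even at 50% vocabulary overlap the learned representation recovers the
generating partition essentially perfectly (ACC 0.987) and edges out the
bag-of-words baseline on NMI/ARI — the double-target training is doing
real work beyond TF-IDF geometry.

The same pipeline is available from the shell for real corpora (one
pre-tokenized document per line; optional parallel integer label file):

```sh
mfdsc synth out/ --k 3 --overlap 0.5 --seed 1     # or bring your own tokens.txt
mfdsc fit config.yaml                             # -> model dir, trace.csv, labels.txt
mfdsc predict run/model tokens.txt pred.txt
mfdsc evaluate pred.txt gold.txt                  # ACC/NMI/ARI/F1 as JSON
mfdsc baseline tokens.txt pred.txt --k 3
```

`config.yaml` is flat and mirrors the training-config field names
(`tokens`, `labels`, `outdir`, `K`, `batch_size`, `epochs`,
`alpha_max`, ablation switches `use_tfidf` / `use_embeddings` /
`use_topic_loss` / `use_cluster_loss`, ...). One global seed fans out to
per-stage seeds; every run writes a manifest and a per-step loss/α trace,
and identical seeded runs are bit-identical.

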