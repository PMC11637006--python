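"""Clustering evaluation: ACC, NMI, ARI and F1 against gold labels.

All four indicators are invariant under relabeling of the predicted cluster
ids.  ACC finds the best one-to-one mapping between predicted clusters and
gold classes by optimal assignment on the contingency table; NMI uses the
arithmetic-mean normalization; F1 is reported in two conventions — macro
(per-class, after the optimal mapping) and pairwise (precision/recall over
same-cluster sample pairs) — because the literature uses both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    nmi: float
    ari: float
    f1: float                       # the default (macro) variant
    f1_macro: float
    f1_pairwise: float
    n: int
    contingency: np.ndarray         # predicted clusters x gold classes

    def as_dict(self) -> dict:
        return {"acc": self.acc, "nmi": self.nmi, "ari": self.ari,
                "f1": self.f1, "f1_macro": self.f1_macro,
                "f1_pairwise": self.f1_pairwise, "n": self.n}


def _check(gold, pred, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    gold = np.asarray(gold)
    pred = np.asarray(pred)
    if gold.shape != pred.shape or gold.ndim != 1:
        raise ValueError(f"label vectors must be 1-D and equal length, "
                         f"got {gold.shape} vs {pred.shape}")
    if gold.size < min_len:
        raise ValueError(f"need at least {min_len} samples")
    return gold, pred


def _optimal_mapping(gold: np.ndarray, pred: np.ndarray) -> tuple[dict, np.ndarray]:
    """Best injective pred-cluster -> gold-class mapping via optimal assignment.

    Ties in matched-sample count are broken toward the mapping with the
    largest summed per-pair F1, so the mapping (and macro F1) is invariant
    under relabeling of either side.
    """
    C = contingency_matrix(gold, pred).T.astype(float)   # rows = pred clusters
    sizes_p = C.sum(axis=1, keepdims=True)
    sizes_g = C.sum(axis=0, keepdims=True)
    f1_pair = 2.0 * C / (sizes_p + sizes_g)
    delta = 0.5 / (gold.size + 1.0)          # too small to disturb the count optimum
    rows, cols = linear_sum_assignment(C + delta * f1_pair, maximize=True)
    pred_ids = np.unique(pred)
    gold_ids = np.unique(gold)
    return {pred_ids[r]: gold_ids[c] for r, c in zip(rows, cols)}, C


def clustering_accuracy(gold, pred) -> float:
    """Fraction correct under the best one-to-one cluster-to-class mapping."""
    gold, pred = _check(gold, pred)
    mapping, C = _optimal_mapping(gold, pred)
    pred_idx = {p: i for i, p in enumerate(np.unique(pred))}
    gold_idx = {g: j for j, g in enumerate(np.unique(gold))}
    matched = sum(C[pred_idx[p], gold_idx[g]] for p, g in mapping.items())
    return float(matched / gold.size)


def nmi(gold, pred) -> float:
    """Mutual information normalized by the mean of the two label entropies."""
    gold, pred = _check(gold, pred)
    return float(normalized_mutual_info_score(gold, pred,
                                              average_method="arithmetic"))


def ari(gold, pred) -> float:
    """Adjusted Rand index: chance-corrected pair-counting agreement."""
    gold, pred = _check(gold, pred, min_len=2)
    return float(adjusted_rand_score(gold, pred))


def clustering_f1(gold, pred, variant: str = "macro") -> float:
    """F1 of the clustering against gold labels.

    "pairwise": precision/recall over unordered sample pairs placed in the
    same cluster.  "macro": unweighted mean of per-gold-class F1 after the
    optimal one-to-one mapping (clusters left unmapped predict no class).
    """
    gold, pred = _check(gold, pred)
    if variant == "pairwise":
        C = contingency_matrix(gold, pred).astype(np.int64)
        def pairs(x):
            return float((x * (x - 1) // 2).sum())
        tp = pairs(C)
        pred_pairs = pairs(C.sum(axis=0))
        gold_pairs = pairs(C.sum(axis=1))
        if pred_pairs == 0 and gold_pairs == 0:
            return 1.0
        precision = tp / pred_pairs if pred_pairs else 0.0
        recall = tp / gold_pairs if gold_pairs else 0.0
        return 0.0 if precision + recall == 0 else \
            float(2 * precision * recall / (precision + recall))
    if variant == "macro":
        mapping, _ = _optimal_mapping(gold, pred)
        mapped = np.array([mapping.get(p, -1) for p in pred])
        scores = []
        for c in np.unique(gold):
            tp = float(np.sum((mapped == c) & (gold == c)))
            fp = float(np.sum((mapped == c) & (gold != c)))
            fn = float(np.sum((mapped != c) & (gold == c)))
            denom = 2 * tp + fp + fn
            scores.append(0.0 if denom == 0 else 2 * tp / denom)
        return float(np.mean(scores))
    raise ValueError(f"unknown F1 variant {variant!r}")


def evaluate(gold, pred) -> MetricsReport:
    """All indicators at once, plus the contingency table."""
    gold, pred = _check(gold, pred)
    C = contingency_matrix(gold, pred).T
    f1_macro = clustering_f1(gold, pred, "macro")
    return MetricsReport(
        acc=clustering_accuracy(gold, pred),
        nmi=nmi(gold, pred),
        ari=ari(gold, pred) if gold.size >= 2 else 1.0,
        f1=f1_macro,
        f1_macro=f1_macro,
        f1_pairwise=clustering_f1(gold, pred, "pairwise"),
        n=int(gold.size),
        contingency=C,
    )
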