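"""Prediction heads and the three training losses.

Prediction uses only the fused graph-side vectors: each depth l has its own
linear head, and the per-layer outputs are averaged into the final logits
(classification) or scalar (regression).  The supervised loss is
cross-entropy / mean squared error; multi-task binary panels use per-task
binary cross-entropy restricted to observed labels.

The prototype contrastive loss treats every prototype in turn as an anchor:
same-class prototypes are positives (averaged in the numerator), and the
denominator runs over the unrestricted double sum of temperature-scaled
cosine similarities — including the anchor's self-similarity term.  For
regression (a single prototype class) pseudo-classes come from a 2-means
partition of the prototypes, refreshed once per training epoch.

The total objective is the weighted combination
``L = lambda_align * L_align + lambda_pred * L_pred + lambda_proto * L_proto``
with all three coefficients defaulting to 0.9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .nn import Linear, ParameterStore, Tensor

__all__ = ["PredictionHeads", "LossWeights", "LossBreakdown", "predict",
           "predictive_loss", "cosine_similarity_matrix",
           "proto_contrastive_cls", "kmeans_partition",
           "proto_contrastive_reg", "total_loss"]


@dataclass
class LossWeights:
    lambda_align: float = 0.9
    lambda_pred: float = 0.9
    lambda_proto: float = 0.9
    tau: float = 0.5            # contrastive temperature
    M: int = 2                  # pseudo-class count for regression

    def __post_init__(self):
        if min(self.lambda_align, self.lambda_pred, self.lambda_proto) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if self.M != 2:
            raise ValueError("the regression partition uses exactly 2 clusters")


@dataclass
class LossBreakdown:
    L_align: float
    L_pred: float
    L_proto: float
    L_total: float
    total: Tensor | None = field(default=None, repr=False)


class PredictionHeads:
    """One linear head per encoder depth, averaged into the prediction."""

    def __init__(self, L: int, d_g: int, out_dim: int, store: ParameterStore,
                 rng: np.random.Generator, name: str = "heads"):
        if L < 1:
            raise ValueError("L must be >= 1")
        self.L = L
        self.out_dim = out_dim
        self.heads = [Linear(store, f"{name}.layer{l}", d_g, out_dim, rng)
                      for l in range(L)]


def predict(hat_z_g_layers: list[Tensor], heads: PredictionHeads) -> Tensor:
    """o-hat = (1/L) sum_i Linear_i(hat_z_g^(i))."""
    if len(hat_z_g_layers) != heads.L:
        raise ValueError(f"expected {heads.L} fused layers, "
                         f"got {len(hat_z_g_layers)}")
    total = heads.heads[0](hat_z_g_layers[0])
    for head, z in zip(heads.heads[1:], hat_z_g_layers[1:]):
        total = total + head(z)
    return total * (1.0 / heads.L)


def predictive_loss(o_hat: Tensor, y: np.ndarray, task_kind: str,
                    label_mask: np.ndarray | None = None) -> Tensor:
    """Supervised loss: cross-entropy, MSE, or masked multi-task binary CE.

    ``o_hat`` may be a single output or a batch (first axis).  Batched
    losses are averaged over samples (and over observed task labels for
    multi-task inputs).
    """
    squeeze = o_hat.ndim == 1 and task_kind == "classification"
    o2 = o_hat.reshape(1, -1) if o_hat.ndim == 1 else o_hat
    y = np.atleast_1d(np.asarray(y))

    if task_kind == "regression":
        pred = o2.reshape(-1)
        target = y.reshape(-1)
        if not np.all(np.isfinite(target)):
            raise ValueError("regression labels must be finite")
        err = pred - Tensor(target)
        return (err * err).mean()

    if task_kind == "classification":
        if label_mask is not None and not np.all(label_mask):
            raise ValueError("single-task classification requires an "
                             "observed label for every sample")
        idx = y.astype(int).reshape(-1)
        if np.any(idx < 0) or np.any(idx >= o2.shape[1]):
            raise ValueError("class labels must lie in [0, C)")
        logp = o2.log_softmax(axis=-1)
        picked = logp.take_cols(idx[:, None])
        loss = -picked.mean()
        return loss

    if task_kind == "multitask":
        if label_mask is None:
            raise ValueError("multi-task loss requires a label mask")
        mask = np.asarray(label_mask, dtype=float).reshape(o2.shape)
        if mask.sum() == 0:
            raise ValueError("no observed labels in batch")
        targets = Tensor(np.asarray(y, dtype=float).reshape(o2.shape))
        # numerically stable BCE-with-logits:
        #   max(o, 0) - o*y + log(1 + exp(-|o|))
        relu_o = o2.relu()
        abs_o = o2 * Tensor(np.sign(o2.data))
        softplus = ((-abs_o).exp() + 1.0).log()
        per = relu_o - o2 * targets + softplus
        return (per * Tensor(mask)).sum() * (1.0 / mask.sum())

    raise ValueError(f"unknown task_kind: {task_kind!r}")


def cosine_similarity_matrix(P: Tensor) -> Tensor:
    """Pairwise cosine similarities between prototype rows."""
    norms = (P * P).sum(axis=-1, keepdims=True).sqrt()
    Z = P / norms
    return Z @ Z.T


def _contrastive_from_masks(P: Tensor, pos_mask: np.ndarray,
                            pos_counts: np.ndarray, tau: float) -> Tensor:
    """InfoNCE over prototype anchors given a positive mask.

    pos_mask[a, b] = 1 when b is a positive for anchor a (b != a, same
    class/cluster); pos_counts[a] is the number of positives of anchor a.
    Anchors without positives are excluded from the mean.
    """
    S = cosine_similarity_matrix(P)
    E = (S * (1.0 / tau)).exp()
    num = (E * Tensor(pos_mask)).sum(axis=-1) / \
        Tensor(np.maximum(pos_counts, 1.0))
    den = E.sum(axis=-1)        # unrestricted sum, anchor term included
    keep = pos_counts > 0
    if not np.all(keep):
        # anchors without positives contribute log(1) = 0, then drop out
        num = num + Tensor((~keep).astype(float)) * den
        losses = -(num / den).log()
        sel = Tensor(keep.astype(float))
        return (losses * sel).sum() * (1.0 / keep.sum())
    return -(num / den).log().mean()


def proto_contrastive_cls(P: Tensor, C: int, N: int, tau: float) -> Tensor:
    """Prototype contrastive loss for classification (C classes, N
    prototypes per class, prototypes flattened class-major)."""
    if C < 2:
        raise ValueError("classification contrastive loss needs C >= 2")
    if N < 2:
        raise ValueError("need N >= 2 prototypes per class (no positives)")
    labels = np.repeat(np.arange(C), N)
    pos_mask = (labels[:, None] == labels[None, :]).astype(float)
    np.fill_diagonal(pos_mask, 0.0)
    pos_counts = np.full(C * N, float(N - 1))
    return _contrastive_from_masks(P, pos_mask, pos_counts, tau)


def kmeans_partition(P_values: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-means partition of prototype vectors into pseudo-classes.

    Lloyd's algorithm with 10 restarts and at most 100 iterations; the seed
    fixes the restarts so the partition is reproducible.  Returns a cluster
    label (0/1) per prototype.
    """
    P_values = np.asarray(P_values, dtype=float)
    if P_values.shape[0] < 2:
        raise ValueError("need at least 2 prototypes to partition")
    if np.allclose(P_values, P_values[0]):
        raise ValueError("degenerate clustering: all prototypes identical")
    km = KMeans(n_clusters=2, n_init=10, max_iter=100, algorithm="lloyd",
                random_state=seed)
    labels = km.fit_predict(P_values)
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate clustering: a cluster is empty")
    return labels


def proto_contrastive_reg(P: Tensor, cluster_labels: np.ndarray,
                          tau: float) -> Tensor:
    """Prototype contrastive loss for regression: the 2-means clusters act
    as pseudo-classes.  Anchors in a singleton cluster have no positives and
    are skipped with a warning."""
    cluster_labels = np.asarray(cluster_labels)
    if P.shape[0] != cluster_labels.shape[0]:
        raise ValueError("one cluster label per prototype is required")
    pos_mask = (cluster_labels[:, None] == cluster_labels[None, :]).astype(float)
    np.fill_diagonal(pos_mask, 0.0)
    pos_counts = pos_mask.sum(axis=1)
    if np.all(pos_counts == 0):
        raise ValueError("both clusters are singletons: no positives exist")
    if np.any(pos_counts == 0):
        warnings.warn("singleton cluster: its anchor is skipped in the "
                      "contrastive loss")
    return _contrastive_from_masks(P, pos_mask, pos_counts, tau)


def total_loss(L_align: Tensor | float, L_pred: Tensor | float,
               L_proto: Tensor | float, weights: LossWeights) -> LossBreakdown:
    """Weighted combination of the three loss components."""
    comps = []
    for comp in (L_align, L_pred, L_proto):
        t = comp if isinstance(comp, Tensor) else Tensor(float(comp))
        if not np.all(np.isfinite(t.data)):
            raise ValueError("non-finite loss component")
        comps.append(t)
    total = comps[0] * weights.lambda_align + \
        comps[1] * weights.lambda_pred + comps[2] * weights.lambda_proto
    return LossBreakdown(
        L_align=float(comps[0].data), L_pred=float(comps[1].data),
        L_proto=float(comps[2].data), L_total=float(total.data),
        total=total)
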