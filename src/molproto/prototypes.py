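"""Unified prototype space for cross-modal alignment.

A learnable tensor of ``C x N`` prototypes (N semantic anchors per class, a
single pseudo-class for regression) lives in a shared ``d_p``-dimensional
latent space.  Fused layer-wise representations are mean-pooled over depth,
projected into the prototype space by modality-specific affine maps, and
scored against every prototype by squared Euclidean distance.  Distances are
converted to bounded similarities with a log-ratio transform
``s = log((D + 1) / (D + eps))``, sparsified to the top-K most responsive
prototypes, and normalised with a softmax over the retained raw scores.
The alignment objective is the KL divergence between the graph-side and
text-side prototype distributions, which pushes both modalities to activate
the same semantic anchors.

Because the two modalities' top-K supports can differ, the KL is evaluated
on full-length (C*N) vectors: off-support mass is floored at a small
constant and the vector renormalised, preserving index correspondence while
keeping the divergence finite.  An alternative restricted to the
intersection of supports is available via ``support="intersection"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, ParameterStore, Tensor

__all__ = ["PrototypeSpace", "PrototypeDistribution", "aggregate_layers",
           "log_ratio_similarity", "topk_distribution", "alignment_loss"]


def aggregate_layers(hat_layers: list[Tensor]) -> Tensor:
    """Mean-pool fused representations over depth: z-bar = (1/L) sum_l z^(l)."""
    if not hat_layers:
        raise ValueError("cannot aggregate an empty layer list")
    total = hat_layers[0]
    for z in hat_layers[1:]:
        total = total + z
    return total * (1.0 / len(hat_layers))


@dataclass
class PrototypeDistribution:
    """Top-K sparse prototype response of one modality."""

    scores: Tensor          # full similarity vector(s), (B, C*N)
    sparse_scores: Tensor   # same shape, zero off the top-K support
    support: np.ndarray     # (B, K) retained flat indices
    alpha: Tensor           # (B, K) softmax weights over retained raw scores
    space_id: int           # identity of the generating PrototypeSpace

    @property
    def K(self) -> int:
        return self.support.shape[-1]


class PrototypeSpace:
    """Learnable prototypes plus the two modality projections."""

    def __init__(self, C: int, N: int, d_p: int, d_g: int, d_t: int,
                 store: ParameterStore, rng: np.random.Generator,
                 epsilon: float = 1e-6, K: int = 5, name: str = "proto"):
        if C < 1 or N < 1:
            raise ValueError("C and N must be >= 1")
        if not (1 <= K <= C * N):
            raise ValueError(f"K must lie in [1, C*N]; got K={K}, C*N={C * N}")
        if not (0.0 < epsilon < 1.0):
            raise ValueError("epsilon must lie in (0, 1)")
        self.C, self.N, self.d_p, self.K, self.epsilon = C, N, d_p, K, epsilon
        # prototypes flattened row-major by class then prototype index
        self.P = store.add(f"{name}.P",
                           rng.standard_normal((C * N, d_p)) / np.sqrt(d_p))
        self.proj_g = Linear(store, f"{name}.proj_g", d_g, d_p, rng)
        self.proj_t = Linear(store, f"{name}.proj_t", d_t, d_p, rng)

    def project(self, z_bar: Tensor, modality: str) -> Tensor:
        if modality == "g":
            proj = self.proj_g
        elif modality == "t":
            proj = self.proj_t
        else:
            raise ValueError(f"modality must be 'g' or 't', got {modality!r}")
        expected = proj.W.shape[0]
        if z_bar.shape[-1] != expected:
            raise ValueError(f"modality {modality!r} expects dimension "
                             f"{expected}, got {z_bar.shape[-1]}")
        return proj(z_bar)

    def distances(self, z_p: Tensor) -> Tensor:
        """Squared Euclidean distance to every prototype, flat (c, n) order."""
        squeeze = z_p.ndim == 1
        if squeeze:
            z_p = z_p.reshape(1, -1)
        diff = z_p.reshape(z_p.shape[0], 1, self.d_p) - \
            self.P.reshape(1, self.C * self.N, self.d_p)
        D = (diff * diff).sum(axis=-1)
        return D.reshape(self.C * self.N) if squeeze else D

    def project_and_distance(self, z_bar: Tensor, modality: str) -> Tensor:
        return self.distances(self.project(z_bar, modality))

    def response(self, z_bar: Tensor, modality: str) -> PrototypeDistribution:
        """Full pipeline: project, distance, log-ratio, top-K, softmax."""
        D = self.project_and_distance(z_bar, modality)
        s = log_ratio_similarity(D, self.epsilon)
        return topk_distribution(s, self.K, space_id=id(self))


def log_ratio_similarity(D: Tensor | np.ndarray, epsilon: float) -> Tensor:
    """s = log((D + 1) / (D + eps)); strictly decreasing in D, with range
    (0, log(1/eps)] for eps < 1."""
    D = D if isinstance(D, Tensor) else Tensor(D)
    if np.any(D.data < 0):
        raise ValueError("squared distances must be non-negative")
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must lie in (0, 1)")
    return ((D + 1.0) / (D + epsilon)).log()


def topk_distribution(s: Tensor | np.ndarray, K: int,
                      space_id: int = 0) -> PrototypeDistribution:
    """Retain the K largest similarity scores (ties broken by lowest flat
    index), zero the rest, and soft-normalise the retained raw scores.

    Gradients flow only through the K retained entries, matching a softmax
    taken over the retained raw scores with masked zeros excluded.
    """
    s = s if isinstance(s, Tensor) else Tensor(s)
    squeeze = s.ndim == 1
    s2 = s.reshape(1, -1) if squeeze else s
    width = s2.shape[1]
    if not (1 <= K <= width):
        raise ValueError(f"K must lie in [1, {width}]; got {K}")
    # stable argsort on -s: equal scores keep ascending index order
    order = np.argsort(-s2.data, axis=1, kind="stable")
    support = np.sort(order[:, :K], axis=1)
    retained = s2.take_cols(support)
    alpha = retained.softmax(axis=-1)
    sparse = retained.scatter_cols(support, width)
    if squeeze:
        return PrototypeDistribution(scores=s2.reshape(width),
                                     sparse_scores=sparse.reshape(width),
                                     support=support[0],
                                     alpha=alpha.reshape(K),
                                     space_id=space_id)
    return PrototypeDistribution(scores=s2, sparse_scores=sparse,
                                 support=support, alpha=alpha,
                                 space_id=space_id)


def alignment_loss(dist_g: PrototypeDistribution,
                   dist_t: PrototypeDistribution,
                   floor: float = 1e-8,
                   support: str = "union") -> Tensor:
    """KL(alpha_g || alpha_t) on index-aligned full-length vectors.

    Off-support entries receive probability ``floor`` and each vector is
    renormalised, so supports that differ between modalities still compare
    coordinate by coordinate.  ``support="intersection"`` instead restricts
    the divergence to indices retained by both modalities (renormalised).
    Batched inputs return the mean divergence over rows.
    """
    if dist_g.space_id != dist_t.space_id:
        raise ValueError("distributions come from different prototype spaces")
    squeeze = dist_g.alpha.ndim == 1
    width = dist_g.scores.data.shape[-1]

    def full(dist: PrototypeDistribution) -> tuple[Tensor, np.ndarray]:
        alpha = dist.alpha.reshape(1, -1) if squeeze else dist.alpha
        sup = dist.support.reshape(alpha.shape[0], -1)
        scattered = alpha.scatter_cols(sup, width)
        mask = np.ones((alpha.shape[0], width))
        rows = np.arange(alpha.shape[0])[:, None]
        mask[rows, sup] = 0.0
        vec = scattered + Tensor(mask * floor)
        return vec / vec.sum(axis=-1, keepdims=True), mask

    p, mask_g = full(dist_g)
    q, mask_t = full(dist_t)
    if support == "intersection":
        both = (mask_g == 0.0) & (mask_t == 0.0)
        if not both.any(axis=1).all():
            raise ValueError("empty support intersection")
        sel = Tensor(both.astype(float))
        p = p * sel
        q = q * sel
        p = p / p.sum(axis=-1, keepdims=True)
        q = q / q.sum(axis=-1, keepdims=True)
        # avoid log(0) off the intersection: those terms carry zero p mass
        q = q + Tensor((~both).astype(float))
        p = p + Tensor((~both).astype(float))
    elif support != "union":
        raise ValueError(f"unknown support mode {support!r}")
    kl_rows = (p * (p / q).log()).sum(axis=-1)
    return kl_rows.mean() if kl_rows.data.ndim else kl_rows
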