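"""Layer-wise bidirectional cross-modal attention with residual fusion.

At every depth l the graph vector is linearly projected into the text space
(z_{g->t} = W_{g->t} z_g) and the text vector into the graph space
(z_{t->g} = W_{t->g} z_t).  Each modality then cross-attends to the projected
counterpart — scaled dot-product attention where the projected vector is both
key and value — and the attended vector is added back through a residual
connection:

    hat_z_t^(l) = z_t^(l) + CrossAttn(z_t^(l), z_{g->t}^(l), z_{g->t}^(l))
    hat_z_g^(l) = z_g^(l) + CrossAttn(z_g^(l), z_{t->g}^(l), z_{t->g}^(l))

With a single key the attention softmax is identically 1, so the attended
vector equals the projected cross-modal vector exactly; the residual fusion
is then hat_z_t = z_t + W_{g->t} z_g (and symmetrically for the graph side).
We implement this literal single-key form; the 1/sqrt(d_g) scale of the
attention logit is kept as written but is inert when there is one key.

Projections carry no bias and use variance-scaled uniform initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import ParameterStore, Tensor

__all__ = ["FusedEmbeddings", "cross_attend", "BidirectionalFusion"]


@dataclass
class FusedEmbeddings:
    """Fused per-layer vectors plus retained intermediates for inspection."""

    hat_z_g_layers: list[Tensor]
    hat_z_t_layers: list[Tensor]
    z_g_to_t_layers: list[Tensor]
    z_t_to_g_layers: list[Tensor]
    tilde_z_g_layers: list[Tensor]
    tilde_z_t_layers: list[Tensor]

    @property
    def L(self) -> int:
        return len(self.hat_z_g_layers)


def cross_attend(query: Tensor | np.ndarray, kv: Tensor | np.ndarray,
                 scale_dim: int) -> Tensor:
    """Scaled dot-product attention of ``query`` over a singleton key/value
    set ``{kv}``: softmax(q . kv / sqrt(scale_dim)) * kv.

    The softmax over a single logit is exactly 1 (and its gradient with
    respect to the logit is exactly 0), so the output is ``kv`` and no
    gradient flows through the query or the scale.
    """
    query = query if isinstance(query, Tensor) else Tensor(query)
    kv = kv if isinstance(kv, Tensor) else Tensor(kv)
    if query.shape != kv.shape:
        raise ValueError(f"query/kv dimensionality mismatch: "
                         f"{query.shape} vs {kv.shape}")
    if not (np.all(np.isfinite(query.data)) and np.all(np.isfinite(kv.data))):
        raise ValueError("non-finite attention inputs")
    logit = (query.data * kv.data).sum(axis=-1) / np.sqrt(scale_dim)
    # softmax over the singleton key set: exp(l) / exp(l) == 1 for any logit
    weight = np.ones_like(np.atleast_1d(logit))
    if query.ndim == 1:
        return kv * float(weight[0])
    return kv * weight[:, None]


class BidirectionalFusion:
    """Per-layer projection matrices plus the bidirectional fuse step."""

    def __init__(self, L: int, d_g: int, d_t: int, store: ParameterStore,
                 rng: np.random.Generator, name: str = "fusion"):
        if L < 1:
            raise ValueError("L must be >= 1")
        self.L, self.d_g, self.d_t = L, d_g, d_t
        lim_gt = np.sqrt(6.0 / (d_g + d_t))
        # stored transposed relative to the W z convention: rows index the
        # source space, so projection is z @ W
        self.W_g_to_t = [
            store.add(f"{name}.layer{l}.W_g_to_t",
                      rng.uniform(-lim_gt, lim_gt, size=(d_g, d_t)))
            for l in range(L)
        ]
        self.W_t_to_g = [
            store.add(f"{name}.layer{l}.W_t_to_g",
                      rng.uniform(-lim_gt, lim_gt, size=(d_t, d_g)))
            for l in range(L)
        ]

    def fuse(self, z_g_layers: list[Tensor], z_t_layers: list[Tensor],
             final_layer_only: bool = False) -> FusedEmbeddings:
        """Fuse the two layer-wise representation sets.

        ``final_layer_only`` reproduces single-stage fusion at the last
        encoder layer (the "w/o CA" ablation): earlier layers pass through
        unfused.
        """
        if len(z_g_layers) != self.L or len(z_t_layers) != self.L:
            raise ValueError(
                f"layer-count mismatch: fusion has L={self.L}, got "
                f"{len(z_g_layers)} graph / {len(z_t_layers)} text layers")
        out = FusedEmbeddings([], [], [], [], [], [])
        for l in range(self.L):
            z_g, z_t = z_g_layers[l], z_t_layers[l]
            z_gt = z_g @ self.W_g_to_t[l]
            z_tg = z_t @ self.W_t_to_g[l]
            tilde_t = cross_attend(z_t, z_gt, self.d_g)
            tilde_g = cross_attend(z_g, z_tg, self.d_g)
            fused_here = (not final_layer_only) or l == self.L - 1
            out.z_g_to_t_layers.append(z_gt)
            out.z_t_to_g_layers.append(z_tg)
            out.tilde_z_t_layers.append(tilde_t)
            out.tilde_z_g_layers.append(tilde_g)
            out.hat_z_t_layers.append(z_t + tilde_t if fused_here else z_t)
            out.hat_z_g_layers.append(z_g + tilde_g if fused_here else z_g)
        return out
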