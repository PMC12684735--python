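"""End-to-end multimodal model: graph encoder + text branch + layer-wise
fusion + prototype space + prediction heads.

The forward pass over a mini-batch of molecule/text records:

1. pack the molecular graphs into one block-diagonal batch and run the
   L-layer GIN, reading out a graph vector after every layer;
2. embed and mean-pool each record's tokens with the text provider (a frozen,
   deterministic embedding by default) and refine the pooled vector through
   the L-layer transformer;
3. fuse the two layer-wise sets with bidirectional singleton cross-attention
   and residuals;
4. mean-pool the fused layers over depth, project both modalities into the
   prototype space, and form top-K prototype distributions;
5. predict from the fused graph-side layers, and combine the alignment (KL),
   supervised, and prototype contrastive losses.

Ablation hooks reproduce the standard variant definitions: ``no_ca`` fuses
only at the final layer, ``no_up`` learns separate per-modality prototype
spaces, and ``no_al`` / ``no_cl`` / ``no_pr`` zero the corresponding loss
weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import objectives
from .fusion import BidirectionalFusion, FusedEmbeddings
from .graph_encoder import GINEncoder, GraphBatch, GraphEncoderConfig
from .mol_io import NUM_ATOM_FEATURES, MoleculeRecord
from .nn import ParameterStore, Tensor
from .objectives import LossBreakdown, LossWeights, PredictionHeads
from .prototypes import PrototypeSpace, aggregate_layers, alignment_loss
from .text_encoder import (DeterministicTextEmbedder, TextProviderContract,
                           TextRefiner, embed_and_pool)

__all__ = ["ModelConfig", "MultimodalPrototypeModel", "ABLATIONS"]

ABLATIONS = ("none", "no_ca", "no_up", "no_al", "no_cl", "no_pr")


@dataclass
class ModelConfig:
    L: int = 3
    d_g: int = 64
    d_t: int = 64
    d_p: int = 64
    C: int = 2                  # prototype classes (1 for regression)
    N: int = 5                  # prototypes per class
    K: int = 5                  # retained prototype responses
    epsilon: float = 1e-6       # log-ratio stabiliser
    tau: float = 0.5            # contrastive temperature
    kl_floor: float = 1e-8      # off-support probability floor in the KL
    out_dim: int = 2            # logits (classification) / 1 (regression)
    task_kind: str = "classification"   # classification|regression|multitask
    ablation: str = "none"
    seed: int = 0

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; "
                             f"choose from {ABLATIONS}")
        if self.task_kind not in ("classification", "regression", "multitask"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")


class MultimodalPrototypeModel:
    """Trainable graph+text predictor with a shared prototype space."""

    def __init__(self, config: ModelConfig,
                 provider: TextProviderContract | None = None):
        self.config = config
        self.store = ParameterStore()
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        self.provider = provider or DeterministicTextEmbedder(
            d_t=config.d_t, seed=config.seed)
        if self.provider.d_t != config.d_t:
            raise ValueError("provider d_t does not match config.d_t")

        enc_cfg = GraphEncoderConfig(L=config.L, d_g=config.d_g)
        self.graph_encoder = GINEncoder(enc_cfg, NUM_ATOM_FEATURES,
                                        self.store, rng)
        self.text_refiner = TextRefiner(config.L, config.d_t, self.store, rng)
        self.fusion = BidirectionalFusion(config.L, config.d_g, config.d_t,
                                          self.store, rng)
        proto_args = dict(C=config.C, N=config.N, d_p=config.d_p,
                          d_g=config.d_g, d_t=config.d_t,
                          epsilon=config.epsilon, K=config.K)
        if config.ablation == "no_up":
            # separate per-modality prototype learning
            self.proto_g = PrototypeSpace(store=self.store, rng=rng,
                                          name="proto_g", **proto_args)
            self.proto_t = PrototypeSpace(store=self.store, rng=rng,
                                          name="proto_t", **proto_args)
            self.proto = None
        else:
            self.proto = PrototypeSpace(store=self.store, rng=rng,
                                        name="proto", **proto_args)
            self.proto_g = self.proto_t = None
        self.heads = PredictionHeads(config.L, config.d_g, config.out_dim,
                                     self.store, rng)
        self._text_cache: dict[str, np.ndarray] = {}
        self._cluster_labels: np.ndarray | None = None

    # -- forward pieces ------------------------------------------------------

    def _pooled_text(self, record: MoleculeRecord) -> np.ndarray:
        key = record.smiles + "\x00" + " ".join(record.tokens)
        vec = self._text_cache.get(key)
        if vec is None:
            vec = embed_and_pool(record.tokens, self.provider)
            self._text_cache[key] = vec
        return vec

    def fused_forward(self, records: list[MoleculeRecord]) -> FusedEmbeddings:
        batch = GraphBatch.from_graphs([r.graph for r in records])
        z_g = self.graph_encoder.encode_batch(batch).z_g_layers
        z_t0 = np.stack([self._pooled_text(r) for r in records])
        z_t = self.text_refiner.refine(Tensor(z_t0)).z_t_layers
        return self.fusion.fuse(
            z_g, z_t, final_layer_only=self.config.ablation == "no_ca")

    def refresh_clusters(self, seed: int = 0) -> None:
        """Recompute the regression pseudo-class partition (once per epoch)."""
        if self.config.task_kind != "regression":
            return
        P = self.proto.P if self.proto is not None else self.proto_g.P
        self._cluster_labels = objectives.kmeans_partition(P.data, seed=seed)

    def _proto_loss_for(self, space: PrototypeSpace, kmeans_seed: int) -> Tensor:
        cfg = self.config
        if cfg.task_kind == "regression":
            if self._cluster_labels is None:
                self.refresh_clusters(seed=kmeans_seed)
            labels = objectives.kmeans_partition(space.P.data, seed=kmeans_seed) \
                if space is not (self.proto or self.proto_g) else \
                self._cluster_labels
            return objectives.proto_contrastive_reg(space.P, labels, cfg.tau)
        C = cfg.C if cfg.task_kind == "classification" else 2
        return objectives.proto_contrastive_cls(space.P, C, cfg.N, cfg.tau)

    # -- full loss -----------------------------------------------------------

    def loss(self, records: list[MoleculeRecord], weights: LossWeights,
             kmeans_seed: int = 0) -> tuple[LossBreakdown, dict]:
        """Forward pass and full loss over a mini-batch."""
        cfg = self.config
        fused = self.fused_forward(records)
        z_bar_g = aggregate_layers(fused.hat_z_g_layers)
        z_bar_t = aggregate_layers(fused.hat_z_t_layers)

        if cfg.ablation == "no_up":
            dist_g = self.proto_g.response(z_bar_g, "g")
            dist_t = self.proto_t.response(z_bar_t, "t")
            # different spaces by design: compare index-aligned responses
            dist_t.space_id = dist_g.space_id
        else:
            dist_g = self.proto.response(z_bar_g, "g")
            dist_t = self.proto.response(z_bar_t, "t")
        L_align = alignment_loss(dist_g, dist_t, floor=cfg.kl_floor)

        o_hat = objectives.predict(fused.hat_z_g_layers, self.heads)
        y = np.stack([r.labels for r in records])
        mask = np.stack([r.label_mask for r in records])
        if cfg.task_kind == "regression":
            L_pred = objectives.predictive_loss(o_hat, y[:, 0], "regression")
        elif cfg.task_kind == "multitask":
            L_pred = objectives.predictive_loss(o_hat, y, "multitask", mask)
        else:
            L_pred = objectives.predictive_loss(o_hat, y[:, 0],
                                                "classification", mask[:, 0])

        if cfg.ablation == "no_up":
            L_proto = (self._proto_loss_for(self.proto_g, kmeans_seed) +
                       self._proto_loss_for(self.proto_t, kmeans_seed)) * 0.5
        else:
            L_proto = self._proto_loss_for(self.proto, kmeans_seed)

        eff = LossWeights(
            lambda_align=0.0 if cfg.ablation == "no_al" else weights.lambda_align,
            lambda_pred=0.0 if cfg.ablation == "no_cl" else weights.lambda_pred,
            lambda_proto=0.0 if cfg.ablation == "no_pr" else weights.lambda_proto,
            tau=weights.tau, M=weights.M)
        breakdown = objectives.total_loss(L_align, L_pred, L_proto, eff)
        aux = {"o_hat": o_hat, "z_bar_g": z_bar_g, "z_bar_t": z_bar_t,
               "dist_g": dist_g, "dist_t": dist_t, "fused": fused}
        return breakdown, aux

    # -- inference -----------------------------------------------------------

    def predict_raw(self, records: list[MoleculeRecord]) -> np.ndarray:
        """Aggregated head outputs (logits or scalars), one row per record."""
        fused = self.fused_forward(records)
        return objectives.predict(fused.hat_z_g_layers, self.heads).data

    def predict_scores(self, records: list[MoleculeRecord]) -> np.ndarray:
        """Task-appropriate scores: positive-class / per-task probabilities
        for classification, the scalar prediction for regression."""
        raw = self.predict_raw(records)
        if self.config.task_kind == "regression":
            return raw.reshape(-1)
        if self.config.task_kind == "multitask":
            return 1.0 / (1.0 + np.exp(-raw))
        e = np.exp(raw - raw.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        return probs[:, 1] if self.config.out_dim == 2 else probs

    def embed_records(self, records: list[MoleculeRecord]) -> np.ndarray:
        """Aggregated fused graph-side embeddings z-bar_g (for export and
        cluster-separability diagnostics)."""
        fused = self.fused_forward(records)
        return aggregate_layers(fused.hat_z_g_layers).data
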