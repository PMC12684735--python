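"""Hierarchical message-passing graph encoder.

An L-layer GNN updates atom states by combining each atom's previous state
with an aggregate over its bonded neighbours, and a permutation-invariant
readout after *every* layer yields the hierarchical representation set
``Z_g = {z_g^(1), ..., z_g^(L)}`` — one graph-level vector per depth, so that
shallow layers expose local substructure and deep layers expose global
topology.

The default backbone is GIN: the combine step is
``MLP((1 + eps) * h_v + sum_{u in N(v)} h_u)`` with a learnable ``eps``
initialised at 0.  Isolated atoms receive a zero neighbour aggregate.

Mini-batches are processed as one block-diagonal graph (concatenated node
matrices plus a node->graph segment index); per-layer readouts then reduce to
segment sums/means, and the result equals single-graph evaluation up to
float-summation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mol_io import MolecularGraph
from .nn import MLP, ParameterStore, Tensor

__all__ = ["GraphEncoderConfig", "GraphBatch", "LayerwiseGraphEmbeddings",
           "GINEncoder", "readout_layer"]


@dataclass
class GraphEncoderConfig:
    L: int = 3
    d_g: int = 64
    backbone: str = "gin"
    aggregation: str = "sum"    # neighbour aggregate: sum | mean | max
    readout: str = "sum"        # graph-level readout: sum | mean | max
    gin_eps: float = 0.0        # initial value of the learnable eps

    def __post_init__(self):
        if self.L < 1 or self.d_g < 1:
            raise ValueError("L and d_g must be >= 1")
        if self.backbone != "gin":
            raise ValueError(f"unsupported backbone: {self.backbone!r}")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError(f"unsupported aggregation: {self.aggregation!r}")
        if self.readout not in ("sum", "mean"):
            raise ValueError(f"unsupported readout: {self.readout!r}")


@dataclass
class LayerwiseGraphEmbeddings:
    """Per-layer graph-level vectors; rows are graphs when batched."""

    z_g_layers: list[Tensor]    # L tensors, each (B, d_g) or (d_g,)

    def __post_init__(self):
        if not self.z_g_layers:
            raise ValueError("need at least one layer embedding")
        for z in self.z_g_layers:
            if not np.all(np.isfinite(z.data)):
                raise ValueError("non-finite graph embedding")

    @property
    def L(self) -> int:
        return len(self.z_g_layers)


@dataclass
class GraphBatch:
    """A set of molecular graphs packed into one block-diagonal graph."""

    X: np.ndarray               # (n_nodes_total, d) raw atom features
    edge_src: np.ndarray        # directed edges, both orientations
    edge_dst: np.ndarray
    node_graph: np.ndarray      # (n_nodes_total,) graph id per node
    n_graphs: int
    node_counts: np.ndarray = field(default=None)

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty batch")
        xs, srcs, dsts, gids = [], [], [], []
        offset = 0
        for gid, g in enumerate(graphs):
            if g.n_atoms == 0:
                raise ValueError("cannot encode an empty graph (no atoms)")
            xs.append(g.features)
            for i, j, _ in g.bonds:
                srcs.extend((offset + i, offset + j))
                dsts.extend((offset + j, offset + i))
            gids.extend([gid] * g.n_atoms)
            offset += g.n_atoms
        return cls(
            X=np.vstack(xs),
            edge_src=np.asarray(srcs, dtype=np.intp),
            edge_dst=np.asarray(dsts, dtype=np.intp),
            node_graph=np.asarray(gids, dtype=np.intp),
            n_graphs=len(graphs),
            node_counts=np.asarray([g.n_atoms for g in graphs]),
        )


def readout_layer(states: Tensor, mode: str = "sum",
                  node_graph: np.ndarray | None = None,
                  n_graphs: int = 1) -> Tensor:
    """Permutation-invariant pooling of node states into graph vectors."""
    if states.shape[0] == 0:
        raise ValueError("readout of an empty node set")
    if node_graph is None:
        node_graph = np.zeros(states.shape[0], dtype=np.intp)
    pooled = states.segment_sum(node_graph, n_graphs)
    if mode == "mean":
        counts = np.bincount(node_graph, minlength=n_graphs).astype(float)
        pooled = pooled / Tensor(counts[:, None])
    return pooled


class GINEncoder:
    """GIN backbone with an input MLP and per-layer readout."""

    def __init__(self, config: GraphEncoderConfig, d_in: int,
                 store: ParameterStore, rng: np.random.Generator,
                 name: str = "graph"):
        self.config = config
        self.store = store
        self.input_mlp = MLP(store, f"{name}.input_mlp", d_in,
                             config.d_g, config.d_g, rng)
        self.layer_mlps = [
            MLP(store, f"{name}.layer{l}.mlp", config.d_g, config.d_g,
                config.d_g, rng)
            for l in range(config.L)
        ]
        self.eps = [
            store.add(f"{name}.layer{l}.eps", np.array(config.gin_eps))
            for l in range(config.L)
        ]

    # -- single-graph surface ------------------------------------------------

    def init_node_embed(self, X: np.ndarray) -> Tensor:
        """h^(0) = MLP(x_v), one row per atom."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] == 0:
            raise ValueError("cannot embed an empty graph (no atoms)")
        return self.input_mlp(Tensor(X))

    def message_pass_layer(self, states: Tensor, batch: GraphBatch,
                           layer: int) -> Tensor:
        """One GIN update on the (possibly block-diagonal) graph."""
        if not np.all(np.isfinite(states.data)):
            raise ValueError("non-finite node states")
        msgs = states.gather_rows(batch.edge_src)
        agg = msgs.segment_sum(batch.edge_dst, states.shape[0])
        if self.config.aggregation == "mean":
            deg = np.bincount(batch.edge_dst,
                              minlength=states.shape[0]).astype(float)
            agg = agg / Tensor(np.maximum(deg, 1.0)[:, None])
        combined = states * (self.eps[layer] + 1.0) + agg
        return self.layer_mlps[layer](combined)

    def encode_batch(self, batch: GraphBatch) -> LayerwiseGraphEmbeddings:
        states = self.init_node_embed(batch.X)
        layers: list[Tensor] = []
        for l in range(self.config.L):
            states = self.message_pass_layer(states, batch, l)
            layers.append(readout_layer(states, self.config.readout,
                                        batch.node_graph, batch.n_graphs))
        return LayerwiseGraphEmbeddings(z_g_layers=layers)

    def encode_graph(self, graph: MolecularGraph) -> LayerwiseGraphEmbeddings:
        """Encode one molecule; returns L vectors of width d_g."""
        batch = GraphBatch.from_graphs([graph])
        out = self.encode_batch(batch)
        return LayerwiseGraphEmbeddings(
            z_g_layers=[z.reshape(self.config.d_g) for z in out.z_g_layers])
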