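"""Text branch: pluggable token embedding, mean pooling, and an L-layer
transformer refinement of the pooled description vector.

Token embedding is delegated to a provider satisfying
:class:`TextProviderContract` — in production that would be a pretrained
language model; the default shipped provider maps each token to a fixed
pseudo-random unit-norm vector derived from a seeded hash of the token
string, so the whole branch is deterministic and needs no downloads.

Mean pooling over token embeddings gives the initial summary vector
``z_t^(0)``; an L-layer transformer then refines it, treating the pooled
vector as a length-1 sequence (self-attention over a single position reduces
to its value path, since the softmax over one key is identically 1).  Each
refinement depth l contributes one vector to ``Z_t = {z_t^(1), ..., z_t^(L)}``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .nn import LayerNorm, Linear, ParameterStore, Tensor

__all__ = ["TokenEmbeddingSequence", "LayerwiseTextEmbeddings",
           "TextProviderContract", "DeterministicTextEmbedder",
           "embed_and_pool", "TextRefiner"]


@dataclass
class TokenEmbeddingSequence:
    vectors: np.ndarray         # (n_tokens, d_t)
    provider_id: str
    provider_version: str

    def __post_init__(self):
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ValueError("need at least one token embedding")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite token embedding")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def d_t(self) -> int:
        return self.vectors.shape[1]


@dataclass
class LayerwiseTextEmbeddings:
    z_t_layers: list[Tensor]    # L tensors, (B, d_t) or (d_t,)
    z_t_0: Tensor               # pooled initial vector(s)

    @property
    def L(self) -> int:
        return len(self.z_t_layers)


@runtime_checkable
class TextProviderContract(Protocol):
    """Anything that can embed a token sequence at a fixed dimensionality."""

    d_t: int
    deterministic: bool
    provider_id: str

    def embed(self, tokens: list[str]) -> TokenEmbeddingSequence: ...


class DeterministicTextEmbedder:
    """Hash-seeded, context-independent token embedder.

    Each token string is hashed together with the vocabulary seed
    (blake2b, stable across processes), the digest seeds a PCG64 generator,
    and a standard-normal draw is normalised to unit Euclidean length.
    Identical (seed, token) pairs therefore always give identical vectors.
    """

    provider_id = "deterministic-hash"
    provider_version = "1"
    deterministic = True

    def __init__(self, d_t: int = 64, seed: int = 0):
        if d_t < 1:
            raise ValueError("d_t must be >= 1")
        self.d_t = d_t
        self.seed = int(seed)
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(f"{self.seed}\x00{token}".encode(),
                                     digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            raw = rng.standard_normal(self.d_t)
            vec = raw / np.linalg.norm(raw)
            self._cache[token] = vec
        return vec

    def embed(self, tokens: list[str]) -> TokenEmbeddingSequence:
        if not tokens:
            raise ValueError("cannot embed an empty token sequence")
        vectors = np.stack([self._token_vector(t) for t in tokens])
        return TokenEmbeddingSequence(vectors=vectors,
                                      provider_id=self.provider_id,
                                      provider_version=self.provider_version)


def embed_and_pool(tokens: list[str],
                   provider: TextProviderContract) -> np.ndarray:
    """z_t^(0): mean of the provider's token embeddings."""
    seq = provider.embed(tokens)
    if seq.d_t != provider.d_t:
        raise ValueError(f"provider dimensionality contract violated: "
                         f"declared {provider.d_t}, emitted {seq.d_t}")
    return seq.vectors.mean(axis=0)


class _TransformerLayer:
    """Pre-norm block: self-attention then a two-layer feed-forward, each
    with a residual connection.

    On a length-1 sequence the attention softmax has a single key, so its
    weight is exactly 1 and the attention output is the value projection of
    the normalised input (query/key projections receive zero gradient and
    are omitted); multi-head splitting of a single position is likewise a
    no-op, so the value/output projections act at full width.
    """

    def __init__(self, store: ParameterStore, name: str, d_t: int,
                 rng: np.random.Generator, ffn_mult: int = 2):
        self.ln_attn = LayerNorm(store, f"{name}.ln_attn", d_t)
        self.w_v = Linear(store, f"{name}.w_v", d_t, d_t, rng)
        self.w_o = Linear(store, f"{name}.w_o", d_t, d_t, rng)
        self.ln_ffn = LayerNorm(store, f"{name}.ln_ffn", d_t)
        self.ffn1 = Linear(store, f"{name}.ffn1", d_t, ffn_mult * d_t, rng)
        self.ffn2 = Linear(store, f"{name}.ffn2", ffn_mult * d_t, d_t, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.w_o(self.w_v(self.ln_attn(x)))
        return x + self.ffn2(self.ffn1(self.ln_ffn(x)).relu())


class TextRefiner:
    """L-layer transformer producing the layer-wise text representations."""

    def __init__(self, L: int, d_t: int, store: ParameterStore,
                 rng: np.random.Generator, name: str = "text"):
        if L < 1:
            raise ValueError("L must be >= 1")
        self.L = L
        self.d_t = d_t
        self.layers = [_TransformerLayer(store, f"{name}.layer{l}", d_t, rng)
                       for l in range(L)]

    def refine(self, z_t_0: Tensor | np.ndarray) -> LayerwiseTextEmbeddings:
        x = z_t_0 if isinstance(z_t_0, Tensor) else Tensor(z_t_0)
        layers: list[Tensor] = []
        for layer in self.layers:
            x = layer(x)
            layers.append(x)
        z0 = z_t_0 if isinstance(z_t_0, Tensor) else Tensor(z_t_0)
        return LayerwiseTextEmbeddings(z_t_layers=layers, z_t_0=z0)
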