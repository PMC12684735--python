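# Methods

This note documents the modelling assumptions, defaults, numerical choices
and known limitations of `molproto`. Notation follows the README: a record
is a pair `(G, t)` of a heavy-atom molecular graph and a token sequence;
`L` is the shared encoder depth; `d_g`, `d_t`, `d_p` are the graph, text and
prototype dimensionalities; `C` is the number of prototype classes and `N`
the prototypes per class.

## Model

**Graph branch.** Atoms are featurised as one-hot element (fixed 100-symbol
vocabulary, positions = atomic number order), one-hot degree (0–6), one-hot
formal charge (−2…+2) and an aromaticity flag — 113 raw dimensions, the
standard MoleculeNet-style scheme. An input MLP lifts raw features to
`d_g`; each of the `L` GIN layers applies
`MLP((1+ε)·h_v + Σ_{u∈N(v)} h_u)` with a learnable `ε` initialised at 0.
Bond order tags are retained in the graph container but the GIN update
aggregates node states only. Isolated atoms receive a zero neighbour
aggregate. A readout (sum by default; mean available) after every layer
produces the hierarchical set `Z_g`. Mini-batches are packed as one
block-diagonal graph; batched results equal single-graph evaluation up to
float-summation order (tested at 1e−6).

**Text branch.** Token embedding is behind a provider contract
(`embed(tokens) → n×d_t`, a declared dimensionality, and a determinism
flag), so a pretrained language model can be plugged in. The shipped
default is a deterministic hash embedder: token string + vocabulary seed →
blake2b digest → seeded PCG64 → unit-norm Gaussian vector. It is
context-independent by construction; it models lexical identity, not
semantics. Mean pooling gives `z_t^(0)`; `L` pre-norm transformer layers
(value/output projections + a 2-layer ReLU FFN, residuals) refine it as a
length-1 sequence. On a single position the attention softmax has one key,
so its weight is identically 1, query/key projections receive zero gradient,
and multi-head splitting is a no-op — the layer's attention sub-block
reduces to its value path. We implement that reduced form directly.

**Fusion.** At each depth, `W_{g→t}^(l)` (no bias, variance-scaled uniform
init) projects the graph vector into text space and vice versa; each
modality cross-attends to the projected counterpart with the projected
vector as both key and value, scaled by `1/√d_g` in both directions as the
model family writes it (the scale is inert with a single key); a residual
adds the attended vector back. Because the key set is a singleton, fusion is
exactly `ẑ_t = z_t + W_{g→t} z_g` (and symmetrically) — this degeneracy is
deliberate: the equations type the attention as vector→vector, and we follow
them literally. A set-level (per-node / per-token) attention mode was
considered and not shipped: it would require per-token differentiable text
states that the pooled-vector refinement does not produce, and a
half-working flag is worse than a documented absence.

**Prototype space.** A learnable `C·N × d_p` tensor (i.i.d. normal scaled by
`1/√d_p`), flattened class-major; modality-specific affine projections map
the depth-averaged fused representations into it. Squared Euclidean
distances are converted by the log-ratio `s = log((D+1)/(D+ε))` — strictly
decreasing in `D`, bounded by `log(1/ε)` — then sparsified to the top-`K`
scores (ties broken toward the lowest flat index, for determinism) and
softmax-normalised *over the retained raw scores only*, so gradients flow
through exactly `K` entries.

**Alignment KL.** The two modalities' top-K supports can differ, and a KL
between two K-vectors with different supports is ill-defined
coordinate-wise. We therefore evaluate `KL(α_g ‖ α_t)` on full-length `C·N`
vectors: off-support entries get a probability floor `ε_kl = 1e−8` and each
vector is renormalised. An alternative restricted to the support
intersection is available (`support="intersection"`). A consequence worth
knowing: when the supports are fully disjoint, the gradient through the
text-side distribution is O(ε_kl) — alignment pressure then comes almost
entirely from the graph side until the supports overlap.

**Objectives.** Prediction uses only graph-side fused vectors: one linear
head per depth, outputs averaged. Classification uses softmax
cross-entropy; regression squared error; multi-task binary panels use
per-task BCE-with-logits restricted to observed labels (the missing-label
mask comes straight from empty CSV cells). The prototype contrastive loss
treats each prototype as an anchor; positives are same-class prototypes
(numerator averaged over the `N−1` positives), the denominator is the
unrestricted double sum including the anchor's self-similarity term, `sim`
is cosine. For regression (`C = 1`) pseudo-classes come from a 2-means
partition (Lloyd, 10 restarts, ≤100 iterations, seeded), recomputed once
per epoch — per-step refreshes add cost and churn without changing the
geometry materially. Anchors in a singleton cluster have no positives and
are skipped with a warning. Total loss:
`λ_align·L_align + λ_pred·L_pred + λ_proto·L_proto`.

## Defaults and why

| Parameter | Default | Rationale |
| --- | --- | --- |
| `λ_align, λ_pred, λ_proto` | 0.9 each | the published default for this model family |
| `N`, `K` | 5, 5 | the published sensitivity-analysis optimum |
| `ε` (log-ratio) | 1e−6 | "small constant"; value unspecified upstream, configurable |
| `ε_kl` | 1e−8 | below any softmax mass of interest, keeps the KL finite |
| `τ` (temperature) | 0.5 | unspecified upstream; mid-range InfoNCE value, configurable |
| `d_g = d_t = d_p` | 64 | unspecified upstream; desk-scale width |
| `L` | 3 | shared between branches — the layer-wise fusion pairs layers one-to-one |
| optimiser | Adam, lr 8e−5, wd 1e−4, cosine, 100 epochs, batch 128 | the published recipe (`configs/paper.yml`) |
| desk scale | lr 3e−3, batch 32, 20 epochs | ~200 optimiser steps on a few-hundred-record set; the published lr cannot move a fresh network in 80 steps |
| model selection | best validation metric epoch, strict improvement (ties keep the earliest) | selection rule unspecified upstream; the standard convention |
| multi-run seeds | 0–4 | per-run seed policy unspecified upstream; documented convention |

Classification labels are 0-based internally ({0…C−1}); atom indices are
0-based except in error messages (1-based, matching how SMILES positions
are read).

## Synthetic data

The generator emulates the *shape* of small-molecule benchmark panels:
graphs average 13.3 heavy atoms (matching the printed average of a typical
aqueous-solubility benchmark; s.d. 3, floor at the motif size), single
bonds, carbon skeletons with 10% N and 10% O substitutions, always valid
and emitted as SMILES so the full parse/featurise path runs. Class 0 plants
a five-membered carbon ring, class 1 a five-carbon chain (kept acyclic), so
the structural signal is exactly "contains a ring" — learnable by a GIN and
verifiable by a ring-count oracle. Labels flip independently with the
configured noise rate; the planted motif always follows the structural
class. Texts are class templates plus random distractor tokens. Regression
plants 0–3 ring motifs and sets `y = α·count + N(0, σ²)` with `α = 1.0`,
`σ = 0.1` (high signal-to-noise by design, so recovery failures indicate
model defects, not an unlearnable task).

What passing these tests does **not** show: real datasets have correlated
label noise, scaffold structure, aromatic heterocycles, charged species and
semantic (not lexical) text; the deterministic embedder cannot capture
paraphrase, and a trivially separable motif task cannot expose the value of
alignment regularisation (see limitations).

## Numerical choices

- Everything is float64, single-threaded numpy; fixed seeds give
  bitwise-identical runs, and checkpoints (npz archive + JSON manifest)
  restore bit-identical predictions.
- Softmax/log-softmax subtract a detached row max; BCE-with-logits uses the
  `max(o,0) − o·y + log(1+exp(−|o|))` form.
- Top-K uses a stable argsort on negated scores, so equal scores keep
  ascending-index order.
- Training aborts with epoch/batch context when any loss or intermediate
  state becomes non-finite.
- Gradient checks: central differences at `eps = 1e−5` resolve nothing
  below ~1e−10; comparison scales are floored at 1e−6 so gradients that are
  negligible to both methods compare as equal (this arises genuinely when
  top-K supports are disjoint, see above).
- Degenerate inputs: empty graphs, empty token sequences, all-identical
  prototypes (2-means), both-singleton clusters, single-class evaluation
  sets (ROC-AUC reported as missing, never 0) all raise or report
  explicitly.

## Limitations

- Singleton attention means the fusion is linear in each modality given the
  other; the hierarchical aspect (per-layer pairing) carries the
  expressiveness.
- The desk-scale motif task saturates: scores concentrate near 0/1, and a
  40-molecule test split resolves AUC only to ~0.003. Ablations with small
  true effects (removing the alignment loss in particular) tie the full
  model at this resolution even though their parameter trajectories differ;
  distinguishing them needs larger evaluation sets or harder tasks than the
  desk conditions provide.
- Multi-task panels share a single `C = 2` prototype space across tasks — a
  surrogate, since the upstream design does not say how `C` scales with
  hundreds of endpoints.
- How real textual descriptions should be produced from SMILES is not
  specified upstream; the tokenized-SMILES fallback and the template texts
  are this package's surrogates.
- No 3D conformers, scaffold splits, edge-feature message passing,
  multi-head fusion, or pretrained-LLM weights (the provider contract is the
  extension point).
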