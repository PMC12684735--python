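# molproto

Prototype-guided multimodal molecular property prediction: a library and CLI
that jointly model a molecule's **graph structure** and a **textual
description** of it, and align the two modalities in a shared, learnable
prototype space.

## Who this is for

Practitioners exploring multimodal molecular representation learning —
toxicity, bioactivity, solubility and similar endpoints — who want a small,
fully inspectable implementation of hierarchical graph/text fusion with
prototype-level alignment, trainable on a laptop CPU. The package ships a
synthetic molecule/text generator emulating MoleculeNet-style dataset shapes
so every stage can be exercised without downloads.

## The model

Each record is a pair `(G, t)`: a heavy-atom molecular graph
`G = (V, E, X)` parsed from SMILES, and a token sequence `t`.

1. **Graph branch** — an `L`-layer GIN updates atom states
   `h_v^(l) = MLP((1+ε)·h_v^(l-1) + Σ_{u∈N(v)} h_u^(l-1))` and a sum readout
   after *every* layer yields `Z_g = {z_g^(1), …, z_g^(L)}`.
2. **Text branch** — a pluggable provider embeds tokens (`e_i = f_text(t_i)`;
   the default provider is a deterministic seeded-hash embedder), mean
   pooling gives `z_t^(0)`, and an `L`-layer transformer refines it into
   `Z_t = {z_t^(1), …, z_t^(L)}`.
3. **Layer-wise bidirectional fusion** — at each depth, learnable maps
   project each modality into the other's space and scaled dot-product
   cross-attention (the projected vector is both key and value) is added
   through a residual: `ẑ_t^(l) = z_t^(l) + W_{g→t}^(l) z_g^(l)` and
   symmetrically for the graph side (with one key the attention weight is
   exactly 1).
4. **Prototype space** — fused layers are mean-pooled over depth, projected
   into a space of `C×N` learnable prototypes, scored by squared Euclidean
   distance, mapped through the log-ratio `s = log((D+1)/(D+ε))`,
   sparsified to the top-`K` responses and softmax-normalised. Training
   minimises
   `L = λ_align·KL(α_g‖α_t) + λ_pred·L_pred + λ_proto·L_proto`,
   where `L_pred` is cross-entropy / MSE from per-layer linear heads on the
   fused graph vectors, and `L_proto` is an InfoNCE-style contrastive loss
   over prototype anchors (2-means pseudo-classes for regression).

There is no PyTorch dependency: the model runs on a small reverse-mode
autodiff core (`molproto.nn`) over numpy, with Adam and cosine annealing.
Gradient paths are verified against finite differences in the test suite.

## Worked example

```bash
molproto generate-synthetic --n 400 --task cls --noise 0.05 --seed 1 --out data.csv
molproto train --data data.csv --config configs/desk.yml --seed 1 \
    --checkpoint model.ckpt --log train.jsonl
```

Training logs one JSON object per epoch; the first and last lines of
`train.jsonl` from this exact command:

```json
{"epoch": 1, "lr": 0.003, "L_align": 7.039684158761401, "L_pred": 5.170506118606854, "L_proto": 2.54435354661063, "L_total": 13.279089441580998, "val_metric": 0.9824999999999999}
{"epoch": 20, "lr": 0.0, "L_align": 1.7142315390942515e-06, "L_pred": 0.1496730395350842, "L_proto": 1.6462978932181298, "L_total": 1.6163753822862788, "val_metric": 0.8725}
```

and the final summary line on stdout:

```json
{"best_epoch": 1, "test": {"n": 40, "roc_auc": [0.9674999999999999], "roc_auc_macro": 0.9674999999999999, "rmse": null, "davies_bouldin": 0.8659500536291049}}
```

Reading this: the three loss components all fall over the 20 desk-scale
epochs (`L_align` → 2e-6 means the two modalities end up activating the same
prototypes); the checkpoint keeps the best-validation epoch (here epoch 1 —
the task saturates immediately and later epochs overfit the prototype
geometry slightly); held-out ROC-AUC is 0.967 on the 40-molecule test
split — close to the ceiling this label-noise rate allows — and the
Davies–Bouldin index of the fused graph embeddings grouped by label is 0.87
(lower = tighter, better-separated classes). `molproto evaluate` re-scores a saved checkpoint and
`molproto export-embeddings` writes the fused embeddings as TSV.

The same pipeline is available as a library:

```python
from molproto import SyntheticSpec, generate_dataset, TrainConfig, train_model, evaluate

records = generate_dataset(SyntheticSpec(n_records=400, label_noise=0.05, seed=1))
checkpoint, history = train_model(records, TrainConfig.from_yaml("configs/desk.yml", seed=1))
```

## Layout

| Path | Contents |
| --- | --- |
| `src/molproto/mol_io.py` | SMILES → featurised graphs, CSV/SDF loading, stratified splits |
| `src/molproto/graph_encoder.py` | GIN with per-layer readout |
| `src/molproto/text_encoder.py` | provider contract, pooling, transformer refiner |
| `src/molproto/fusion.py` | layer-wise bidirectional cross-modal attention |
| `src/molproto/prototypes.py` | prototype space, top-K distributions, KL alignment |
| `src/molproto/objectives.py` | heads, supervised + contrastive losses |
| `src/molproto/pipeline.py` | training loop, metrics, checkpoints |
| `src/molproto/synthetic.py` | motif-planted synthetic datasets |
| `src/molproto/nn/` | reverse-mode autodiff core, layers, Adam |
| `configs/` | `desk.yml` (CPU-scale) and `paper.yml` (full-scale) |
| `docs/methods.md` | modelling assumptions, defaults, limitations |
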