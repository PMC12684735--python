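"""Training and evaluation pipeline.

Optimisation follows the standard recipe for this model family: Adam
(learning rate 8e-5, weight decay 1e-4), cosine-annealed learning rate, 100
epochs, batch size 128.  Desk-scale work uses ``configs/desk.yml`` (3 layers,
64-dimensional embeddings, 20 epochs, a correspondingly larger learning
rate); ``configs/paper.yml`` keeps the full-scale defaults.

Model selection keeps the epoch with the best validation metric (macro
ROC-AUC for classification, RMSE for regression); with no usable validation
metric the final epoch is kept.  Runs are deterministic under a fixed seed,
and a saved checkpoint restores bit-identical predictions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import yaml
from sklearn.metrics import davies_bouldin_score, roc_auc_score

from .mol_io import DatasetSplit, MoleculeRecord, stratified_split
from .model import ModelConfig, MultimodalPrototypeModel
from .nn import Adam, cosine_annealing
from .objectives import LossWeights
from .text_encoder import TextProviderContract

__all__ = ["TrainConfig", "MetricReport", "Checkpoint", "train_model",
           "evaluate", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    learning_rate: float = 8e-5
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 128
    schedule: str = "cosine"
    seed: int = 0
    device: str = "cpu"
    lambda_align: float = 0.9
    lambda_pred: float = 0.9
    lambda_proto: float = 0.9
    tau: float = 0.5
    N: int = 5
    K: int = 5
    L: int = 3
    d_g: int = 64
    d_t: int = 64
    d_p: int = 64
    epsilon: float = 1e-6
    kl_floor: float = 1e-8
    ablation: str = "none"
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self):
        for name in ("learning_rate", "epochs", "batch_size", "tau", "N", "K",
                     "L", "d_g", "d_t", "d_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "ratios" in data:
            data["ratios"] = tuple(data["ratios"])
        return cls(**data)

    def loss_weights(self) -> LossWeights:
        return LossWeights(lambda_align=self.lambda_align,
                           lambda_pred=self.lambda_pred,
                           lambda_proto=self.lambda_proto, tau=self.tau)


@dataclass
class MetricReport:
    n: int = 0
    roc_auc: list[float | None] = field(default_factory=list)  # per task
    roc_auc_macro: float | None = None
    rmse: float | None = None
    davies_bouldin: float | None = None

    def primary(self, task_kind: str) -> float | None:
        return self.rmse if task_kind == "regression" else self.roc_auc_macro


@dataclass
class Checkpoint:
    model_config: ModelConfig
    train_config: TrainConfig
    state: dict[str, np.ndarray]
    best_epoch: int
    provider_id: str
    provider_seed: int

    def build_model(self,
                    provider: TextProviderContract | None = None
                    ) -> MultimodalPrototypeModel:
        model = MultimodalPrototypeModel(self.model_config, provider)
        model.store.load_state_dict(self.state)
        return model


def _infer_task(records: list[MoleculeRecord]) -> tuple[str, int, int]:
    """Return (task_kind, prototype classes C, head output width)."""
    first = records[0]
    n_tasks = first.labels.shape[0]
    if first.task_kind == "regression":
        return "regression", 1, 1
    if n_tasks > 1:
        return "multitask", 2, n_tasks
    n_classes = int(max(r.labels[0] for r in records)) + 1
    return "classification", max(n_classes, 2), max(n_classes, 2)


def _batches(indices: np.ndarray, batch_size: int):
    for start in range(0, len(indices), batch_size):
        yield indices[start:start + batch_size]


def train_model(records: list[MoleculeRecord], config: TrainConfig,
                split: DatasetSplit | None = None,
                provider: TextProviderContract | None = None,
                log_fn: Callable[[dict], None] | None = None
                ) -> tuple[Checkpoint, list[dict]]:
    """Train on the records' train split; returns a checkpoint (best
    validation epoch) and the per-epoch history."""
    if not records:
        raise ValueError("no records to train on")
    if split is None:
        split = stratified_split(records, config.ratios, seed=config.seed)
    if not split.train:
        raise ValueError("empty train split")
    task_kind, C, out_dim = _infer_task(records)

    model_cfg = ModelConfig(
        L=config.L, d_g=config.d_g, d_t=config.d_t, d_p=config.d_p,
        C=C, N=config.N, K=min(config.K, C * config.N),
        epsilon=config.epsilon, tau=config.tau, kl_floor=config.kl_floor,
        out_dim=out_dim, task_kind=task_kind, ablation=config.ablation,
        seed=config.seed)
    model = MultimodalPrototypeModel(model_cfg, provider)
    optimizer = Adam(model.store, lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    weights = config.loss_weights()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))

    train_recs = [records[i] for i in split.train]
    val_recs = [records[i] for i in split.validation]
    history: list[dict] = []
    best_metric: float | None = None
    best_state = model.store.state_dict()
    best_epoch = 0
    minimise = task_kind == "regression"

    for epoch in range(config.epochs):
        lr = config.learning_rate if config.schedule == "constant" else \
            cosine_annealing(config.learning_rate, epoch, config.epochs)
        model.refresh_clusters(seed=config.seed)
        order = rng.permutation(len(train_recs))
        epoch_loss = np.zeros(4)
        n_seen = 0
        for b, batch_idx in enumerate(_batches(order, config.batch_size)):
            batch = [train_recs[i] for i in batch_idx]
            model.store.zero_grad()
            try:
                breakdown, _ = model.loss(batch, weights,
                                          kmeans_seed=config.seed)
            except ValueError as err:
                if "non-finite" in str(err):
                    raise RuntimeError(
                        f"training diverged: {err} at epoch {epoch + 1}, "
                        f"batch {b + 1}") from err
                raise
            if not np.isfinite(breakdown.L_total):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch "
                    f"{epoch + 1}, batch {b + 1}")
            breakdown.total.backward()
            optimizer.step(lr=lr)
            w = len(batch)
            epoch_loss += w * np.array([breakdown.L_align, breakdown.L_pred,
                                        breakdown.L_proto, breakdown.L_total])
            n_seen += w
        epoch_loss /= n_seen

        val_report = evaluate(model, val_recs) if val_recs else MetricReport()
        val_metric = val_report.primary(task_kind)
        entry = {
            "epoch": epoch + 1, "lr": lr,
            "L_align": float(epoch_loss[0]), "L_pred": float(epoch_loss[1]),
            "L_proto": float(epoch_loss[2]), "L_total": float(epoch_loss[3]),
            "val_metric": val_metric,
        }
        history.append(entry)
        if log_fn is not None:
            log_fn(entry)
        # strict improvement: ties keep the earliest best epoch
        if val_metric is not None and (
                best_metric is None or
                (val_metric < best_metric if minimise
                 else val_metric > best_metric)):
            best_metric = val_metric
            best_state = model.store.state_dict()
            best_epoch = epoch + 1
    if best_metric is None:     # no usable validation metric: keep last
        best_state = model.store.state_dict()
        best_epoch = config.epochs

    provider_seed = getattr(model.provider, "seed", config.seed)
    checkpoint = Checkpoint(model_config=model_cfg, train_config=config,
                            state=best_state, best_epoch=best_epoch,
                            provider_id=model.provider.provider_id,
                            provider_seed=provider_seed)
    return checkpoint, history


def evaluate(model: MultimodalPrototypeModel | Checkpoint,
             records: list[MoleculeRecord],
             batch_size: int = 256) -> MetricReport:
    """Held-out metrics: per-task ROC-AUC with macro average (classification;
    a single-class task reports None, not 0), RMSE (regression), and the
    Davies-Bouldin index of the fused graph embeddings grouped by label."""
    if isinstance(model, Checkpoint):
        model = model.build_model()
    report = MetricReport(n=len(records))
    if not records:
        return report
    scores = []
    embeds = []
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        scores.append(np.atleast_1d(model.predict_scores(chunk)))
        embeds.append(model.embed_records(chunk))
    scores = np.concatenate(scores)
    embeds = np.vstack(embeds)
    task = model.config.task_kind

    if task == "regression":
        y = np.array([r.y for r in records])
        report.rmse = float(np.sqrt(np.mean((y - scores) ** 2)))
        return report

    labels = np.stack([r.labels for r in records])
    masks = np.stack([r.label_mask for r in records])
    if task == "multitask":
        per_task = []
        for t in range(labels.shape[1]):
            obs = masks[:, t]
            y_t = labels[obs, t]
            if len(np.unique(y_t)) < 2:
                per_task.append(None)
                continue
            per_task.append(float(roc_auc_score(y_t, scores[obs, t])))
        report.roc_auc = per_task
        seen = [a for a in per_task if a is not None]
        report.roc_auc_macro = float(np.mean(seen)) if seen else None
        return report

    y = labels[:, 0].astype(int)
    if len(np.unique(y)) < 2:
        report.roc_auc = [None]
        return report
    if model.config.out_dim == 2:
        auc = float(roc_auc_score(y, scores))
    else:
        auc = float(roc_auc_score(y, scores, multi_class="ovr"))
    report.roc_auc = [auc]
    report.roc_auc_macro = auc
    report.davies_bouldin = float(davies_bouldin_score(embeds, y))
    return report


# -- checkpoint serialisation -------------------------------------------------

def save_checkpoint(checkpoint: Checkpoint, path) -> None:
    """Single-archive checkpoint: parameter arrays plus a JSON manifest of
    configs, shapes and seeds."""
    path = Path(path)
    manifest = {
        "model_config": asdict(checkpoint.model_config),
        "train_config": asdict(checkpoint.train_config),
        "best_epoch": checkpoint.best_epoch,
        "provider_id": checkpoint.provider_id,
        "provider_seed": checkpoint.provider_seed,
        "shapes": {k: list(v.shape) for k, v in checkpoint.state.items()},
    }
    arrays = {f"param/{k}": v for k, v in checkpoint.state.items()}
    np.savez(path, __manifest__=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Checkpoint:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    tc = manifest["train_config"]
    tc["ratios"] = tuple(tc["ratios"])
    return Checkpoint(
        model_config=ModelConfig(**manifest["model_config"]),
        train_config=TrainConfig(**tc),
        state=state,
        best_epoch=manifest["best_epoch"],
        provider_id=manifest["provider_id"],
        provider_seed=manifest["provider_seed"],
    )
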