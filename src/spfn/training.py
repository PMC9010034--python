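"""Dataset splitting, the AdaGrad training loop, and cross-validation.

The protocol: pairs are shuffled once (seeded), split 4:1 into train and
validation, and the split is rotated five times so every pair is validated
exactly once. Training minimizes the SSIM + weight-L1 objective with
AdaGrad (per-parameter accumulated squared gradients), Xavier-initialized
weights, whole slices as samples.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .losses import SSIMConfig, fusion_loss_tensor
from .metrics import HistogramConfig, MetricReport, evaluate_pair
from .model import ModelConfig, ModelParams, fuse, fuse_tensor, init_parameters
from .preprocessing import ImagePair

__all__ = [
    "TrainConfig",
    "TrainRecord",
    "split_dataset",
    "train",
    "run_cross_validation",
    "AdaGrad",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 4
    lam: float = 1e-4  # weight of the L1 regularizer
    seed: int = 0
    n_folds: int = 5  # 4:1 split rotated this many times
    ssim_mode: str = "global"
    adagrad_eps: float = 1e-8

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @property
    def ssim_config(self) -> SSIMConfig:
        return SSIMConfig(mode=self.ssim_mode)


@dataclass(frozen=True)
class TrainRecord:
    epoch: int
    step: int
    total: float
    ssim_ct: float
    ssim_pet: float
    l1_term: float
    timestamp: float = field(default_factory=time.time)


class AdaGrad:
    """Per-parameter adaptive gradient descent: G += g^2; w -= lr * g / (sqrt(G) + eps).

    The accumulator starts at 0.1 (the TensorFlow 1.x convention) rather
    than 0, which damps the first updates and avoids saturating the output
    sigmoid before any structure has been learned.
    """

    def __init__(
        self,
        params: ModelParams,
        learning_rate: float = 0.01,
        eps: float = 1e-8,
        initial_accumulator: float = 0.1,
    ):
        self.params = params
        self.lr = learning_rate
        self.eps = eps
        self.accum = {
            k: np.full_like(t.data, initial_accumulator) for k, t in params.items()
        }

    def step(self) -> None:
        for name, t in self.params.items():
            if t.grad is None:
                continue
            acc = self.accum[name]
            acc += t.grad**2
            t.data -= self.lr * t.grad / (np.sqrt(acc) + self.eps)

    def zero_grad(self) -> None:
        self.params.zero_grad()


def split_dataset(pairs: list, cfg: TrainConfig = TrainConfig()) -> list[tuple[list, list]]:
    """Rotated 4:1 folds: shuffle once, cut into n_folds chunks, each fold
    validates one chunk and trains on the rest. Validation chunks are
    pairwise disjoint and jointly cover the dataset."""
    n = len(pairs)
    if n < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} pairs, got {n}")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    bounds = [(i * n) // cfg.n_folds for i in range(cfg.n_folds + 1)]
    folds = []
    for f in range(cfg.n_folds):
        val_idx = set(order[bounds[f] : bounds[f + 1]].tolist())
        val = [pairs[i] for i in sorted(val_idx)]
        tr = [pairs[i] for i in range(n) if i not in val_idx]
        folds.append((tr, val))
    return folds


def train(
    dataset: list[ImagePair],
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    params: ModelParams | None = None,
) -> tuple[ModelParams, list[TrainRecord]]:
    """Minimize the fusion objective over the dataset; returns the final
    parameters and the per-batch loss trace."""
    if not dataset:
        raise ValueError("training requires a non-empty dataset")
    if params is None:
        params = init_parameters(model_cfg, train_cfg.seed)
    opt = AdaGrad(params, train_cfg.learning_rate, train_cfg.adagrad_eps)
    ssim_cfg = train_cfg.ssim_config
    rng = np.random.default_rng(train_cfg.seed + 1)
    records: list[TrainRecord] = []
    step = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(dataset))
        for start in range(0, len(dataset), train_cfg.batch_size):
            batch = [dataset[i] for i in order[start : start + train_cfg.batch_size]]
            opt.zero_grad()
            totals = []
            parts_acc = {"ssim_ct": 0.0, "ssim_pet": 0.0, "l1_term": 0.0}
            for pair in batch:
                fused = fuse_tensor(pair, params, model_cfg)
                total, parts = fusion_loss_tensor(
                    pair.ct, pair.pet, fused, params, train_cfg.lam, ssim_cfg
                )
                scaled = total * (1.0 / len(batch))
                scaled.backward()
                totals.append(float(total.data))
                for k in parts_acc:
                    parts_acc[k] += parts[k] / len(batch)
            batch_loss = float(np.mean(totals))
            if not np.isfinite(batch_loss):
                ids = [p.identifier for p in batch]
                raise FloatingPointError(
                    f"non-finite loss {batch_loss} at epoch {epoch}, step {step}, batch {ids}"
                )
            opt.step()
            step += 1
            records.append(
                TrainRecord(
                    epoch=epoch,
                    step=step,
                    total=batch_loss,
                    ssim_ct=parts_acc["ssim_ct"],
                    ssim_pet=parts_acc["ssim_pet"],
                    l1_term=parts_acc["l1_term"],
                )
            )
    return params, records


def run_cross_validation(
    dataset: list[ImagePair],
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    hist_cfg: HistogramConfig = HistogramConfig(),
) -> list[dict]:
    """Train on each rotated fold and evaluate the seven metrics on its
    validation pairs; returns one {metric: (mean, std)} summary per fold."""
    folds = split_dataset(dataset, train_cfg)
    summaries = []
    for k, (tr, val) in enumerate(folds):
        params, _ = train(tr, model_cfg, train_cfg)
        reports: list[MetricReport] = []
        for pair in val:
            fused = fuse(pair, params, model_cfg)
            reports.append(evaluate_pair(pair, fused, hist_cfg))
        summary = {"fold": k, "n_train": len(tr), "n_val": len(val)}
        for name in ("mean", "std", "avg_gradient", "entropy", "rmse", "nmi", "vif"):
            vals = np.array([getattr(r, name) for r in reports])
            summary[name] = (float(vals.mean()), float(vals.std()))
        summaries.append(summary)
    return summaries
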