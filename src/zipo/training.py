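"""Training loop: Adam, warm-down learning-rate schedule, plateau reduction,
early stopping.

The learning rate starts high (default 0.0212 — large library sizes need large
initial steps) and decays geometrically by 0.9 per epoch until it reaches the
target rate of 0.001 around epoch 30. After the warm-down, the rate is halved
whenever the validation loss fails to improve by at least 0.1% (relative) for
15 consecutive epochs. Training stops early once the validation loss has not
improved for 30 epochs; the parameters from the best validation epoch are
restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .data import CountMatrix, CovariateTable, PreprocessSpec, preprocess
from .exceptions import ValidationError
from .losses import LossBreakdown, total_loss, total_loss_t
from .model import (
    CellDistribution,
    ZiPoNetwork,
    load_checkpoint,
    save_checkpoint,
)

__all__ = ["TrainConfig", "TrainResult", "Adam", "lr_at_epoch", "train", "impute"]


@dataclass
class TrainConfig:
    """Optimization settings (see module docstring for the schedule)."""

    lr_initial: float = 0.0212
    lr_target: float = 0.001
    lr_decay: float = 0.9
    plateau_patience_epochs: int = 15
    plateau_min_improvement: float = 0.001  # relative, i.e. 0.1%
    plateau_factor: float = 0.5
    early_stop_epochs: int = 30
    batch_size: int = 128
    validation_fraction: float = 0.1
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lr_target < self.lr_initial):
            raise ValidationError("require 0 < lr_target < lr_initial")
        if not (0 < self.lr_decay < 1):
            raise ValidationError("lr_decay must lie in (0, 1)")
        if self.plateau_patience_epochs < 1 or self.early_stop_epochs < 1:
            raise ValidationError("patience values must be >= 1")
        if not (0 < self.validation_fraction < 1):
            raise ValidationError("validation_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValidationError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainResult:
    best_validation_loss: float
    epochs_run: int
    history: list  # per-epoch dicts: train/validation LossBreakdowns + lr
    checkpoint_path: Optional[Path] = None


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Warm-down schedule: geometric decay from ``lr_initial`` clamped at
    ``lr_target`` (plateau reductions apply on top, later)."""
    if epoch < 1:
        raise ValidationError("epoch numbering starts at 1")
    return max(cfg.lr_target, cfg.lr_initial * cfg.lr_decay ** (epoch - 1))


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _resolve_inputs(X, covariates, preprocess_spec):
    if isinstance(X, CountMatrix):
        counts = X.values
    else:
        counts = np.asarray(X)
    if preprocess_spec is not None:
        cm = X if isinstance(X, CountMatrix) else CountMatrix(
            counts,
            [f"cell{i}" for i in range(counts.shape[0])],
            [f"gene{j}" for j in range(counts.shape[1])],
        )
        inputs = preprocess(cm, preprocess_spec)
    else:
        inputs = counts.astype(np.float64)
    cov = None
    if covariates is not None:
        cov = (
            covariates.values
            if isinstance(covariates, CovariateTable)
            else np.asarray(covariates, dtype=np.float64)
        )
        if cov.shape[0] != counts.shape[0]:
            raise ValidationError("covariate row count does not match cells")
    return counts, inputs, cov


def _evaluate(model, counts, inputs, cov, batch_size) -> LossBreakdown:
    _, dist = model.predict(inputs, cov, batch_size=batch_size)
    return total_loss(counts, dist, model.first_layer_weights(), model.spec)


def train(
    model: ZiPoNetwork,
    X,
    covariates=None,
    cfg: TrainConfig | None = None,
    preprocess_spec: PreprocessSpec | None = None,
    log_path=None,
    checkpoint_path=None,
) -> TrainResult:
    """Optimize ``model`` on counts ``X`` (CountMatrix or integer array).

    The likelihood is always evaluated against the raw counts; ``preprocess_spec``
    only shapes the encoder input. Cells are split into train/validation by a
    seeded permutation and everything downstream is deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    counts, inputs, cov = _resolve_inputs(X, covariates, preprocess_spec)
    n = counts.shape[0]
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    if n_val >= n:
        raise ValidationError("validation split leaves no training cells")
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    opt = Adam(model.parameters())
    W = model.first_layer_weight_tensor()
    history = []
    best_val = np.inf
    best_state = None
    epochs_since_best = 0
    plateau_ref = np.inf
    plateau_counter = 0
    plateau_scale = 1.0
    epochs_run = 0

    for epoch in range(1, cfg.max_epochs + 1):
        base_lr = lr_at_epoch(epoch, cfg)
        warm_down_done = base_lr <= cfg.lr_target
        lr = base_lr * (plateau_scale if warm_down_done else 1.0)

        order = train_idx[rng.permutation(len(train_idx))]
        batch_bds = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            _, _, out = model.forward_tensors(
                inputs[idx], None if cov is None else cov[idx], training=True
            )
            loss, bd = total_loss_t(counts[idx], out, W, model.spec)
            loss.backward()
            opt.step(lr)
            batch_bds.append((len(idx), bd))

        w_total = sum(nb for nb, _ in batch_bds)
        train_bd = LossBreakdown(
            *[
                sum(nb * getattr(bd, f) for nb, bd in batch_bds) / w_total
                for f in ("nll", "zero_penalty", "weight_penalty", "theta_penalty",
                          "rate_penalty")
            ]
        )
        val_bd = _evaluate(
            model, counts[val_idx], inputs[val_idx],
            None if cov is None else cov[val_idx], cfg.batch_size,
        )
        val_bd.validate()
        history.append({"epoch": epoch, "train": train_bd, "validation": val_bd,
                        "lr": lr})
        epochs_run = epoch

        val_total = val_bd.total
        if val_total < best_val:
            best_val = val_total
            best_state = [a.copy() for a in model.state_arrays()]
            epochs_since_best = 0
        else:
            epochs_since_best += 1

        if warm_down_done:
            if plateau_ref == np.inf or (
                (plateau_ref - val_total) / abs(plateau_ref)
                >= cfg.plateau_min_improvement
            ):
                plateau_ref = val_total
                plateau_counter = 0
            else:
                plateau_counter += 1
                if plateau_counter >= cfg.plateau_patience_epochs:
                    plateau_scale *= cfg.plateau_factor
                    plateau_counter = 0

        if epochs_since_best >= cfg.early_stop_epochs:
            break

    if best_state is not None:
        for target, saved in zip(model.state_arrays(), best_state):
            target[...] = saved

    if log_path is not None:
        _write_log(log_path, history)
    ckpt = None
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path,
                        extra={"best_validation_loss": best_val})
        ckpt = Path(checkpoint_path)
    return TrainResult(float(best_val), epochs_run, history, ckpt)


def _write_log(path, history) -> None:
    cols = ["epoch", "nll", "zero_penalty", "weight_penalty", "theta_penalty",
            "rate_penalty", "total", "lr"]
    lines = ["\t".join(cols)]
    for rec in history:
        bd = rec["validation"]
        vals = [rec["epoch"], bd.nll, bd.zero_penalty, bd.weight_penalty,
                bd.theta_penalty, bd.rate_penalty, bd.total, rec["lr"]]
        lines.append("\t".join(f"{v:.10g}" if isinstance(v, float) else str(v)
                               for v in vals))
    Path(path).write_text("\n".join(lines) + "\n")


def impute(
    model_or_checkpoint,
    X,
    covariates=None,
    preprocess_spec: PreprocessSpec | None = None,
    batch_size: int = 256,
) -> CellDistribution:
    """Evaluation-mode forward pass over all cells, batched.

    Accepts a live network or a checkpoint path; results are independent of the
    batch size because batch norm runs on its tracked statistics.
    """
    model = (
        model_or_checkpoint
        if isinstance(model_or_checkpoint, ZiPoNetwork)
        else load_checkpoint(model_or_checkpoint)
    )
    counts, inputs, cov = _resolve_inputs(X, covariates, preprocess_spec)
    if counts.shape[1] != model.spec.n_genes:
        raise ValidationError(
            f"data has {counts.shape[1]} genes, model expects {model.spec.n_genes}"
        )
    _, dist = model.predict(inputs, cov, batch_size=batch_size)
    return dist
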