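"""Optimization of the classifier: AdamW, mini-batches, early stopping.

The protocol: categorical cross-entropy over the two diagnostic classes,
AdamW (beta1 0.9, beta2 0.999, eps 1e-8, initial learning rate 1e-3, no
schedule), batch size 16, and early stopping on the validation loss with
patience 3 — training stops after `patience` consecutive epochs without
strict improvement (absolute tolerance 1e-6) and the best snapshot, not the
last, is returned. Everything is seeded: parameter initialization, batch
shuffling and dropout draw from independent streams derived from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .data_io import build_sequences
from .model import IGnet, ModelConfig, get_state, set_state


def cross_entropy_loss(scores, labels) -> float:
    """Mean -log p(true class), computed stably from raw scores."""
    loss, _ = nn.softmax_cross_entropy(scores, labels)
    return loss


@dataclass
class OptimizerConfig:
    method: str = "adamw"
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 16

    def __post_init__(self):
        if not (0.0 < self.beta1 < 1.0 and 0.0 < self.beta2 < 1.0):
            raise ValueError("betas must be in (0, 1)")
        if self.epsilon <= 0 or self.batch_size < 1:
            raise ValueError("invalid epsilon or batch size")
        if self.method != "adamw":
            raise ValueError("only adamw is supported")


class AdamW:
    """Decoupled weight decay Adam; decay applies to matrices only."""

    def __init__(self, model: nn.Module, config: OptimizerConfig) -> None:
        self.model = model
        self.config = config
        self.t = 0
        self.m = {name: np.zeros_like(v) for name, v, _ in model.named_parameters()}
        self.v = {name: np.zeros_like(v) for name, v, _ in model.named_parameters()}

    def step(self) -> None:
        c = self.config
        self.t += 1
        b1c = 1.0 - c.beta1 ** self.t
        b2c = 1.0 - c.beta2 ** self.t
        for name, value, grad in self.model.named_parameters():
            m, v = self.m[name], self.v[name]
            m *= c.beta1
            m += (1.0 - c.beta1) * grad
            v *= c.beta2
            v += (1.0 - c.beta2) * grad * grad
            update = (m / b1c) / (np.sqrt(v / b2c) + c.epsilon)
            if value.ndim >= 2:
                update = update + c.weight_decay * value
            value -= c.learning_rate * update


class EarlyStopping:
    """Patience counter on a monitored loss; strict improvement, tol 1e-6."""

    def __init__(self, patience: int = 3, min_delta: float = 1e-6) -> None:
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self.since_improvement = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record one epoch's loss; True if it improved on the best so far."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = epoch
            self.since_improvement = 0
            return True
        self.since_improvement += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.since_improvement >= self.patience


@dataclass
class TrainState:
    epoch: int
    train_loss_history: list
    val_loss_history: list
    best_val_loss: float
    best_epoch: int
    epochs_since_improvement: int
    patience: int
    max_epochs: int
    rng_seed: int
    stopped_early: bool

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, self.epoch + 1),
                             "train_loss": self.train_loss_history,
                             "val_loss": self.val_loss_history})


@dataclass
class TrainingData:
    """Arrays the optimizer consumes, aligned on subject order."""

    subject_ids: list
    labels: np.ndarray
    volumes: np.ndarray | None = None     # (N, D, H, W) in [0, 1]
    tokens: np.ndarray | None = None      # (N, seq_len) in {0, 1, 2}
    apoe_position: int | None = None

    @classmethod
    def from_cohort(cls, cohort, panel=None) -> "TrainingData":
        """Build from an assembled or simulated cohort (+ SNP panel)."""
        volumes = np.asarray(cohort.volumes)
        if np.issubdtype(volumes.dtype, np.integer):
            volumes = volumes.astype(np.float32) / 255.0
        tokens = apoe_position = None
        if panel is not None:
            tokens = build_sequences(cohort, panel)
            apoe_position = panel.apoe_position
        return cls(subject_ids=list(cohort.subject_ids),
                   labels=np.asarray(cohort.labels).astype(int),
                   volumes=volumes,
                   tokens=tokens,
                   apoe_position=apoe_position)

    def subset(self, idx) -> dict:
        return {
            "volumes": None if self.volumes is None else self.volumes[idx],
            "tokens": None if self.tokens is None else self.tokens[idx],
            "labels": self.labels[idx],
        }


def _partition_indices(data: TrainingData, split: pd.Series) -> dict:
    sid_to_pos = {sid: i for i, sid in enumerate(data.subject_ids)}
    out = {}
    for part in ("train", "val", "test"):
        ids = split.index[split == part]
        out[part] = np.array([sid_to_pos[s] for s in ids if s in sid_to_pos],
                             dtype=int)
    return out


def _batch_scores(model: IGnet, data: TrainingData, idx, batch_size=32):
    """Eval-mode raw scores over the given subject indices."""
    scores = []
    for lo in range(0, len(idx), batch_size):
        sub = data.subset(idx[lo:lo + batch_size])
        _, s = model.forward(volumes=sub["volumes"], tokens=sub["tokens"],
                             apoe_position=data.apoe_position,
                             train=False, return_scores=True)
        scores.append(s)
    return np.concatenate(scores)


def train(data: TrainingData, split: pd.Series, model_config: ModelConfig,
          opt_config: OptimizerConfig | None = None, patience: int = 3,
          max_epochs: int = 100, seed: int = 0,
          init_seed: int | None = None,
          monitor: str = "val_loss") -> tuple[IGnet, TrainState]:
    """Optimize a model variant; returns the best-validation snapshot.

    `seed` drives batch shuffling and dropout; `init_seed` (default: same
    value) drives parameter initialization. Two runs with identical seeds on
    identical data produce identical loss histories.

    `monitor` selects the quantity that early stopping and snapshot
    selection track: `"val_loss"` (default) or `"val_auc"` (minimizes the
    negated validation AUC-ROC; useful when the reported endpoint is a
    ranking metric rather than calibrated probabilities). The returned
    state's `best_val_loss` holds the best *monitored* value.
    """
    if monitor not in ("val_loss", "val_auc"):
        raise ValueError("monitor must be 'val_loss' or 'val_auc'")
    opt_config = opt_config or OptimizerConfig()
    parts = _partition_indices(data, split)
    if len(parts["train"]) == 0 or len(parts["val"]) == 0:
        raise ValueError("train and val partitions must be non-empty")

    model = IGnet(model_config, init_seed=seed if init_seed is None else init_seed)
    optimizer = AdamW(model, opt_config)
    shuffle_rng = np.random.default_rng([seed, 1])
    dropout_rng = np.random.default_rng([seed, 2])
    stopper = EarlyStopping(patience=patience)
    best_state = get_state(model)
    train_hist, val_hist = [], []
    stopped_early = False
    epoch = 0

    for epoch in range(1, max_epochs + 1):
        order = shuffle_rng.permutation(parts["train"])
        losses, sizes = [], []
        for lo in range(0, len(order), opt_config.batch_size):
            sub = data.subset(order[lo:lo + opt_config.batch_size])
            _, scores = model.forward(
                volumes=sub["volumes"], tokens=sub["tokens"],
                apoe_position=data.apoe_position,
                train=True, rng=dropout_rng, return_scores=True)
            loss, dscores = nn.softmax_cross_entropy(scores, sub["labels"])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            model.zero_grad()
            model.backward_from_scores(dscores)
            optimizer.step()
            losses.append(loss)
            sizes.append(len(sub["labels"]))
        train_hist.append(float(np.average(losses, weights=sizes)))

        val_scores = _batch_scores(model, data, parts["val"])
        val_labels = data.labels[parts["val"]]
        val_loss = cross_entropy_loss(val_scores, val_labels)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        val_hist.append(float(val_loss))
        if monitor == "val_auc":
            from sklearn.metrics import roc_auc_score
            monitored = -float(roc_auc_score(val_labels, val_scores[:, 1]
                                             - val_scores[:, 0]))
        else:
            monitored = val_loss
        if stopper.update(monitored, epoch):
            best_state = get_state(model)
        if stopper.should_stop:
            stopped_early = True
            break

    set_state(model, best_state)
    state = TrainState(epoch=epoch,
                       train_loss_history=train_hist,
                       val_loss_history=val_hist,
                       best_val_loss=float(stopper.best),
                       best_epoch=stopper.best_epoch,
                       epochs_since_improvement=stopper.since_improvement,
                       patience=patience,
                       max_epochs=max_epochs,
                       rng_seed=seed,
                       stopped_early=stopped_early)
    return model, state


def predict(model: IGnet, data: TrainingData, idx=None,
            batch_size: int = 32) -> pd.DataFrame:
    """Per-subject AD probabilities: columns subject_id, p_ad, label."""
    if idx is None:
        idx = np.arange(len(data.subject_ids))
    idx = np.asarray(idx)
    scores = _batch_scores(model, data, idx, batch_size)
    probs = nn.softmax(scores)
    return pd.DataFrame({
        "subject_id": [data.subject_ids[i] for i in idx],
        "p_ad": probs[:, 1],
        "label": data.labels[idx],
    })
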