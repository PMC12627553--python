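"""Training protocol for the tile detector.

The protocol mirrors common practice for long-term monitoring detectors:
a random 80/20 train/validation split, Z-score standardization with
statistics fitted on the training split only, inverse-frequency class
weights, and an epoch-level checkpointing rule — a model is saved when
validation sensitivity reaches at least 0.8 with a false-positive rate
below 0.01, later saves must further lower the false-positive rate, and
training stops after 15 epochs without a save (patience) or at the epoch
budget.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._nn import clip_global_norm, sigmoid, weighted_bce_with_logits
from .detector_net import Network
from .inference_review import threshold_scores
from .presence_metrics import confusion_summary


@dataclass(frozen=True)
class TrainConfig:
    train_fraction: float = 0.8
    save_min_sensitivity: float = 0.8
    save_max_fp_rate: float = 0.01
    patience: int = 15
    max_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_schedule: str = "constant"   # constant | cosine (decay to lr/10)
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not (0 <= self.save_min_sensitivity <= 1
                and 0 <= self.save_max_fp_rate <= 1):
            raise ValueError("save thresholds must lie in [0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")


@dataclass(frozen=True)
class NormStats:
    """Global mean/sd of training-split tile values (scalar Z-score)."""

    mean: float
    sd: float

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean, "sd": self.sd})

    @classmethod
    def from_json(cls, text: str) -> "NormStats":
        return cls(**json.loads(text))


@dataclass
class TrainHistory:
    records: List[dict] = field(default_factory=list)
    best_epoch: Optional[int] = None
    stop_epoch: Optional[int] = None
    met_criteria: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["epoch", "train_loss",
                                     "val_sensitivity", "val_fp_rate", "saved"])


def split_dataset(manifest: pd.DataFrame, train_fraction: float = 0.8,
                  seed: int = 0) -> Tuple[List[str], List[str]]:
    """Disjoint, exhaustive random split of manifest clip ids.

    The training split takes floor(n * train_fraction) ids of a uniform
    seed-determined permutation; the split is not class-stratified (class
    weights absorb imbalance downstream).  Warns when the validation split
    misses a class, since sensitivity or false-positive rate is then
    undefined.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    ids = manifest["clip_id"].to_numpy()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(len(ids) * train_fraction))
    train_ids = list(ids[perm[:n_train]])
    val_ids = list(ids[perm[n_train:]])
    if "label" in manifest.columns and val_ids:
        val_labels = manifest.set_index("clip_id").loc[val_ids, "label"]
        if val_labels.nunique() < 2:
            warnings.warn("validation split contains a single class; "
                          "validation metrics will be undefined", stacklevel=2)
    return train_ids, val_ids


def fit_norm_stats(train_tiles: np.ndarray) -> NormStats:
    """Scalar Z-score statistics over all training tile values."""
    values = np.asarray(train_tiles)
    mean = float(values.mean())
    sd = float(values.std())
    if sd == 0:
        raise ValueError("training tiles are constant-valued: "
                         "Z-score standardization is undefined (sd = 0)")
    return NormStats(mean=mean, sd=sd)


def apply_norm(tiles: np.ndarray, stats: NormStats) -> np.ndarray:
    """Standardize with training-split statistics (never refitted here)."""
    return ((np.asarray(tiles, dtype=np.float32) - np.float32(stats.mean))
            / np.float32(stats.sd))


def class_weights(labels: Sequence[int]) -> Dict[int, float]:
    """Balanced inverse-frequency weights w_c = N / (2 * N_c)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("class weights need both classes present")
    n = labels.size
    return {int(c): n / (2 * cnt) for c, cnt in zip(classes, counts)}


class SaveProtocol:
    """Epoch-level save rule with patience counted since the last save.

    An epoch's model is saved when sensitivity >= min_sensitivity and
    fp_rate < max_fp_rate and the fp rate strictly improves on the
    incumbent; training stops once ``patience`` consecutive epochs pass
    without a save.
    """

    def __init__(self, min_sensitivity: float = 0.8,
                 max_fp_rate: float = 0.01, patience: int = 15):
        self.min_sensitivity = min_sensitivity
        self.max_fp_rate = max_fp_rate
        self.patience = patience
        self.best_fp: Optional[float] = None
        self.best_epoch: Optional[int] = None
        self.epochs_since_save = 0

    def update(self, epoch: int, sensitivity: Optional[float],
               fp_rate: Optional[float]) -> Tuple[bool, bool]:
        """Returns (saved_this_epoch, stop_now)."""
        meets = (sensitivity is not None and fp_rate is not None
                 and sensitivity >= self.min_sensitivity
                 and fp_rate < self.max_fp_rate)
        improves = self.best_fp is None or fp_rate < self.best_fp
        saved = bool(meets and improves)
        if saved:
            self.best_fp = fp_rate
            self.best_epoch = epoch
            self.epochs_since_save = 0
        else:
            self.epochs_since_save += 1
        return saved, self.epochs_since_save >= self.patience


def _score_standardized(network: Network, tiles: np.ndarray,
                        batch_size: int) -> np.ndarray:
    probs = np.empty(tiles.shape[0], dtype=np.float64)
    for i in range(0, tiles.shape[0], batch_size):
        logits = network.forward_logits(tiles[i:i + batch_size], training=False)
        probs[i:i + batch_size] = sigmoid(logits)
    return probs


def evaluate_detector(network: Network, tiles: np.ndarray,
                      labels: np.ndarray, batch_size: int = 16
                      ) -> Tuple[Optional[float], Optional[float]]:
    """File-level (sensitivity, fp_rate) of a network on standardized tiles."""
    probs = _score_standardized(network, np.asarray(tiles, dtype=np.float32),
                                batch_size)
    preds = threshold_scores(probs)
    summary = confusion_summary(preds, np.asarray(labels), level="file")
    return summary.sensitivity, summary.fp_rate


def train_detector(network: Network,
                   train_tiles: np.ndarray, train_labels: np.ndarray,
                   val_tiles: np.ndarray, val_labels: np.ndarray,
                   config: TrainConfig,
                   verbose: bool = False) -> Tuple[Network, TrainHistory]:
    """Run the training protocol; inputs must already be standardized.

    Optimises class-weighted binary cross-entropy with Adam; validates at
    file level each epoch and applies the save/patience rule.  Returns the
    network loaded with the incumbent best weights (or the final weights
    with ``history.met_criteria`` False when no epoch met the criteria).
    """
    train_tiles = np.asarray(train_tiles, dtype=np.float32)
    val_tiles = np.asarray(val_tiles, dtype=np.float32)
    train_labels = np.asarray(train_labels).astype(np.float32)
    val_labels = np.asarray(val_labels).astype(int)
    if val_tiles.shape[0] == 0:
        raise ValueError("empty validation set")
    weights = class_weights(train_labels.astype(int))
    sample_w = np.where(train_labels > 0.5, weights[1], weights[0]).astype(np.float32)

    rng = np.random.default_rng(config.seed)
    optimizer = network.make_optimizer(config.learning_rate)
    protocol = SaveProtocol(config.save_min_sensitivity,
                            config.save_max_fp_rate, config.patience)
    history = TrainHistory()
    best_weights = None
    n = train_tiles.shape[0]

    for epoch in range(1, config.max_epochs + 1):
        if config.lr_schedule == "cosine":
            frac = (epoch - 1) / max(config.max_epochs - 1, 1)
            optimizer.lr = config.learning_rate * (
                0.1 + 0.45 * (1 + np.cos(np.pi * frac)))
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = network.forward_logits(train_tiles[idx], training=True,
                                            rng=rng)
            loss, dlogits = weighted_bce_with_logits(
                logits, train_labels[idx], sample_w[idx])
            network.backward(dlogits)
            grads = network.gradients()
            if config.grad_clip:
                grads = clip_global_norm(grads, config.grad_clip)
            optimizer.step(grads)
            losses.append(loss)
        sens, fp = evaluate_detector(network, val_tiles, val_labels,
                                     batch_size=config.batch_size)
        saved, stop = protocol.update(epoch, sens, fp)
        if saved:
            best_weights = network.get_weights()
        history.records.append({"epoch": epoch,
                                "train_loss": float(np.mean(losses)),
                                "val_sensitivity": sens,
                                "val_fp_rate": fp,
                                "saved": saved})
        if verbose:
            print(f"epoch {epoch}: loss={np.mean(losses):.4f} "
                  f"sens={sens} fp={fp} saved={saved}")
        if stop:
            history.stop_epoch = epoch
            break
    if history.stop_epoch is None:
        history.stop_epoch = history.records[-1]["epoch"] if history.records else 0
    history.best_epoch = protocol.best_epoch
    history.met_criteria = best_weights is not None
    if best_weights is not None:
        network.set_weights(best_weights)
    return network, history
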