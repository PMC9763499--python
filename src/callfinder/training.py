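"""Network training: Adam, plateau learning-rate decay, early stopping.

The schedule follows plateau semantics on validation accuracy: an epoch
"improves" only by strictly exceeding the best accuracy seen so far; after
``lr_patience_epochs`` stale epochs the learning rate halves (and the decay
counter resets); after ``early_stop_patience_epochs`` stale epochs training
stops.  The weights of the best validation epoch are restored before the
trained network is returned.

Training clips are re-preprocessed every epoch with augmentation and random
cropping (when enabled); validation and test clips are preprocessed once,
centered and unaugmented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .audio import Waveform, read_wav
from .config import PreprocessingConfig
from .dataset import ClipRecord, DatasetSplit
from .model import ResNetClassifier, predict_proba
from .preprocessing import preprocess_clip

__all__ = ["TrainingConfig", "TrainingHistory", "PlateauSchedule", "train",
           "evaluate_split", "split_metrics"]


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 8
    learning_rate: float = 1e-5
    beta1: float = 0.5
    beta2: float = 0.999
    lr_decay_factor: float = 0.5
    lr_patience_epochs: int = 4
    early_stop_patience_epochs: int = 10
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.lr_patience_epochs, self.early_stop_patience_epochs,
               self.max_epochs) <= 0:
            raise ValueError("batch size, patiences and max_epochs must be positive")
        if self.learning_rate <= 0 or not (0 < self.lr_decay_factor <= 1):
            raise ValueError("invalid learning rate or decay factor")
        for b in (self.beta1, self.beta2):
            if not 0 < b < 1:
                raise ValueError("Adam betas must lie in (0, 1)")


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    train_accuracy: List[float] = field(default_factory=list)
    validation_accuracy: List[float] = field(default_factory=list)
    learning_rate: List[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class PlateauSchedule:
    """Plateau bookkeeping for LR decay and early stopping.

    Improvement means a strict increase of validation accuracy over the best
    seen so far; ties count as stale.  Both counters reset on improvement;
    the decay counter additionally resets whenever a decay fires.
    """

    def __init__(self, initial_lr: float, decay_factor: float,
                 lr_patience: int, stop_patience: int) -> None:
        self.lr = initial_lr
        self.decay_factor = decay_factor
        self.lr_patience = lr_patience
        self.stop_patience = stop_patience
        self.best = -math.inf
        self._stale = 0
        self._decay_stale = 0

    def update(self, val_metric: float) -> Tuple[bool, bool]:
        """Register one epoch's validation metric; returns (improved, stop)."""
        if val_metric > self.best:
            self.best = val_metric
            self._stale = 0
            self._decay_stale = 0
            return True, False
        self._stale += 1
        self._decay_stale += 1
        if self._decay_stale >= self.lr_patience:
            self.lr *= self.decay_factor
            self._decay_stale = 0
        return False, self._stale >= self.stop_patience


def _load_waveform(record: ClipRecord) -> Waveform:
    return read_wav(record.path)


def _encode_labels(records: Sequence[ClipRecord], class_names: Sequence[str]) -> np.ndarray:
    index = {name: i for i, name in enumerate(class_names)}
    try:
        return np.array([index[r.label] for r in records], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"label {exc} not among classes {list(class_names)}") from None


def _preprocess_set(
    records: Sequence[ClipRecord],
    pcfg: PreprocessingConfig,
    noise_pool: Optional[Sequence[Waveform]],
    rng: Optional[np.random.Generator],
) -> np.ndarray:
    clips = [
        preprocess_clip(_load_waveform(r), pcfg, noise_pool=noise_pool, rng=rng).values
        for r in records
    ]
    return np.stack(clips).astype(nn.DTYPE)


def train(
    network: ResNetClassifier,
    splits: DatasetSplit,
    pcfg: PreprocessingConfig,
    tcfg: TrainingConfig,
    class_names: Optional[Sequence[str]] = None,
    noise_pool: Optional[Sequence[Waveform]] = None,
    verbose: bool = False,
) -> Tuple[ResNetClassifier, TrainingHistory]:
    """Fit the classifier on the train split, monitoring validation accuracy."""
    if not splits.train or not splits.validation:
        raise ValueError("train and validation splits must be non-empty")
    if class_names is None:
        class_names = sorted({r.label for r in splits.train})
    if len(class_names) != network.spec.n_classes:
        raise ValueError("number of classes does not match the network head")

    rng = np.random.default_rng(tcfg.seed)
    y_train = _encode_labels(splits.train, class_names)
    y_val = _encode_labels(splits.validation, class_names)

    eval_pcfg = pcfg.replace(augment=False)
    x_val = _preprocess_set(splits.validation, eval_pcfg, None, None)
    x_train_static = None
    if not pcfg.augment:
        x_train_static = _preprocess_set(splits.train, eval_pcfg, None, None)

    optimizer = nn.Adam(network.parameters(), lr=tcfg.learning_rate,
                        beta1=tcfg.beta1, beta2=tcfg.beta2)
    history = TrainingHistory()
    schedule = PlateauSchedule(tcfg.learning_rate, tcfg.lr_decay_factor,
                               tcfg.lr_patience_epochs, tcfg.early_stop_patience_epochs)
    best_state = network.copy_state()

    for epoch in range(tcfg.max_epochs):
        if pcfg.augment:
            x_train = _preprocess_set(splits.train, pcfg, noise_pool, rng)
        else:
            x_train = x_train_static
        order = rng.permutation(len(splits.train))
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            logits = network.forward(x_train[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, y_train[idx])
            network.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == y_train[idx]).sum())

        val_probs = predict_proba(network, x_val)
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        history.train_loss.append(epoch_loss / len(order))
        history.train_accuracy.append(epoch_correct / len(order))
        history.validation_accuracy.append(val_acc)
        history.learning_rate.append(optimizer.lr)
        if verbose:  # pragma: no cover - console side effect
            print(f"epoch {epoch + 1:3d}  loss {history.train_loss[-1]:.4f}  "
                  f"train acc {history.train_accuracy[-1]:.3f}  val acc {val_acc:.3f}  "
                  f"lr {optimizer.lr:.2e}")

        improved, stop = schedule.update(val_acc)
        optimizer.lr = schedule.lr
        if improved:
            best_state = network.copy_state()
            history.best_epoch = epoch
        if stop:
            break

    network.load_state(best_state)
    return network, history


def split_metrics(
    y_true: np.ndarray,
    probs: np.ndarray,
    positive_index: int = 1,
) -> Dict[str, Optional[float]]:
    """ACC/TPR/FPR/PREC/F1/AUC from labels and per-class probabilities.

    For binary tasks the positive class is ``positive_index``.  AUC uses the
    rank statistic over the positive-class probability and is ``None`` when
    the ground truth contains a single class.
    """
    y_true = np.asarray(y_true)
    y_pred = probs.argmax(axis=1)
    acc = float((y_pred == y_true).mean())
    if probs.shape[1] != 2:
        return {"ACC": acc, "TPR": None, "FPR": None, "PREC": None, "F1": None, "AUC": None}
    pos, neg = positive_index, 1 - positive_index
    tp = int(np.sum((y_pred == pos) & (y_true == pos)))
    fp = int(np.sum((y_pred == pos) & (y_true == neg)))
    fn = int(np.sum((y_pred == neg) & (y_true == pos)))
    tn = int(np.sum((y_pred == neg) & (y_true == neg)))
    tpr = tp / (tp + fn) if tp + fn else None
    fpr = fp / (fp + tn) if fp + tn else None
    prec = tp / (tp + fp) if tp + fp else None
    f1 = (2 * prec * tpr / (prec + tpr)) if prec and tpr and (prec + tpr) else (
        0.0 if prec is not None and tpr is not None else None
    )
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score((y_true == pos).astype(int), probs[:, pos]))
    else:
        auc = None
    return {"ACC": acc, "TPR": tpr, "FPR": fpr, "PREC": prec, "F1": f1, "AUC": auc}


def evaluate_split(
    network: ResNetClassifier,
    records: Sequence[ClipRecord],
    pcfg: PreprocessingConfig,
    class_names: Sequence[str],
    positive_class: Optional[str] = None,
) -> Dict[str, Optional[float]]:
    """Evaluate a labeled clip set with centered, unaugmented preprocessing."""
    if not records:
        raise ValueError("cannot evaluate an empty split")
    eval_pcfg = pcfg.replace(augment=False)
    x = _preprocess_set(records, eval_pcfg, None, None)
    y = _encode_labels(records, class_names)
    probs = predict_proba(network, x)
    if positive_class is not None:
        positive_index = list(class_names).index(positive_class)
    else:
        positive_index = 1 if len(class_names) == 2 else 0
    return split_metrics(y, probs, positive_index=positive_index)
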