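"""Split construction, full-batch training and the gated early-stopping rule.

Two evaluation regimes are supported, matching the study design of the
height-fear dataset:

* **subject-independent** (``si``) — leave-one-subject-out cross-
  validation: each fold validates on all 120 windows of one held-out
  subject and trains on everybody else's windows (1560 for 14 subjects);
  learning rate 0.1.
* **subject-dependent** (``sd``) — per subject: train on the windows of
  the first six recorded trials (three fear, three non-fear; 72 windows),
  validate on the remaining four (48 windows); learning rate 0.005.

Training is full-batch: one Adam step per epoch on the entire training
set, cross-entropy on softmaxed class scores. Early stopping fires after
``patience`` epochs without a new best validation loss, but only once
training accuracy has reached the 75% gate (guards against stopping on a
by-chance-small validation loss before the model has learned anything).
Each (fold, model) pair is repeated across seeds that control only the
weight initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DataError, TrainingError
from .preprocess import WindowSet

DEFAULT_SEEDS = tuple(range(10))
SD_TRAIN_TRIALS = 6


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fold:
    """One cross-validation fold over flattened window indices."""

    name: str
    train_idx: np.ndarray
    val_idx: np.ndarray


@dataclass(frozen=True)
class SplitPlan:
    mode: str  # "si" | "sd"
    folds: tuple


def loso_splits(windows: WindowSet) -> SplitPlan:
    """Leave-one-subject-out folds: validation = one subject's windows."""
    s = len(windows.subjects)
    if s < 2:
        raise ContractError("leave-one-subject-out needs at least 2 subjects")
    _, _, subj_idx, _ = windows.flat()
    folds = []
    for i, subj in enumerate(windows.subjects):
        val = np.nonzero(subj_idx == i)[0]
        train = np.nonzero(subj_idx != i)[0]
        folds.append(Fold(str(subj), train, val))
    return SplitPlan("si", tuple(folds))


def subject_dependent_splits(windows: WindowSet) -> SplitPlan:
    """Per-subject folds: first six trials train, last four validate."""
    _, _, subj_idx, trial_idx = windows.flat()
    n_trials = windows.labels.shape[1]
    folds = []
    for i, subj in enumerate(windows.subjects):
        lab6 = windows.labels[i, :SD_TRAIN_TRIALS]
        if lab6.sum() * 2 != SD_TRAIN_TRIALS:
            raise DataError(
                f"subject {subj}: first {SD_TRAIN_TRIALS} trials are not "
                f"label-balanced ({int(lab6.sum())} fear)"
            )
        mine = subj_idx == i
        train = np.nonzero(mine & (trial_idx < SD_TRAIN_TRIALS))[0]
        val = np.nonzero(mine & (trial_idx >= SD_TRAIN_TRIALS))[0]
        if val.size == 0 or n_trials <= SD_TRAIN_TRIALS:
            raise DataError(f"subject {subj}: no trials left for validation")
        folds.append(Fold(str(subj), train, val))
    return SplitPlan("sd", tuple(folds))


# ---------------------------------------------------------------------------
# training configuration / results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.1
    patience: int = 5
    accuracy_gate: float = 0.75
    max_epochs: int = 200
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.patience < 1:
            raise ContractError("patience must be at least 1")
        if not 0.0 < self.accuracy_gate < 1.0:
            raise ContractError("accuracy gate must lie in (0, 1)")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "TrainConfig":
        """Published learning rates: 0.1 subject-independent, 0.005 dependent."""
        if mode not in ("si", "sd"):
            raise ContractError("mode must be 'si' or 'sd'")
        lr = 0.1 if mode == "si" else 0.005
        overrides.setdefault("learning_rate", lr)
        return cls(**overrides)


@dataclass
class TrainResult:
    seed: int
    train_loss: np.ndarray
    train_acc: np.ndarray
    val_loss: np.ndarray
    val_acc: np.ndarray
    weights: np.ndarray
    stopped_epoch: int  # 1-based count of epochs run
    stopped_early: bool
    best_val_epoch: int  # 1-based epoch with the lowest validation loss

    @property
    def final_val_acc(self) -> float:
        return float(self.val_acc[-1])

    @property
    def best_val_acc(self) -> float:
        return float(self.val_acc[self.best_val_epoch - 1])

    def curve_table(self) -> str:
        """Delimited per-epoch log (epoch, losses, accuracies)."""
        lines = ["epoch\ttrain_loss\ttrain_acc\tval_loss\tval_acc"]
        for e in range(len(self.train_loss)):
            lines.append(
                f"{e + 1}\t{self.train_loss[e]!r}\t{self.train_acc[e]!r}"
                f"\t{self.val_loss[e]!r}\t{self.val_acc[e]!r}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# loss / optimizer
# ---------------------------------------------------------------------------


def softmax_cross_entropy(scores: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of softmaxed scores; returns (loss, d_loss/d_scores)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    shifted = scores - scores.max(axis=-1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=-1))
    logp = shifted - logz[..., None]
    n = y.shape[0]
    loss = -float(logp[np.arange(n), y].mean())
    dscores = np.exp(logp)
    dscores[np.arange(n), y] -= 1.0
    return loss, dscores / n


class Adam:
    """Standard Adam with bias correction (the paper's optimizer)."""

    def __init__(self, n_params: int, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def step(self, w: np.ndarray, g: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * g
        self.v = self.beta2 * self.v + (1 - self.beta2) * g * g
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        return w - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# early stopping / training loop
# ---------------------------------------------------------------------------


def should_stop(
    val_loss_history, train_acc_history, patience: int = 5, gate: float = 0.75
) -> bool:
    """True iff the best validation loss is ``patience`` epochs stale AND
    training accuracy has reached the gate at some epoch so far."""
    vl = list(val_loss_history)
    ta = list(train_acc_history)
    if not vl:
        raise ContractError("history must be non-empty")
    if max(ta) < gate:
        return False
    best = int(np.argmin(vl))  # earliest minimum; strict improvement resets it
    return (len(vl) - 1 - best) >= patience


def _accuracy(scores: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(scores.argmax(axis=-1) == y))


def train_full_batch(
    model,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    seed: int,
) -> TrainResult:
    """Full-batch Adam training of one fold; all randomness comes from ``seed``.

    Per epoch: one gradient step on the entire training batch (train
    metrics are recorded from the forward pass that produced the
    gradient, i.e. pre-update), then a validation pass with the updated
    weights. Stops early per :func:`should_stop` or at the epoch cap.
    """
    rng = np.random.default_rng(seed)
    w = model.init_weights(rng)
    opt = Adam(model.n_params, config.learning_rate, config.beta1, config.beta2, config.eps)
    tl, ta, vl, va = [], [], [], []
    stopped_early = False
    for _epoch in range(config.max_epochs):
        scores, vjp = model.forward_with_vjp(X_train, w)
        loss, dscores = softmax_cross_entropy(scores, y_train)
        if not np.isfinite(loss):
            raise TrainingError(
                f"non-finite training loss at epoch {_epoch + 1} (seed {seed})"
            )
        tl.append(loss)
        ta.append(_accuracy(scores, y_train))
        w = opt.step(w, vjp(dscores))
        val_scores = model.forward(X_val, w)
        v_loss, _ = softmax_cross_entropy(val_scores, y_val)
        vl.append(v_loss)
        va.append(_accuracy(val_scores, y_val))
        if should_stop(vl, ta, config.patience, config.accuracy_gate):
            stopped_early = True
            break
    return TrainResult(
        seed=seed,
        train_loss=np.asarray(tl),
        train_acc=np.asarray(ta),
        val_loss=np.asarray(vl),
        val_acc=np.asarray(va),
        weights=w,
        stopped_epoch=len(tl),
        stopped_early=stopped_early,
        best_val_epoch=int(np.argmin(vl)) + 1,
    )


def run_repeats(
    model,
    X_train,
    y_train,
    X_val,
    y_val,
    config: TrainConfig,
    seeds=DEFAULT_SEEDS,
) -> tuple[list, dict]:
    """Repeat training across weight-initialization seeds.

    Returns the per-seed results and a summary with the mean and
    (population) standard deviation of final validation accuracy.
    """
    results = [
        train_full_batch(model, X_train, y_train, X_val, y_val, config, seed)
        for seed in seeds
    ]
    accs = np.asarray([r.final_val_acc for r in results])
    summary = {
        "seeds": list(seeds),
        "val_acc_mean": float(accs.mean()),
        "val_acc_sd": float(accs.std()),
    }
    return results, summary
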