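"""Accuracy, confusion matrices, the Wilson-score chance threshold and
occlusion-based channel importance.

With validation sets of 120 (leave-one-subject-out) or 48 (subject-
dependent) windows, an accuracy slightly above 50% is not evidence of
learning. A classifier is called better than chance when the lower bound
of the 95% Wilson score interval of its accuracy exceeds 0.5; the minimum
accuracy satisfying that is found by a grid scan at the 0.01-percentage-
point precision of the reported thresholds (58.95% at n=120, 64.15% at
n=48).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError

#: standard-normal critical value for 95% two-sided confidence
WILSON_Z_95 = 1.959964


def wilson_lower_bound(p_hat: float, n: int, z: float = WILSON_Z_95) -> float:
    """Lower bound of the Wilson score interval for a binomial proportion."""
    p_hat = float(p_hat)
    if n < 1:
        raise ContractError("sample count must be at least 1")
    if not 0.0 <= p_hat <= 1.0:
        raise ContractError("p_hat must lie in [0, 1]")
    shrink = 1.0 / (1.0 + z * z / n)
    center = p_hat + z * z / (2.0 * n)
    radius = z * np.sqrt(p_hat * (1.0 - p_hat) / n + z * z / (4.0 * n * n))
    return shrink * (center - radius)


def min_significant_accuracy(n: int, confidence: float = 0.95, grid: float = 0.01) -> float:
    """Smallest accuracy (percent, on a ``grid``-point grid) whose Wilson
    lower bound exceeds 50%.

    Only the 95% level is supported (the published critical value is
    baked in to reproduce the printed thresholds exactly).
    """
    if confidence != 0.95:
        raise ContractError("only the 95% confidence level is supported")
    steps = int(round(100.0 / grid))
    for k in range(steps + 1):
        pct = k * grid
        if wilson_lower_bound(pct / 100.0, n) > 0.5:
            return round(pct, 10)
    raise ContractError("no accuracy on the grid clears the bound")  # pragma: no cover


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts, true class (non-fear=0 / fear=1) by predicted class."""

    counts: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized matrix; empty true-class rows stay all-zero."""
        row = self.counts.sum(axis=1, keepdims=True)
        return np.divide(
            self.counts, row, out=np.zeros_like(self.counts, dtype=float), where=row > 0
        )

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


def accuracy_and_confusion(predictions, labels) -> tuple[float, ConfusionMatrix]:
    """Classification accuracy plus the 2x2 confusion matrix."""
    pred = np.asarray(predictions, dtype=int).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if pred.size == 0 or pred.shape != y.shape:
        raise ContractError("predictions and labels must be non-empty and equal length")
    if not (np.isin(pred, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ContractError("binary predictions / labels expected")
    counts = np.zeros((2, 2), dtype=float)
    for t, p in ((0, 0), (0, 1), (1, 0), (1, 1)):
        counts[t, p] = np.sum((y == t) & (pred == p))
    cm = ConfusionMatrix(counts)
    return cm.accuracy, cm


def occlusion_importance(
    forward, X: np.ndarray, output: str = "scores", mask_value: float = 0.0
) -> np.ndarray:
    """Channel importances by masking, normalized to sum 1.

    ``forward`` maps a (batch, channels, length) array to model outputs;
    each channel is set to ``mask_value`` in turn and the importance of
    channel i is the batch-and-element mean of ``|baseline - masked_i|``,
    normalized across channels. ``output`` selects pre-softmax scores
    (default) or softmax probabilities.

    Masking zeroes the robust-arctan-scaled values (zero = the channel's
    training median there); when the model input has additionally been
    shifted into [0, pi] for angle embedding, pass ``mask_value=pi/2`` —
    the image of that zero under the shift.

    If the model ignores all channels, a uniform vector is returned with
    a warning (degenerate normalization).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[0] == 0:
        raise ContractError("expected a non-empty (batch, channels, length) input")
    if output not in ("scores", "probs"):
        raise ContractError("output must be 'scores' or 'probs'")

    def run(batch):
        out = np.asarray(forward(batch), dtype=float)
        if output == "probs":
            e = np.exp(out - out.max(axis=-1, keepdims=True))
            out = e / e.sum(axis=-1, keepdims=True)
        return out

    baseline = run(X)
    n_channels = X.shape[1]
    diffs = np.empty(n_channels)
    for c in range(n_channels):
        masked = X.copy()
        masked[:, c, :] = mask_value
        diffs[c] = np.mean(np.abs(baseline - run(masked)))
    total = diffs.sum()
    if total == 0:
        warnings.warn(
            "occlusion produced zero output differences on every channel; "
            "returning uniform importances",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(n_channels, 1.0 / n_channels)
    return diffs / total


def aggregate(per_subject_accuracies: dict) -> pd.DataFrame:
    """Mean/SD accuracy table: one row per subject plus a grand-Mean row.

    Input maps subject id to an iterable of per-seed accuracies (percent).
    Per-subject SD is over seeds, the Mean row is the mean of subject
    means with SD across subject means (population SD throughout).
    """
    if not per_subject_accuracies:
        raise ContractError("need at least one subject")
    rows = []
    means = []
    for subj, accs in per_subject_accuracies.items():
        a = np.asarray(list(accs), dtype=float)
        rows.append({"subject": str(subj), "mean": a.mean(), "sd": a.std()})
        means.append(a.mean())
    means = np.asarray(means)
    rows.append({"subject": "Mean", "mean": means.mean(), "sd": means.std()})
    return pd.DataFrame(rows).set_index("subject")
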