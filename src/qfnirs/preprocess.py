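"""Trial windowing, robust-IQR/arctan scaling and Pearson channel pruning.

The scaling pipeline is the one applied to the oxyhemoglobin (dHbO)
signals before quantum embedding: per-channel robust scaling (subtract
the median, divide by the interquartile range) composed with an arctan
squash, ``x_scaled = arctan((x - Q2) / (Q3 - Q1))``, which bounds
occasional heavy outliers away from the embedding's periodic range.
Outputs lie strictly inside (-pi/2, pi/2); an affine shift by +pi/2 maps
them into the [0, pi] interval that the RY angle embedding requires.

Conventions: 0-based sample indexing, stimulus onset at sample 0, and a
half-open [3 s, 15 s) analysis window. Quartiles use linear interpolation
between order statistics (numpy's default, the common "type 7" rule) and
are pooled per channel over all training samples of that channel.
Channel labels are 1-based in all I/O and reports, 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError, DegenerateDataError, RangeError, ShapeError

ANALYSIS_START_S = 3.0
ANALYSIS_END_S = 15.0
WINDOW_SAMPLES = 10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TrialSet:
    """Labeled dHbO trials: subjects x trials x channels x samples.

    ``labels`` uses 1 = fear, 0 = non-fear and must be balanced per
    subject. ``channel_labels`` are the 1-based labels used in reports.
    """

    subjects: list
    signals: np.ndarray  # (S, T, C, N)
    labels: np.ndarray  # (S, T) in {0, 1}
    sampling_rate: float = 10.0
    channel_labels: list = None

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signals.ndim != 4:
            raise ShapeError("signals must be (subjects, trials, channels, samples)")
        s, t, c, _ = self.signals.shape
        if len(self.subjects) != s or self.labels.shape != (s, t):
            raise DataError("subject / label bookkeeping does not match signals")
        if not np.isin(self.labels, (0, 1)).all():
            raise DataError("labels must be binary (1 = fear, 0 = non-fear)")
        counts = self.labels.sum(axis=1)
        if np.any(counts * 2 != t):
            raise DataError("labels must be balanced (equal fear / non-fear) per subject")
        if self.channel_labels is None:
            self.channel_labels = list(range(1, c + 1))
        if len(self.channel_labels) != c:
            raise DataError("channel_labels length must match channel count")

    @property
    def n_subjects(self):
        return self.signals.shape[0]

    @property
    def n_trials(self):
        return self.signals.shape[1]

    @property
    def n_channels(self):
        return self.signals.shape[2]

    @property
    def n_samples(self):
        return self.signals.shape[3]


@dataclass
class WindowSet:
    """Non-overlapping 10-sample windows derived from a TrialSet.

    ``windows`` has shape (subjects, trials, windows_per_trial, channels,
    10); window labels are inherited from their trial.
    """

    subjects: list
    windows: np.ndarray  # (S, T, W, C, 10)
    labels: np.ndarray  # (S, T)
    channel_labels: list

    @property
    def windows_per_trial(self):
        return self.windows.shape[2]

    @property
    def n_channels(self):
        return self.windows.shape[3]

    def flat(self):
        """Flatten to (X, y, subject_idx, trial_idx) over all windows."""
        s, t, w, c, l = self.windows.shape
        X = self.windows.reshape(s * t * w, c, l)
        y = np.repeat(self.labels.reshape(-1), w)
        subj = np.repeat(np.arange(s), t * w)
        trial = np.tile(np.repeat(np.arange(t), w), s)
        return X, y, subj, trial


@dataclass(frozen=True)
class ScalerParams:
    """Per-channel quartiles of the training data (Q1 <= Q2 <= Q3, IQR > 0)."""

    q1: np.ndarray
    q2: np.ndarray
    q3: np.ndarray

    @property
    def iqr(self) -> np.ndarray:
        return self.q3 - self.q1


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_analysis_window(trials: TrialSet) -> TrialSet:
    """Truncate every trial to the 3-15 s post-stimulus window.

    At 10 Hz this keeps samples [30, 150) — 120 samples: the segment in
    which the hemodynamic response to the stimulus is expected.
    """
    lo = int(round(ANALYSIS_START_S * trials.sampling_rate))
    hi = int(round(ANALYSIS_END_S * trials.sampling_rate))
    if trials.n_samples < hi:
        raise DataError(
            f"trials have {trials.n_samples} samples; need at least {hi} "
            f"({ANALYSIS_END_S} s at {trials.sampling_rate} Hz)"
        )
    return replace(trials, signals=trials.signals[..., lo:hi].copy())


def make_windows(trials: TrialSet) -> WindowSet:
    """Partition each (already truncated) trial into 10-sample windows."""
    n = trials.n_samples
    if n % WINDOW_SAMPLES != 0:
        raise DataError(f"trial length {n} is not divisible by {WINDOW_SAMPLES}")
    s, t, c, _ = trials.signals.shape
    w = n // WINDOW_SAMPLES
    win = trials.signals.reshape(s, t, c, w, WINDOW_SAMPLES).swapaxes(2, 3).copy()
    return WindowSet(trials.subjects, win, trials.labels.copy(), list(trials.channel_labels))


def fit_robust_scaler(training_windows: np.ndarray, channel_labels=None) -> ScalerParams:
    """Per-channel quartiles pooled over all training samples of that channel.

    ``training_windows`` is (..., channels, samples); every axis except the
    channel axis is pooled. Raises if any channel has zero IQR.
    """
    x = np.asarray(training_windows, dtype=float)
    if x.ndim < 2 or x.size == 0:
        raise ShapeError("training windows must be a non-empty (..., C, L) array")
    c = x.shape[-2]
    pooled = np.moveaxis(x, -2, 0).reshape(c, -1)
    q1, q2, q3 = np.quantile(pooled, [0.25, 0.5, 0.75], axis=1)
    bad = np.nonzero(q3 - q1 <= 0)[0]
    if bad.size:
        labels = channel_labels or list(range(1, c + 1))
        raise DegenerateDataError(
            f"zero interquartile range on channel(s) {[labels[i] for i in bad]}"
        )
    return ScalerParams(q1, q2, q3)


def apply_robust_arctan(x: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Elementwise arctan((x - Q2) / (Q3 - Q1)); strictly inside (-pi/2, pi/2)."""
    x = np.asarray(x, dtype=float)
    c = params.q2.shape[0]
    if x.shape[-2] != c:
        raise ShapeError(f"expected channel axis of size {c}, got {x.shape}")
    q2 = params.q2[:, None]
    iqr = params.iqr[:, None]
    return np.arctan((x - q2) / iqr)


def rescale_to_embedding_range(x: np.ndarray) -> np.ndarray:
    """Shift (-pi/2, pi/2) values into [0, pi] (the unique pure shift)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= -np.pi / 2) or np.any(x >= np.pi / 2):
        raise RangeError("inputs must lie strictly inside (-pi/2, pi/2)")
    return x + np.pi / 2


def pearson_channel_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-channel mean |Pearson r| between each time point and the label.

    ``X`` is (windows, channels, samples), ``y`` binary labels. Constant
    features contribute score 0 for that time point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 3 or X.shape[0] != y.shape[0]:
        raise ShapeError("expected X (N, C, L) and matching labels")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = np.einsum("nct,n->ct", xc, yc)
    den = np.sqrt(np.einsum("nct,nct->ct", xc, xc) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.abs(r).mean(axis=1)


def select_channels_pearson(
    X: np.ndarray, y: np.ndarray, channel_labels=None, n_drop: int = 2
):
    """Drop the ``n_drop`` channels least correlated with the class label.

    Returns ``(kept_labels, dropped_labels, scores)`` with 1-based labels.
    Ties are broken deterministically: the lower channel label is dropped
    first.
    """
    scores = pearson_channel_scores(X, y)
    c = scores.shape[0]
    if n_drop < 0 or n_drop >= c:
        raise DataError(f"cannot drop {n_drop} of {c} channels")
    labels = list(channel_labels) if channel_labels is not None else list(range(1, c + 1))
    order = sorted(range(c), key=lambda i: (scores[i], labels[i]))
    dropped = sorted(labels[i] for i in order[:n_drop])
    kept = [lab for lab in labels if lab not in dropped]
    return kept, dropped, scores


def channel_indices(channel_labels, selected_labels) -> np.ndarray:
    """0-based indices of ``selected_labels`` within ``channel_labels``."""
    lut = {lab: i for i, lab in enumerate(channel_labels)}
    return np.asarray([lut[lab] for lab in selected_labels], dtype=int)


def flatten_channel_major(window: np.ndarray) -> np.ndarray:
    """Flatten a (channels, samples) window channel-major (channel 1 first)."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ShapeError("expected a 2-D (channels, samples) window")
    return w.reshape(-1)


def unflatten_channel_major(flat: np.ndarray, n_channels: int, n_samples: int) -> np.ndarray:
    v = np.asarray(flat, dtype=float)
    if v.size != n_channels * n_samples:
        raise ShapeError("flat vector size does not match the requested shape")
    return v.reshape(n_channels, n_samples)


def flatten_for_aepqc(window: np.ndarray) -> np.ndarray:
    """Channel-major flattening of a pruned 25x10 window into 250 features."""
    w = np.asarray(window, dtype=float)
    if w.shape != (25, WINDOW_SAMPLES):
        raise ShapeError(f"expected a 25x{WINDOW_SAMPLES} pruned window, got {w.shape}")
    return flatten_channel_major(w)
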