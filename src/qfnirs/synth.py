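"""Synthetic fNIRS-like dHbO datasets with the structure the pipeline assumes.

The generator emulates the shape and statistics of the virtual-reality
height-exposure recordings the classifiers target: 14 subjects, 10
balanced 30 s trials each, 27 channels at 10 Hz, values in a narrow range
with occasional heavy outliers. Fear trials add a canonical double-gamma
hemodynamic response (scaled by a per-subject gain) to a configurable set
of informative channels; everything else is white noise. The point is to
exercise every pipeline branch — outliers stress the robust scaler,
zero-effect channels drive Pearson pruning, balanced labels satisfy the
split preconditions — not physiological realism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .preprocess import TrialSet

MANIFEST_NAME = "manifest.json"


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_time: float = 6.0
    undershoot_time: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    onset_delay: float = 3.0

    def __post_init__(self):
        if not self.peak_time < self.undershoot_time:
            raise ConfigError("HRF peak must precede the undershoot")


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the generator.

    Defaults mirror the balanced 14-subject design the classifiers are
    evaluated on; informative channels default to everything except the
    two channels reported as least informative (22 and 24), so channel
    pruning has a known right answer on synthetic data.
    """

    n_subjects: int = 14
    n_trials: int = 10
    n_channels: int = 27
    sampling_rate: float = 10.0
    trial_duration: float = 30.0
    informative_channels: tuple = None  # 1-based labels
    effect_amplitude: float = 3.0
    noise_sd: float = 1.0
    outlier_rate: float = 0.005
    outlier_scale: float = 100.0
    subject_variability_sd: float = 0.2
    hrf: HRFParams = field(default_factory=HRFParams)
    seed: int = 0

    def __post_init__(self):
        if self.informative_channels is None:
            inf = tuple(c for c in range(1, self.n_channels + 1) if c not in (22, 24))
            object.__setattr__(self, "informative_channels", inf)
        else:
            object.__setattr__(
                self, "informative_channels", tuple(int(c) for c in self.informative_channels)
            )
        if not 0 <= self.outlier_rate <= 1:
            raise ConfigError("outlier_rate must lie in [0, 1]")
        if self.n_trials % 2:
            raise ConfigError("n_trials must be even (balanced labels)")
        if any(not 1 <= c <= self.n_channels for c in self.informative_channels):
            raise ConfigError("informative_channels must be 1-based channel labels")
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ConfigError("need at least one subject and one channel")


def hrf_kernel(params: HRFParams = HRFParams(), sampling_rate: float = 10.0,
               duration: float = 30.0) -> np.ndarray:
    """Peak-normalized double-gamma HRF sampled over a trial.

    Gamma shapes are chosen so the modes fall at ``peak_time`` and
    ``undershoot_time`` after an ``onset_delay`` dead time; the kernel is
    zero before the onset and has maximum exactly 1.
    """
    t = np.arange(0.0, duration, 1.0 / sampling_rate) - params.onset_delay
    g1 = stats.gamma.pdf(t, a=params.peak_time + 1.0, scale=1.0)
    g2 = stats.gamma.pdf(t, a=params.undershoot_time + 1.0, scale=1.0)
    h = g1 - params.undershoot_ratio * g2
    h[t < 0] = 0.0
    return h / h.max()


def _trial_labels(n_trials: int) -> np.ndarray:
    # Alternating fear / non-fear: balanced overall and 3/3 in the first
    # six trials, as the subject-dependent split requires.
    lab = np.zeros(n_trials, dtype=int)
    lab[::2] = 1
    return lab


def simulate_dataset(config: SynthConfig) -> TrialSet:
    """Generate a TrialSet; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    s, t, c = config.n_subjects, config.n_trials, config.n_channels
    n = int(round(config.trial_duration * config.sampling_rate))
    signals = rng.normal(0.0, config.noise_sd, size=(s, t, c, n))
    gains = rng.normal(0.0, config.subject_variability_sd, size=s)
    labels = np.tile(_trial_labels(t), (s, 1))

    h = hrf_kernel(config.hrf, config.sampling_rate, config.trial_duration)
    inf_idx = np.asarray([lab - 1 for lab in config.informative_channels], dtype=int)
    if inf_idx.size:
        fear = labels.astype(bool)  # (S, T)
        bump = config.effect_amplitude * (1.0 + gains)[:, None] * fear  # (S, T)
        signals[:, :, inf_idx, :] += bump[:, :, None, None] * h

    if config.outlier_rate > 0:
        mask = rng.random(size=signals.shape) < config.outlier_rate
        spikes = rng.normal(0.0, config.outlier_scale * config.noise_sd, size=signals.shape)
        signals[mask] = spikes[mask]

    subjects = [f"S{i + 1:02d}" for i in range(s)]
    return TrialSet(subjects, signals, labels, config.sampling_rate)


# ---------------------------------------------------------------------------
# on-disk layout: one TSV per subject + a JSON manifest
# ---------------------------------------------------------------------------


def write_dataset(trials: TrialSet, path, synth_config: SynthConfig | None = None) -> Path:
    """Write one delimited file per subject plus a manifest.

    Rows are samples (trials concatenated in recorded order), columns are
    channels with 1-based headers. The manifest records trial boundaries,
    labels, the sampling rate and — for synthetic data — the generating
    config, for provenance.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, subj in enumerate(trials.subjects):
        fname = f"{subj}.tsv"
        sig = trials.signals[i]  # (T, C, N)
        t, c, n = sig.shape
        table = sig.transpose(0, 2, 1).reshape(t * n, c)
        header = "\t".join(f"ch{lab:02d}" for lab in trials.channel_labels)
        with open(path / fname, "w") as fh:
            fh.write(header + "\n")
            for row in table:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
        entries.append(
            {
                "id": subj,
                "file": fname,
                "n_trials": int(t),
                "trial_length": int(n),
                "labels": [int(v) for v in trials.labels[i]],
            }
        )
    manifest = {
        "format_version": 1,
        "sampling_rate": trials.sampling_rate,
        "n_channels": trials.n_channels,
        "channel_labels": list(trials.channel_labels),
        "subjects": entries,
        "synthetic": synth_config is not None,
    }
    if synth_config is not None:
        cfg = asdict(synth_config)
        cfg["informative_channels"] = list(cfg["informative_channels"])
        manifest["synth_config"] = cfg
    with open(path / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def read_dataset(path) -> TrialSet:
    """Read a dataset directory back into a TrialSet, validating the layout."""
    path = Path(path)
    mf = path / MANIFEST_NAME
    if not mf.exists():
        raise DataError(f"missing manifest {mf}")
    with open(mf) as fh:
        manifest = json.load(fh)
    n_channels = int(manifest["n_channels"])
    entries = manifest["subjects"]
    if not entries:
        raise DataError("manifest lists no subjects")

    signals, labels, subjects = [], [], []
    for ent in entries:
        fpath = path / ent["file"]
        if not fpath.exists():
            raise DataError(f"manifest names missing file {ent['file']}")
        with open(fpath) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) != n_channels:
                raise DataError(
                    f"{ent['file']}: {len(header)} channel headers, manifest says {n_channels}"
                )
            table = np.loadtxt(fh, delimiter="\t", ndmin=2)
        t, n = int(ent["n_trials"]), int(ent["trial_length"])
        if table.shape != (t * n, n_channels):
            raise DataError(
                f"{ent['file']}: shape {table.shape} does not match manifest "
                f"({t} trials x {n} samples x {n_channels} channels)"
            )
        lab = np.asarray(ent["labels"], dtype=int)
        if lab.shape != (t,):
            raise DataError(f"{ent['file']}: label count does not match trials")
        if lab.sum() * 2 != t:
            raise DataError(f"{ent['file']}: unbalanced labels")
        signals.append(table.reshape(t, n, n_channels).transpose(0, 2, 1))
        labels.append(lab)
        subjects.append(ent["id"])

    shapes = {s.shape for s in signals}
    if len(shapes) != 1:
        raise DataError("subjects have inconsistent trial shapes")
    return TrialSet(
        subjects,
        np.stack(signals),
        np.stack(labels),
        float(manifest["sampling_rate"]),
        list(manifest.get("channel_labels", range(1, n_channels + 1))),
    )


def toy_fixtures() -> dict:
    """Deterministic micro-fixtures for fast end-to-end tests.

    Includes a Bell-state circuit (RY(pi/2) + CNOT, amplitudes
    (1/sqrt2, 0, 0, 1/sqrt2)) and a 2-subject, 4-trial micro-dataset that
    runs the full pipeline in seconds.
    """
    from .core import Circuit, GateSpec

    bell = Circuit(
        2,
        (GateSpec("RY", (0,), (np.pi / 2,)), GateSpec("CNOT", (0, 1))),
        readout=(0, 1),
    )
    micro_cfg = SynthConfig(
        n_subjects=2, n_trials=4, effect_amplitude=4.0, noise_sd=1.0, seed=7
    )
    return {
        "bell_circuit": bell,
        "bell_amplitudes": np.array([1, 0, 0, 1], dtype=complex) / np.sqrt(2),
        "micro_config": micro_cfg,
        "micro_dataset": simulate_dataset(micro_cfg),
    }
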