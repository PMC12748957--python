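"""End-to-end experiment orchestration.

Reproduces the full evaluation workflow as importable functions: split
the dataset (subject-independent LOSO or subject-dependent), fit the
robust-arctan scaler and — for the AEPQC — Pearson channel pruning on
the training fold only, train with full-batch Adam + gated early
stopping, repeat over seeds, and report per-subject accuracy tables,
pooled confusion matrices, occlusion-based channel importances and the
Wilson chance threshold for the validation-set size.

All outputs are plain delimited text; every table embeds the config hash
and seed list so deterministic outputs are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, protocol
from .errors import ConfigError
from .models import QCNN, AEPQC, ModelSpec, fuse, make_model
from .preprocess import (
    TrialSet,
    WindowSet,
    apply_robust_arctan,
    channel_indices,
    extract_analysis_window,
    fit_robust_scaler,
    make_windows,
    rescale_to_embedding_range,
    select_channels_pearson,
)
from .synth import SynthConfig, simulate_dataset, write_dataset

MODEL_NAMES = {
    "aepqc": ModelSpec("AEPQC"),
    "qcnn-k1": ModelSpec("QCNN", kernel="K1"),
    "qcnn-k2": ModelSpec("QCNN", kernel="K2"),
}


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def model_spec_for(name: str) -> ModelSpec:
    try:
        return MODEL_NAMES[name.lower()]
    except KeyError:
        raise ConfigError(f"unknown model name {name!r}; pick from {sorted(MODEL_NAMES)}")


# ---------------------------------------------------------------------------
# per-fold preprocessing (leakage-free: everything fitted on the train split)
# ---------------------------------------------------------------------------


@dataclass
class FoldData:
    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    kept_channels: list  # 1-based labels entering the model
    # channelwise model inputs (pre-flattening for AEPQC), for occlusion
    X_val_channels: np.ndarray


def prepare_fold(windows: WindowSet, fold: protocol.Fold, spec: ModelSpec) -> FoldData:
    """Scale (and for AEPQC prune + flatten) one fold's windows."""
    X, y, _, _ = windows.flat()
    Xtr_raw, Xva_raw = X[fold.train_idx], X[fold.val_idx]
    ytr, yva = y[fold.train_idx], y[fold.val_idx]

    scaler = fit_robust_scaler(Xtr_raw, windows.channel_labels)
    Xtr = apply_robust_arctan(Xtr_raw, scaler)
    Xva = apply_robust_arctan(Xva_raw, scaler)

    if spec.family == "AEPQC":
        kept, _, _ = select_channels_pearson(Xtr, ytr, windows.channel_labels, n_drop=2)
        idx = channel_indices(windows.channel_labels, kept)
        Xtr_c, Xva_c = Xtr[:, idx, :], Xva[:, idx, :]
        return FoldData(
            Xtr_c.reshape(len(ytr), -1),
            ytr,
            Xva_c.reshape(len(yva), -1),
            yva,
            kept,
            Xva_c,
        )
    Xtr_e = rescale_to_embedding_range(Xtr)
    Xva_e = rescale_to_embedding_range(Xva)
    return FoldData(Xtr_e, ytr, Xva_e, yva, list(windows.channel_labels), Xva_e)


def _channelwise_forward(model, w):
    """Forward pass taking (batch, channels, length) for occlusion masking."""
    if isinstance(model, AEPQC):
        return lambda Xc: model.forward(Xc.reshape(Xc.shape[0], -1), w)
    return lambda Xc: model.forward(Xc, w)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CrossvalResult:
    mode: str
    model_name: str
    table: pd.DataFrame  # per-subject mean/SD accuracy (%) + Mean row
    accuracies: dict  # subject -> list of per-seed final val accuracies (%)
    confusion: metrics.ConfusionMatrix  # pooled over folds and seeds
    importance: pd.DataFrame  # subject x channel (1-based columns)
    wilson_threshold: float  # percent
    n_val: int
    seeds: list
    config_hash: str
    runs: pd.DataFrame = None  # one row per (fold, seed) training run
    channel_scores: dict | None = None  # (subject, seed) -> validation (B, C, 2)


def _dataset_windows(trials: TrialSet) -> WindowSet:
    return make_windows(extract_analysis_window(trials))


def run_crossval(
    trials: TrialSet,
    model_name: str = "qcnn-k1",
    mode: str = "si",
    seeds=protocol.DEFAULT_SEEDS,
    train_config: protocol.TrainConfig | None = None,
    compute_importance: bool = True,
    keep_channel_scores: bool = False,
    out_dir=None,
) -> CrossvalResult:
    """Run the full cross-validation workflow on a TrialSet.

    ``mode`` selects leave-one-subject-out ("si") or the per-subject
    first-six/last-four trial split ("sd"). Returns the aggregate table
    (accuracies in percent), pooled confusion matrix, per-subject channel
    importances and the Wilson chance threshold for the fold's
    validation-set size; optionally writes all of it under ``out_dir``.
    """
    spec = model_spec_for(model_name)
    cfg = train_config or protocol.TrainConfig.for_mode(mode)
    windows = _dataset_windows(trials)
    plan = protocol.loso_splits(windows) if mode == "si" else subject_dependent_plan(windows)

    chash = config_hash(
        {
            "model": model_name,
            "mode": mode,
            "seeds": list(seeds),
            "lr": cfg.learning_rate,
            "max_epochs": cfg.max_epochs,
            "patience": cfg.patience,
            "gate": cfg.accuracy_gate,
        }
    )

    accuracies: dict = {}
    conf_counts = np.zeros((2, 2))
    importance_rows = {}
    channel_scores: dict = {}
    run_log = []
    n_val = None
    for fold in plan.folds:
        data = prepare_fold(windows, fold, spec)
        n_val = len(data.y_val)
        model = make_model(spec)
        accs, imp_rows = [], []
        for seed in seeds:
            res = protocol.train_full_batch(
                model, data.X_train, data.y_train, data.X_val, data.y_val, cfg, seed
            )
            val_scores = model.forward(data.X_val, res.weights)
            preds = val_scores.argmax(axis=-1)
            _, cm = metrics.accuracy_and_confusion(preds, data.y_val)
            conf_counts += cm.counts
            accs.append(100.0 * res.final_val_acc)
            run_log.append(
                {
                    "fold": fold.name,
                    "seed": seed,
                    "config": chash,
                    "epochs": res.stopped_epoch,
                    "stopped_early": res.stopped_early,
                    "best_val_epoch": res.best_val_epoch,
                    "final_val_acc_pct": 100.0 * res.final_val_acc,
                    "best_val_acc_pct": 100.0 * res.best_val_acc,
                }
            )
            if compute_importance:
                # masking zeroes the post-arctan values; the QCNN input has
                # been shifted into [0, pi], where that zero sits at pi/2
                mask = 0.0 if spec.family == "AEPQC" else np.pi / 2
                imp = metrics.occlusion_importance(
                    _channelwise_forward(model, res.weights),
                    data.X_val_channels,
                    mask_value=mask,
                )
                # expand to the full channel list; channels pruned in this
                # fold (AEPQC) carry zero importance
                full = np.zeros(len(windows.channel_labels))
                full[channel_indices(windows.channel_labels, data.kept_channels)] = imp
                imp_rows.append(full)
            if keep_channel_scores and isinstance(model, QCNN):
                channel_scores[(fold.name, seed)] = (
                    model.channel_scores(data.X_val, res.weights),
                    data.y_val,
                    res.weights,
                )
        accuracies[fold.name] = accs
        if compute_importance:
            mean_imp = np.mean(imp_rows, axis=0)
            importance_rows[fold.name] = mean_imp / mean_imp.sum()

    table = metrics.aggregate(accuracies)
    importance = (
        pd.DataFrame.from_dict(
            importance_rows, orient="index",
            columns=[f"ch{c:02d}" for c in windows.channel_labels],
        )
        if compute_importance
        else pd.DataFrame()
    )
    result = CrossvalResult(
        mode=mode,
        model_name=model_name,
        table=table,
        accuracies=accuracies,
        confusion=metrics.ConfusionMatrix(conf_counts),
        importance=importance,
        wilson_threshold=metrics.min_significant_accuracy(n_val),
        n_val=n_val,
        seeds=list(seeds),
        config_hash=chash,
        runs=pd.DataFrame(run_log),
        channel_scores=channel_scores if keep_channel_scores else None,
    )
    if out_dir is not None:
        _write_crossval(result, out_dir)
    return result


def subject_dependent_plan(windows: WindowSet) -> protocol.SplitPlan:
    return protocol.subject_dependent_splits(windows)


def _write_table(df: pd.DataFrame, path: Path, header_lines: list):
    with open(path, "w") as fh:
        for ln in header_lines:
            fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t", float_format="%.6f")


def _write_crossval(result: CrossvalResult, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = [
        f"model={result.model_name} mode={result.mode} config={result.config_hash}",
        f"seeds={result.seeds}",
        f"wilson_threshold_pct={result.wilson_threshold} (n={result.n_val})",
    ]
    _write_table(result.table, out / "accuracy.tsv", hdr)
    cm = pd.DataFrame(
        result.confusion.normalized,
        index=["true_nonfear", "true_fear"],
        columns=["pred_nonfear", "pred_fear"],
    )
    _write_table(cm, out / "confusion.tsv", hdr)
    if len(result.importance):
        _write_table(result.importance, out / "importance.tsv", hdr)
    # append-only run log: one line per (fold, seed) training
    runs_path = out / "runs.tsv"
    write_header = not runs_path.exists()
    with open(runs_path, "a") as fh:
        result.runs.to_csv(fh, sep="\t", index=False, header=write_header)


# ---------------------------------------------------------------------------
# fusion ablation
# ---------------------------------------------------------------------------


def run_ablation(
    trials: TrialSet,
    kernels=("K1", "K2"),
    seeds=protocol.DEFAULT_SEEDS,
    train_config: protocol.TrainConfig | None = None,
    out_dir=None,
):
    """Fusion ablation (subject-independent): c_head vs avg / max / amax.

    The QCNN is trained once per (kernel, fold, seed) with the
    classification head; the simple fusions are then evaluated post hoc
    on the logged validation channel scores, so upstream kernel weights
    are shared bit-exactly across fusion modes. Returns the comparison
    table (fusion rows x kernel columns, "mean (sd)" in percent) plus the
    raw per-mode accuracy lists and the logged channel scores.
    """
    fusion_modes = ("c_head", "avg", "max", "amax")
    cell_accs = {k: {m: {} for m in fusion_modes} for k in kernels}
    logs = {}
    for kernel in kernels:
        name = f"qcnn-{kernel.lower()}"
        res = run_crossval(
            trials,
            model_name=name,
            mode="si",
            seeds=seeds,
            train_config=train_config,
            compute_importance=False,
            keep_channel_scores=True,
        )
        logs[kernel] = res.channel_scores
        model = QCNN(model_spec_for(name))
        for (subj, seed), (cs, y_val, weights) in res.channel_scores.items():
            head_scores = model._head_forward(cs, model.head_weights(weights), False)[0]
            outs = {"c_head": head_scores}
            for m in ("avg", "max", "amax"):
                outs[m] = fuse(cs, m)
            for m, sc in outs.items():
                acc = 100.0 * float(np.mean(sc.argmax(axis=-1) == y_val))
                cell_accs[kernel][m].setdefault(subj, []).append(acc)

    rows = []
    for m in fusion_modes:
        row = {"method": m}
        for kernel in kernels:
            per_subj = cell_accs[kernel][m]
            means = np.asarray([np.mean(v) for v in per_subj.values()])
            row[kernel] = f"{means.mean():.2f} ({means.std():.2f})"
        rows.append(row)
    table = pd.DataFrame(rows).set_index("method")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_table(table, out / "ablation.tsv", [f"seeds={list(seeds)}"])
    return table, cell_accs, logs


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(config: SynthConfig, out_dir) -> Path:
    """Simulate a synthetic dataset and write it (with provenance) to disk."""
    trials = simulate_dataset(config)
    return write_dataset(trials, out_dir, synth_config=config)
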