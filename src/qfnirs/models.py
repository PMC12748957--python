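"""The PQC classifier architectures.

Two families are implemented:

* **AEPQC** — a single 8-qubit circuit fed by amplitude embedding of the
  250-feature flattened window (25 channels x 10 samples after pruning,
  6 zero-padding values). Three U3 layers interleaved with IsingXX
  entanglement, a pre-pooling IsingXX ring, and measurement-conditioned
  (two-branch) U3 pooling on alternating neighbouring qubits; exactly
  112 trainable angles, enforced at build time.

* **QCNN** — a convolutional scheme: a 4-qubit kernel (K1 light, or K2
  with quantum pooling) slides over each channel's 10 temporal features
  with window 4 / stride 2, shrinking the length by 2 per layer
  (10 -> 8 -> 6 -> 4 -> 2 over 4 layers); kernel weights are shared
  across window positions but separate per channel and per layer. The
  27x2 channel outputs are fused either by a 6-qubit amplitude-embedding
  classification head (``c_head``, 18 trainable angles) or by simple
  columnwise reductions (``avg`` / ``max`` / ``amax``).

Class scores are the Pauli-Z expectations of the two designated readout
wires (the two lowest-index surviving wires); softmax is applied only
inside the training loss. Kernel outputs in [-1, 1] are affinely mapped
to [0, pi] before re-embedding in the next layer.

The sliding-kernel forward/backward uses compiled per-channel kernel
unitaries with analytic parameter derivatives (algebraically identical
to gate-by-gate application — the equivalence is covered by tests).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _engine
from .errors import (
    BuildVerificationError,
    ConfigError,
    ContractError,
    NormalizationError,
    RangeError,
    ShapeError,
)

_RANGE_TOL = 1e-9

FAMILIES = ("AEPQC", "QCNN")
KERNELS = ("K1", "K2")
FUSIONS = ("c_head", "avg", "max", "amax")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; the weight layout is derived from it."""

    family: str
    kernel: str | None = None
    fusion: str | None = None
    n_channels: int | None = None
    window_len: int = 4
    stride: int = 2
    input_len: int = 10
    n_classes: int = 2

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        if self.family == "AEPQC":
            if self.kernel is not None or self.fusion is not None:
                raise ConfigError("AEPQC takes neither a kernel nor a fusion mode")
            object.__setattr__(self, "n_channels", self.n_channels or 25)
        else:
            object.__setattr__(self, "kernel", self.kernel or "K1")
            object.__setattr__(self, "fusion", self.fusion or "c_head")
            object.__setattr__(self, "n_channels", self.n_channels or 27)
            if self.kernel not in KERNELS:
                raise ConfigError(f"unknown kernel {self.kernel!r}")
            if self.fusion not in FUSIONS:
                raise ConfigError(f"unknown fusion {self.fusion!r}")
            if self.window_len != 4 or self.stride != 2:
                raise ConfigError("the sliding kernel uses window 4 / stride 2")
            if self.input_len < 4 or self.input_len % 2:
                raise ConfigError("input_len must be even and at least 4")
        if self.n_classes != 2:
            raise ConfigError("only binary classification is supported")

    @property
    def n_layers(self) -> int:
        if self.family != "QCNN":
            raise ConfigError("n_layers is a QCNN property")
        return (self.input_len - 2) // self.stride

    @property
    def layer_lengths(self) -> tuple:
        """Temporal lengths entering each layer plus the final length."""
        lens = [self.input_len]
        while lens[-1] > 2:
            lens.append(lens[-1] - 2)
        return tuple(lens)


# ---------------------------------------------------------------------------
# circuit definitions (runtime ops with weight indices)
# ---------------------------------------------------------------------------


def _w(i):
    return ("w", i)


def _c(v):
    return ("c", float(v))


def aepqc_ops() -> tuple[list, list]:
    """AEPQC gate list and parameter labels; 8 qubits, readout (0, 2)."""
    ops, labels = [], []
    k = 0

    def u3_layer(tag):
        nonlocal k
        for wire in range(8):
            ops.append(_engine.RtOp("U3", (wire,), (_w(k), _w(k + 1), _w(k + 2))))
            labels.extend((tag, wire, p) for p in range(3))
            k += 3

    def xx_layer(tag, pairs):
        nonlocal k
        for pair in pairs:
            ops.append(_engine.RtOp("IsingXX", tuple(pair), (_w(k),)))
            labels.append((tag, pair, 0))
            k += 1

    u3_layer("u3_a")
    xx_layer("xx_even", [(0, 1), (2, 3), (4, 5), (6, 7)])
    u3_layer("u3_b")
    xx_layer("xx_odd", [(1, 2), (3, 4), (5, 6), (7, 0)])
    u3_layer("u3_c")
    xx_layer("xx_ring", [(i, (i + 1) % 8) for i in range(8)])
    for measured, target in ((1, 0), (3, 2), (5, 4), (7, 6)):
        ops.append(
            _engine.RtOp(
                "COND_U3",
                (measured, target),
                tuple(_w(k + j) for j in range(6)),
            )
        )
        labels.extend(("pool", (measured, target), p) for p in range(6))
        k += 6
    return ops, labels


def kernel_ops(kind: str) -> tuple[list, list, int]:
    """Weight-only ops of a 4-qubit kernel (embedding handled separately)."""
    ops, labels = [], []
    if kind == "K1":
        # light kernel: one RY + RZ rotation pair per wire, circular CNOTs
        for wire in range(4):
            ops.append(_engine.RtOp("RY", (wire,), (_w(wire),)))
            labels.append(("ry", wire))
        for wire in range(4):
            ops.append(_engine.RtOp("RZ", (wire,), (_w(4 + wire),)))
            labels.append(("rz", wire))
        for wire in range(4):
            ops.append(_engine.RtOp("CNOT", (wire, (wire + 1) % 4)))
        n_params = 8
    elif kind == "K2":
        # U3/IsingXX kernel with quantum pooling: 9 U3 parameters per wire
        # (every wire carries exactly three U3-type gates) + 3 entanglers
        k = 0
        for wire in range(4):
            ops.append(_engine.RtOp("U3", (wire,), (_w(k), _w(k + 1), _w(k + 2))))
            labels.extend(("u3_a", wire, p) for p in range(3))
            k += 3
        for pair in ((0, 1), (2, 3)):
            ops.append(_engine.RtOp("IsingXX", pair, (_w(k),)))
            labels.append(("xx", pair))
            k += 1
        for wire in range(4):
            ops.append(_engine.RtOp("U3", (wire,), (_w(k), _w(k + 1), _w(k + 2))))
            labels.extend(("u3_b", wire, p) for p in range(3))
            k += 3
        ops.append(_engine.RtOp("IsingXX", (1, 2), (_w(k),)))
        labels.append(("xx", (1, 2)))
        k += 1
        for wire in (1, 3):  # pre-measurement rotations on the pooled wires
            ops.append(_engine.RtOp("U3", (wire,), (_w(k), _w(k + 1), _w(k + 2))))
            labels.extend(("u3_pre", wire, p) for p in range(3))
            k += 3
        for measured, target in ((1, 0), (3, 2)):
            # single-branch pooling: identity on outcome |0>
            ops.append(
                _engine.RtOp(
                    "COND_U3",
                    (measured, target),
                    (_c(0), _c(0), _c(0), _w(k), _w(k + 1), _w(k + 2)),
                )
            )
            labels.extend(("pool", (measured, target), p) for p in range(3))
            k += 3
        n_params = k
    else:
        raise ConfigError(f"unknown kernel {kind!r}")
    return ops, labels, n_params


def c_head_ops() -> tuple[list, list]:
    """6-qubit classification head: RY+RZ+RX per wire, circular CNOTs."""
    ops, labels = [], []
    for i, kind in enumerate(("RY", "RZ", "RX")):
        for wire in range(6):
            ops.append(_engine.RtOp(kind, (wire,), (_w(6 * i + wire),)))
            labels.append((kind.lower(), wire))
    for wire in range(6):
        ops.append(_engine.RtOp("CNOT", (wire, (wire + 1) % 6)))
    return ops, labels


KERNEL_READOUT = (0, 2)
HEAD_READOUT = (0, 1)
AEPQC_READOUT = (0, 2)
AEPQC_N_QUBITS = 8
AEPQC_N_PARAMS = 112
AEPQC_INPUT_LEN = 250
HEAD_N_QUBITS = 6
HEAD_N_PARAMS = 18
INIT_SCALE = np.pi / 10  # uniform init range per angle


def _check_angle_range(x):
    if np.any(x < -_RANGE_TOL) or np.any(x > np.pi + _RANGE_TOL):
        raise RangeError("angle-embedded features must lie in [0, pi]")


def _amplitude_rows(X: np.ndarray, dim: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise amplitude embedding with tail zero-padding."""
    if X.shape[-1] > dim:
        raise ShapeError(f"{X.shape[-1]} features exceed {dim} amplitudes")
    norms = np.linalg.norm(X, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise NormalizationError("cannot amplitude-embed an all-zero row")
    amp = np.zeros(X.shape[:-1] + (dim,), dtype=complex)
    amp[..., : X.shape[-1]] = X / norms
    return amp, norms


def _softmax(scores: np.ndarray) -> np.ndarray:
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# AEPQC
# ---------------------------------------------------------------------------


class AEPQC:
    """Amplitude-embedding PQC classifier (8 qubits, 112 trainable angles)."""

    def __init__(self, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec("AEPQC")
        if self.spec.family != "AEPQC":
            raise ConfigError("AEPQC model requires an AEPQC spec")
        self.ops, self.param_labels = aepqc_ops()
        self.n_qubits = AEPQC_N_QUBITS
        self.readout = AEPQC_READOUT
        self.n_inputs = AEPQC_INPUT_LEN
        self.n_params = len(self.param_labels)
        if self.n_params != AEPQC_N_PARAMS:
            raise BuildVerificationError(
                f"AEPQC built with {self.n_params} trainable parameters, "
                f"expected {AEPQC_N_PARAMS}"
            )
        self._zd = [_engine.z_diag(self.n_qubits, r) for r in self.readout]

    def init_weights(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-INIT_SCALE, INIT_SCALE, size=self.n_params)

    def _embed(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[-1] != self.n_inputs:
            raise ShapeError(f"expected {self.n_inputs}-feature inputs, got {X.shape}")
        amp, _ = _amplitude_rows(X, 2 ** self.n_qubits)
        return amp, squeeze

    def forward(self, X: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Class scores (Z-expectations on wires 0 and 2) for scaled inputs."""
        psi0, squeeze = self._embed(X)
        w = self._check_w(w)
        psi = _engine.rt_forward(self.ops, self.n_qubits, psi0, w=w)
        scores = _engine.expect_z_batch(psi, self.readout, self.n_qubits)
        return scores[0] if squeeze else scores

    def forward_with_vjp(self, X: np.ndarray, w: np.ndarray):
        psi0, _ = self._embed(X)
        w = self._check_w(w)
        psi = _engine.rt_forward(self.ops, self.n_qubits, psi0, w=w)
        scores = _engine.expect_z_batch(psi, self.readout, self.n_qubits)

        def vjp(dscores: np.ndarray) -> np.ndarray:
            zc = dscores[..., 0:1] * self._zd[0] + dscores[..., 1:2] * self._zd[1]
            gw, _, _ = _engine.rt_vjp(
                self.ops, self.n_qubits, psi, zc, w=w, n_w=self.n_params
            )
            return gw

        return scores, vjp

    def _check_w(self, w) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_params,):
            raise ShapeError(f"expected {self.n_params} weights, got {w.shape}")
        return w

    def to_circuit(self, w) -> "object":
        """Concrete-parameter Circuit (for serialization / oracle checks)."""
        from .core import Circuit, GateSpec

        w = self._check_w(w)
        gates = []
        for op in self.ops:
            params = tuple(w[key] if src == "w" else key for src, key in op.params)
            gates.append(GateSpec(op.kind, op.wires, params))
        return Circuit(self.n_qubits, tuple(gates), self.readout)


# ---------------------------------------------------------------------------
# QCNN
# ---------------------------------------------------------------------------


class QCNN:
    """Quantum CNN: per-channel sliding 4-qubit kernel + fusion stage."""

    def __init__(self, spec: ModelSpec | None = None, **spec_kwargs):
        self.spec = spec or ModelSpec("QCNN", **spec_kwargs)
        if self.spec.family != "QCNN":
            raise ConfigError("QCNN model requires a QCNN spec")
        self.kernel_ops, kernel_labels, self.kernel_n_params = kernel_ops(self.spec.kernel)
        self.n_channels = self.spec.n_channels
        self.n_layers = self.spec.n_layers
        self.head_ops, head_labels = (c_head_ops() if self.spec.fusion == "c_head" else ([], []))
        self.head_n_params = HEAD_N_PARAMS if self.spec.fusion == "c_head" else 0
        if self.spec.fusion == "c_head" and 2 * self.n_channels > 2 ** HEAD_N_QUBITS:
            raise ConfigError("channel outputs exceed the head's amplitude capacity")

        self.param_labels = []
        for layer in range(self.n_layers):
            for ch in range(self.n_channels):
                self.param_labels.extend(
                    ("layer", layer, "channel", ch, lab) for lab in kernel_labels
                )
        self.param_labels.extend(("head", lab) for lab in head_labels)
        self.n_params = (
            self.n_layers * self.n_channels * self.kernel_n_params + self.head_n_params
        )
        self._zk = [_engine.z_diag(4, r) for r in KERNEL_READOUT]
        self._zh = [_engine.z_diag(HEAD_N_QUBITS, r) for r in HEAD_READOUT]

    # -- weight bookkeeping -------------------------------------------------

    def init_weights(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-INIT_SCALE, INIT_SCALE, size=self.n_params)

    def kernel_weights(self, w: np.ndarray, layer: int) -> np.ndarray:
        pk, c = self.kernel_n_params, self.n_channels
        block = w[layer * c * pk : (layer + 1) * c * pk]
        return block.reshape(c, 1, pk)

    def head_weights(self, w: np.ndarray) -> np.ndarray:
        return w[self.n_layers * self.n_channels * self.kernel_n_params :]

    def _check_w(self, w) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_params,):
            raise ShapeError(f"expected {self.n_params} weights, got {w.shape}")
        return w

    # -- sliding-kernel layers ----------------------------------------------

    @staticmethod
    def _positions(length: int) -> int:
        return (length - 4) // 2 + 1

    @staticmethod
    def _window_angles(Xl: np.ndarray) -> np.ndarray:
        pos = QCNN._positions(Xl.shape[-1])
        return np.stack([Xl[..., 2 * p : 2 * p + 4] for p in range(pos)], axis=-2)

    @staticmethod
    def _embed_vectors(A: np.ndarray) -> np.ndarray:
        """Per-qubit RY(|0>) factors of the product-state embedding."""
        return np.stack([np.cos(A / 2), np.sin(A / 2)], axis=-1)  # (..., 4, 2)

    @staticmethod
    def _product_state(V: np.ndarray) -> np.ndarray:
        psi = np.einsum(
            "...i,...j,...k,...l->...ijkl",
            V[..., 0, :], V[..., 1, :], V[..., 2, :], V[..., 3, :],
            optimize=True,
        )
        return psi.reshape(V.shape[:-2] + (16,))

    def _layer_forward(self, Xl: np.ndarray, wl: np.ndarray, with_cache: bool):
        """One convolutional layer. ``Xl`` (B, C, L) in [0, pi]; returns
        (B, C, L-2) outputs in [-1, 1] (position-major pairs of readouts)."""
        A = self._window_angles(Xl)  # (B, C, pos, 4)
        V = self._embed_vectors(A)
        psi0 = self._product_state(V)
        if with_cache:
            U, D = _engine.compile_unitary_and_derivs(self.kernel_ops, 4, wl)
        else:
            U, D = _engine.compile_unitary(self.kernel_ops, 4, wl), None
        psi = np.einsum("cij,bcpj->bcpi", U, psi0, optimize=True)
        probs = np.abs(psi) ** 2
        out = np.stack([probs @ z for z in self._zk], axis=-1)  # (B, C, pos, 2)
        flat = out.reshape(out.shape[:2] + (-1,))
        cache = (A, V, psi0, psi, U, D) if with_cache else None
        return flat, cache

    def _layer_vjp(self, d_flat: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray]:
        """Backward through one layer: returns (d_weights (C, Pk), d_Xl)."""
        A, V, psi0, psi, U, D = cache
        b, c, pos = A.shape[:3]
        d_out = d_flat.reshape(b, c, pos, 2)
        zc = d_out[..., 0:1] * self._zk[0] + d_out[..., 1:2] * self._zk[1]
        lam = zc * psi
        R = np.einsum("bcpi,bcpj->cij", np.conj(lam), psi0, optimize=True)
        gW = 2.0 * np.real(np.einsum("ckij,cij->ck", D, R, optimize=True))
        lamp = np.einsum("cji,bcpj->bcpi", np.conj(U), lam, optimize=True)
        L4 = np.conj(lamp).reshape(b, c, pos, 2, 2, 2, 2)
        dV = np.stack([-np.sin(A / 2) / 2, np.cos(A / 2) / 2], axis=-1)
        f = [V[..., q, :] for q in range(4)]
        df = [dV[..., q, :] for q in range(4)]
        # tree-structured contraction: share the partial products across qubits
        front = np.einsum("bcpwxyz,bcpy,bcpz->bcpwx", L4, f[2], f[3], optimize=True)
        back = np.einsum("bcpwxyz,bcpw,bcpx->bcpyz", L4, f[0], f[1], optimize=True)
        dA = np.empty_like(A)
        dA[..., 0] = 2.0 * np.real(np.einsum("bcpwx,bcpw,bcpx->bcp", front, df[0], f[1]))
        dA[..., 1] = 2.0 * np.real(np.einsum("bcpwx,bcpw,bcpx->bcp", front, f[0], df[1]))
        dA[..., 2] = 2.0 * np.real(np.einsum("bcpyz,bcpy,bcpz->bcp", back, df[2], f[3]))
        dA[..., 3] = 2.0 * np.real(np.einsum("bcpyz,bcpy,bcpz->bcp", back, f[2], df[3]))
        d_Xl = np.zeros(d_flat.shape[:2] + (2 * pos + 2,))
        for p in range(pos):
            d_Xl[..., 2 * p : 2 * p + 4] += dA[..., p, :]
        return gW, d_Xl

    # -- fusion stage ---------------------------------------------------------

    def _head_forward(self, cs: np.ndarray, wh: np.ndarray, with_cache: bool):
        x = cs.reshape(cs.shape[0], -1)  # channel-major flattening (C*2,)
        a, norms = _amplitude_rows(x, 2 ** HEAD_N_QUBITS)
        if with_cache:
            U, D = _engine.compile_unitary_and_derivs(self.head_ops, HEAD_N_QUBITS, wh)
        else:
            U, D = _engine.compile_unitary(self.head_ops, HEAD_N_QUBITS, wh), None
        psi = np.einsum("ij,bj->bi", U, a)
        probs = np.abs(psi) ** 2
        scores = np.stack([probs @ z for z in self._zh], axis=-1)
        cache = (x, a, norms, psi, U, D) if with_cache else None
        return scores, cache

    def _head_vjp(self, dscores: np.ndarray, cache):
        x, a, norms, psi, U, D = cache
        zc = dscores[..., 0:1] * self._zh[0] + dscores[..., 1:2] * self._zh[1]
        lam = zc * psi
        R = np.einsum("bi,bj->ij", np.conj(lam), a)
        gWh = 2.0 * np.real(np.einsum("kij,ij->k", D, R))
        lamp = np.einsum("ji,bj->bi", np.conj(U), lam)
        g_a = 2.0 * np.real(lamp)
        inner = np.sum(np.real(a) * g_a, axis=-1, keepdims=True)
        g_x = (g_a[..., : x.shape[-1]] - np.real(a[..., : x.shape[-1]]) * inner) / norms
        return gWh, g_x.reshape(dscores.shape[0], self.n_channels, 2)

    # -- full forward / backward ---------------------------------------------

    def _check_X(self, X) -> tuple[np.ndarray, bool]:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 2
        if squeeze:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != self.n_channels or X.shape[2] != self.spec.input_len:
            raise ShapeError(
                f"expected (batch, {self.n_channels}, {self.spec.input_len}) inputs, "
                f"got {np.asarray(X).shape}"
            )
        _check_angle_range(X)
        return X, squeeze

    def channel_scores(self, X, w) -> np.ndarray:
        """Per-channel 2-vector outputs after the last layer (pre-fusion)."""
        X, squeeze = self._check_X(X)
        w = self._check_w(w)
        cs = self._run_layers(X, w, with_cache=False)[0]
        return cs[0] if squeeze else cs

    def _run_layers(self, X, w, with_cache: bool):
        Xl = X
        caches = []
        for layer in range(self.n_layers):
            flat, cache = self._layer_forward(Xl, self.kernel_weights(w, layer), with_cache)
            caches.append(cache)
            if layer < self.n_layers - 1:
                Xl = (np.clip(flat, -1.0, 1.0) + 1.0) * (np.pi / 2)
        cs = flat.reshape(flat.shape[0], self.n_channels, 2)
        return cs, caches

    def forward(self, X, w) -> np.ndarray:
        X, squeeze = self._check_X(X)
        w = self._check_w(w)
        cs, _ = self._run_layers(X, w, with_cache=False)
        if self.spec.fusion == "c_head":
            scores, _ = self._head_forward(cs, self.head_weights(w), with_cache=False)
        else:
            scores = fuse(cs, self.spec.fusion)
        return scores[0] if squeeze else scores

    def forward_with_vjp(self, X, w):
        X, _ = self._check_X(X)
        w = self._check_w(w)
        cs, caches = self._run_layers(X, w, with_cache=True)
        if self.spec.fusion == "c_head":
            scores, head_cache = self._head_forward(cs, self.head_weights(w), with_cache=True)
        else:
            scores = fuse(cs, self.spec.fusion)
            head_cache = None

        def vjp(dscores: np.ndarray) -> np.ndarray:
            grad = np.zeros(self.n_params)
            if self.spec.fusion == "c_head":
                gWh, d_cs = self._head_vjp(dscores, head_cache)
                grad[self.n_layers * self.n_channels * self.kernel_n_params :] = gWh
            else:
                d_cs = _fuse_vjp(cs, dscores, self.spec.fusion)
            d_flat = d_cs.reshape(d_cs.shape[0], self.n_channels, 2)
            pk, c = self.kernel_n_params, self.n_channels
            for layer in range(self.n_layers - 1, -1, -1):
                gW, d_Xl = self._layer_vjp(
                    d_flat.reshape(d_flat.shape[0], c, -1), caches[layer]
                )
                grad[layer * c * pk : (layer + 1) * c * pk] = gW.reshape(-1)
                if layer > 0:
                    d_flat = d_Xl * (np.pi / 2)  # remap x -> (x+1)*pi/2
            return grad

        return scores, vjp


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


def fuse(channel_scores: np.ndarray, mode: str) -> np.ndarray:
    """Columnwise (per-class) reduction of (..., channels, 2) scores.

    ``avg`` = mean, ``max`` = maximum, ``amax`` = value of largest absolute
    magnitude with its sign preserved.
    """
    cs = np.asarray(channel_scores, dtype=float)
    if cs.ndim < 2 or cs.shape[-2] == 0:
        raise ContractError("channel scores must be a non-empty (..., C, K) array")
    if not np.all(np.isfinite(cs)):
        raise ContractError("channel scores must be finite")
    if mode == "avg":
        return cs.mean(axis=-2)
    if mode == "max":
        return cs.max(axis=-2)
    if mode == "amax":
        idx = np.abs(cs).argmax(axis=-2)
        return np.take_along_axis(cs, idx[..., None, :], axis=-2)[..., 0, :]
    raise ConfigError(f"unknown fusion mode {mode!r}")


def _fuse_vjp(cs: np.ndarray, dscores: np.ndarray, mode: str) -> np.ndarray:
    c = cs.shape[-2]
    if mode == "avg":
        return np.broadcast_to(dscores[..., None, :] / c, cs.shape).copy()
    if mode == "max":
        idx = cs.argmax(axis=-2)
    elif mode == "amax":
        idx = np.abs(cs).argmax(axis=-2)
    else:
        raise ConfigError(f"unknown fusion mode {mode!r}")
    d = np.zeros_like(cs)
    np.put_along_axis(d, idx[..., None, :], dscores[..., None, :], axis=-2)
    return d


# ---------------------------------------------------------------------------
# spec-level operations
# ---------------------------------------------------------------------------


def make_model(spec: ModelSpec):
    return AEPQC(spec) if spec.family == "AEPQC" else QCNN(spec)


def build_aepqc() -> AEPQC:
    """Build the AEPQC classifier; fails unless the parameter count is 112."""
    return AEPQC()


def count_params(spec: ModelSpec) -> int:
    """Exact number of trainable angles of an architecture."""
    return make_model(spec).n_params


def aepqc_forward(window_flat, weights) -> np.ndarray:
    """Class scores of the AEPQC for one (or a batch of) 250-vectors."""
    return build_aepqc().forward(window_flat, weights)


def kernel_forward(features_4, kernel_weights, kind: str = "K1") -> np.ndarray:
    """One application of a 4-qubit kernel to angle-embedded features.

    Runs the gate-by-gate engine (the reference path); the QCNN's sliding
    layers use the compiled equivalent.
    """
    f = np.asarray(features_4, dtype=float)
    if f.shape != (4,):
        raise ShapeError(f"expected 4 features, got {f.shape}")
    if np.any(f < 0) or np.any(f > np.pi):
        raise RangeError("kernel features must lie in [0, pi]")
    ops, _, n_params = kernel_ops(kind)
    w = np.asarray(kernel_weights, dtype=float)
    if w.shape != (n_params,):
        raise ShapeError(f"{kind} takes {n_params} weights, got {w.shape}")
    embed = [_engine.RtOp("RY", (q,), (("x", q),)) for q in range(4)]
    psi0 = np.zeros(16, dtype=complex)
    psi0[0] = 1.0
    psi = _engine.rt_forward(embed + ops, 4, psi0, w=w, x=f)
    return _engine.expect_z_batch(psi, KERNEL_READOUT, 4)


def qcnn_forward(trial_window, weights, kernel: str = "K1", fusion: str = "c_head") -> np.ndarray:
    """Class scores of the QCNN for one (or a batch of) channels x 10 windows."""
    X = np.asarray(trial_window, dtype=float)
    n_channels = X.shape[-2]
    model = QCNN(ModelSpec("QCNN", kernel=kernel, fusion=fusion, n_channels=n_channels))
    return model.forward(X, weights)


def c_head_forward(flat_54, head_weights) -> np.ndarray:
    """Class scores of the 6-qubit amplitude-embedding classification head."""
    x = np.asarray(flat_54, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[-1] != 54:
        raise ShapeError(f"expected 54 features (27 channels x 2), got {x.shape}")
    w = np.asarray(head_weights, dtype=float)
    if w.shape != (HEAD_N_PARAMS,):
        raise ShapeError(f"head takes {HEAD_N_PARAMS} weights, got {w.shape}")
    ops, _ = c_head_ops()
    a, _ = _amplitude_rows(x, 2 ** HEAD_N_QUBITS)
    psi = _engine.rt_forward(ops, HEAD_N_QUBITS, a, w=w)
    scores = _engine.expect_z_batch(psi, HEAD_READOUT, HEAD_N_QUBITS)
    return scores[0] if squeeze else scores


# ---------------------------------------------------------------------------
# save / load
# ---------------------------------------------------------------------------


def save_model(path, spec: ModelSpec, weights) -> Path:
    """Plain-text (JSON) model archive; weights round-trip bit-exactly."""
    path = Path(path)
    model = make_model(spec)
    w = np.asarray(weights, dtype=float)
    if w.shape != (model.n_params,):
        raise ShapeError(f"expected {model.n_params} weights, got {w.shape}")
    payload = {
        "spec": asdict(spec),
        "weights": [repr(float(v)) for v in w],
        "param_labels": [repr(lab) for lab in model.param_labels],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def load_model(path) -> tuple[ModelSpec, np.ndarray]:
    with open(path) as fh:
        payload = json.load(fh)
    spec = ModelSpec(**payload["spec"])
    w = np.asarray([float(v) for v in payload["weights"]], dtype=float)
    model = make_model(spec)
    if w.shape != (model.n_params,):
        raise ShapeError("weight vector does not match the spec's layout")
    return spec, w
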