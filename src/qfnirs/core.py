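"""Statevector simulation of the parameterized gate set.

The public surface covers the gate matrices (U3, RY, RZ, RX, CNOT,
IsingXX and the two-branch conditional U3 used for quantum pooling),
gate application, the two data embeddings (angle and amplitude),
Pauli-Z readout and adjoint-mode gradients of Z-expectations with
respect to the trainable gate angles.

Bit-order convention: qubit 0 is the most significant bit of the basis
index, i.e. ``|q0 q1 ... q_{n-1}>`` maps to index ``sum q_k 2**(n-1-k)``.
All angles are in radians.

Measurement-conditioned pooling is implemented by *deferred measurement*:
instead of collapsing the state, a controlled two-branch U3 is applied
(U3(branch 0) when the measured wire is |0>, U3(branch 1) when it is |1>).
For any later Z-expectation on other wires this is exactly equivalent to
explicitly collapsing into each outcome and probability-averaging, while
keeping the state pure and differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .errors import (
    CapacityError,
    ContractError,
    NormalizationError,
    RangeError,
)

NORM_ATOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantumState:
    """Pure n-qubit state as a complex amplitude vector of unit L2 norm."""

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self):
        amp = np.asarray(self.amplitudes, dtype=complex)
        object.__setattr__(self, "amplitudes", amp)
        if self.n_qubits < 1:
            raise ContractError("n_qubits must be positive")
        if amp.shape != (2 ** self.n_qubits,):
            raise ContractError(
                f"expected {2 ** self.n_qubits} amplitudes, got {amp.shape}"
            )
        norm = np.linalg.norm(amp)
        if abs(norm - 1.0) > NORM_ATOL:
            raise NormalizationError(f"state norm {norm} deviates from 1")

    @classmethod
    def zero(cls, n_qubits: int) -> "QuantumState":
        amp = np.zeros(2 ** n_qubits, dtype=complex)
        amp[0] = 1.0
        return cls(n_qubits, amp)


@dataclass(frozen=True)
class GateSpec:
    """A named parameterized gate bound to wires.

    ``trainable`` flags one entry per parameter; it defaults to all-True.
    """

    kind: str
    wires: tuple
    params: tuple = ()
    trainable: tuple = None

    def __post_init__(self):
        gd = _engine.check_known_kind(self.kind)
        object.__setattr__(self, "wires", tuple(int(w) for w in self.wires))
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        _engine.check_wires(self.wires, gd.arity)
        if len(self.params) != gd.n_params:
            raise ContractError(
                f"{self.kind} takes {gd.n_params} parameters, got {len(self.params)}"
            )
        tr = self.trainable
        if tr is None:
            tr = (True,) * gd.n_params
        tr = tuple(bool(t) for t in tr)
        if len(tr) != gd.n_params:
            raise ContractError("trainable mask length mismatch")
        object.__setattr__(self, "trainable", tr)

    @property
    def arity(self) -> int:
        return _engine.GATES[self.kind].arity


@dataclass(frozen=True)
class Circuit:
    """Ordered gate list with designated Pauli-Z readout wires."""

    n_qubits: int
    gates: tuple = ()
    readout: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "gates", tuple(self.gates))
        object.__setattr__(self, "readout", tuple(int(w) for w in self.readout))
        for g in self.gates:
            _engine.check_wires(g.wires, g.arity, self.n_qubits)
        if len(set(self.readout)) != len(self.readout):
            raise ContractError("readout wires must be distinct")
        for w in self.readout:
            if not 0 <= w < self.n_qubits:
                raise ContractError(f"readout wire {w} out of range")

    @property
    def n_trainable(self) -> int:
        return sum(sum(g.trainable) for g in self.gates)

    def trainable_params(self) -> np.ndarray:
        vals = []
        for g in self.gates:
            vals.extend(p for p, t in zip(g.params, g.trainable) if t)
        return np.asarray(vals, dtype=float)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def gate_matrix(spec: GateSpec) -> np.ndarray:
    """Closed-form unitary matrix (2x2 or 4x4) of a gate."""
    gd = _engine.GATES[spec.kind]
    if gd.n_params == 0:
        return gd.mat()
    return gd.mat(*spec.params)


def apply_gate(state: QuantumState, spec: GateSpec) -> QuantumState:
    """Contract the gate into the statevector."""
    _engine.check_wires(spec.wires, spec.arity, state.n_qubits)
    amp = _engine.apply_gate_mat(
        state.amplitudes, gate_matrix(spec), spec.wires, state.n_qubits
    )
    return QuantumState(state.n_qubits, amp)


def run_circuit(circuit: Circuit, state: QuantumState | None = None) -> QuantumState:
    """Apply all gates of a circuit to ``state`` (default ``|0...0>``)."""
    st = state if state is not None else QuantumState.zero(circuit.n_qubits)
    for g in circuit.gates:
        st = apply_gate(st, g)
    return st


def angle_embed(features, n_qubits: int) -> QuantumState:
    """Encode one feature per qubit as an RY rotation angle.

    Inputs must lie in [0, pi]: the RY embedding is 2*pi-periodic, so a
    half-period range keeps distinct values distinguishable.
    """
    f = np.asarray(features, dtype=float)
    if f.shape != (n_qubits,):
        raise ContractError(f"expected {n_qubits} features, got shape {f.shape}")
    if np.any(f < 0) or np.any(f > np.pi):
        raise RangeError("angle-embedding features must lie in [0, pi]")
    st = QuantumState.zero(n_qubits)
    for w, val in enumerate(f):
        st = apply_gate(st, GateSpec("RY", (w,), (val,)))
    return st


def amplitude_embed(vector, n_qubits: int) -> tuple[QuantumState, int]:
    """Encode a real vector as normalized amplitudes, zero-padded at the tail.

    Returns the state and the number of padding values appended.
    """
    v = np.asarray(vector, dtype=float).ravel()
    dim = 2 ** n_qubits
    if v.size == 0 or v.size > dim:
        raise CapacityError(f"vector of length {v.size} does not fit {n_qubits} qubits")
    norm = np.linalg.norm(v)
    if norm == 0:
        raise NormalizationError("cannot amplitude-embed an all-zero vector")
    amp = np.zeros(dim, dtype=complex)
    amp[: v.size] = v / norm
    return QuantumState(n_qubits, amp), dim - v.size


def expect_z(state: QuantumState, wire: int) -> float:
    """Born-rule Pauli-Z expectation on ``wire``; always in [-1, 1]."""
    if not 0 <= wire < state.n_qubits:
        raise ContractError(f"wire {wire} out of range")
    probs = np.abs(state.amplitudes) ** 2
    return float(probs @ _engine.z_diag(state.n_qubits, wire))


def pool_conditional_u3(
    state: QuantumState,
    measured_wire: int,
    target_wire: int,
    branch_params,
) -> QuantumState:
    """Quantum pooling by deferred measurement.

    ``branch_params`` holds 6 angles: U3 parameters applied to the target
    when the measured wire reads |0>, then when it reads |1>. Downstream
    Z-expectations on wires other than ``measured_wire`` equal the
    probability-weighted average over explicit collapse into each outcome.
    """
    if measured_wire == target_wire:
        raise ContractError("measured and target wires must differ")
    bp = tuple(float(p) for p in np.asarray(branch_params, dtype=float).ravel())
    if len(bp) != 6:
        raise ContractError("pooling takes 3+3 branch parameters")
    return apply_gate(state, GateSpec("COND_U3", (measured_wire, target_wire), bp))


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------


def _circuit_ops_and_weights(circuit: Circuit, weights=None):
    """Lower a Circuit to runtime ops with trainable params pulled from a vector."""
    ops = []
    w0 = []
    k = 0
    for g in circuit.gates:
        refs = []
        for p, t in zip(g.params, g.trainable):
            if t:
                refs.append(("w", k))
                w0.append(p)
                k += 1
            else:
                refs.append(("c", p))
        ops.append(_engine.RtOp(g.kind, g.wires, tuple(refs)))
    w = np.asarray(w0, dtype=float) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (k,):
        raise ContractError(f"expected {k} trainable parameters, got {w.shape}")
    return ops, w, k


def circuit_expectations(
    circuit: Circuit, weights=None, init_state: QuantumState | None = None
) -> np.ndarray:
    """Z-expectations on the readout wires, optionally overriding trainable params."""
    ops, w, _ = _circuit_ops_and_weights(circuit, weights)
    psi0 = (init_state or QuantumState.zero(circuit.n_qubits)).amplitudes
    psi = _engine.rt_forward(ops, circuit.n_qubits, psi0, w=w)
    return _engine.expect_z_batch(psi, circuit.readout, circuit.n_qubits)


def circuit_grad(
    circuit: Circuit,
    weights=None,
    init_state: QuantumState | None = None,
    cotangent=None,
):
    """Adjoint-mode gradient of the readout Z-expectations.

    Without ``cotangent`` returns ``(expvals, jac)`` with
    ``jac[r, k] = d<Z_r>/dw_k``; with a cotangent vector ``c`` returns
    ``(expvals, grad)`` where ``grad = d(sum_r c_r <Z_r>)/dw`` computed in
    a single backward pass. A circuit with no trainable parameters yields
    an empty gradient.
    """
    ops, w, n_w = _circuit_ops_and_weights(circuit, weights)
    n = circuit.n_qubits
    psi0 = (init_state or QuantumState.zero(n)).amplitudes
    psi = _engine.rt_forward(ops, n, psi0, w=w)
    vals = _engine.expect_z_batch(psi, circuit.readout, n)
    diags = [_engine.z_diag(n, r) for r in circuit.readout]
    if cotangent is not None:
        ct = np.asarray(cotangent, dtype=float)
        if ct.shape != (len(circuit.readout),):
            raise ContractError("cotangent length must match readout count")
        zc = sum(c * d for c, d in zip(ct, diags))
        gw, _, _ = _engine.rt_vjp(ops, n, psi, zc, w=w, n_w=n_w)
        return vals, (gw if n_w else np.zeros(0))
    jac = np.zeros((len(circuit.readout), n_w))
    for r, d in enumerate(diags):
        gw, _, _ = _engine.rt_vjp(ops, n, psi, d, w=w, n_w=n_w)
        if n_w:
            jac[r] = gw
    return vals, jac


# ---------------------------------------------------------------------------
# plain-text serialization (debugging / fixtures)
# ---------------------------------------------------------------------------


def circuit_to_text(circuit: Circuit) -> str:
    lines = [f"qubits {circuit.n_qubits}"]
    lines.append("readout " + (" ".join(str(w) for w in circuit.readout) or "-"))
    for g in circuit.gates:
        wires = ",".join(str(w) for w in g.wires)
        params = ",".join(repr(p) for p in g.params) or "-"
        mask = "".join("1" if t else "0" for t in g.trainable) or "-"
        lines.append(f"{g.kind} {wires} {params} {mask}")
    return "\n".join(lines) + "\n"


def circuit_from_text(text: str) -> Circuit:
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("qubits "):
        raise ContractError("circuit text must start with a 'qubits <n>' line")
    n = int(lines[0].split()[1])
    ro = lines[1].split()[1:]
    readout = () if ro == ["-"] else tuple(int(w) for w in ro)
    gates = []
    for ln in lines[2:]:
        kind, wires_s, params_s, mask_s = ln.split()
        wires = tuple(int(w) for w in wires_s.split(","))
        params = () if params_s == "-" else tuple(float(p) for p in params_s.split(","))
        mask = None if mask_s == "-" else tuple(c == "1" for c in mask_s)
        gates.append(GateSpec(kind, wires, params, mask))
    return Circuit(n, tuple(gates), readout)
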