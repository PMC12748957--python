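"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: dense Kronecker-product unitaries,
explicit basis-index bookkeeping, central finite differences and
explicit measurement collapse. These implementations share no code with
the package's engine (which contracts gates into the statevector and
differentiates in adjoint mode).
"""

import numpy as np

from qfnirs.core import Circuit, GateSpec, gate_matrix


def dense_1q(mat: np.ndarray, wire: int, n: int) -> np.ndarray:
    """Identity-Kronecker expansion of a 2x2 gate (qubit 0 = MSB)."""
    return np.kron(np.kron(np.eye(2 ** wire), mat), np.eye(2 ** (n - wire - 1)))


def dense_2q(mat4: np.ndarray, wires, n: int) -> np.ndarray:
    """Dense expansion of a 4x4 gate on arbitrary (ordered) wires."""
    w1, w2 = wires
    dim = 2 ** n
    full = np.zeros((dim, dim), dtype=complex)
    for col in range(dim):
        bits = [(col >> (n - 1 - q)) & 1 for q in range(n)]
        a, b = bits[w1], bits[w2]
        for sub in range(4):
            na, nb = sub >> 1, sub & 1
            amp = mat4[sub, a * 2 + b]
            if amp == 0:
                continue
            nbits = list(bits)
            nbits[w1], nbits[w2] = na, nb
            row = sum(bit << (n - 1 - q) for q, bit in enumerate(nbits))
            full[row, col] += amp
    return full


def dense_gate(spec: GateSpec, n: int) -> np.ndarray:
    m = gate_matrix(spec)
    if len(spec.wires) == 1:
        return dense_1q(m, spec.wires[0], n)
    return dense_2q(m, spec.wires, n)


def dense_circuit_unitary(circuit: Circuit) -> np.ndarray:
    u = np.eye(2 ** circuit.n_qubits, dtype=complex)
    for g in circuit.gates:
        u = dense_gate(g, circuit.n_qubits) @ u
    return u


def dense_expect_z(amplitudes: np.ndarray, wire: int, n: int) -> float:
    """<psi| Z_wire |psi> via the dense observable sandwich."""
    z = dense_1q(np.diag([1.0, -1.0]), wire, n)
    return float(np.real(np.conj(amplitudes) @ z @ amplitudes))


def fd_grad(f, params: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central finite differences of a scalar function of a flat vector."""
    params = np.asarray(params, dtype=float)
    g = np.zeros_like(params)
    for i in range(params.size):
        p = params.copy()
        p[i] += eps
        hi = f(p)
        p[i] -= 2 * eps
        g[i] = (hi - f(p)) / (2 * eps)
    return g


def collapse_pool_expect_z(
    amplitudes: np.ndarray,
    n: int,
    measured: int,
    target: int,
    branch0,
    branch1,
    obs_wire: int,
) -> float:
    """Explicit two-branch collapse-and-average pooling oracle.

    Projects the measured wire onto each outcome, applies that branch's
    U3 to the (renormalized) collapsed state, and returns the
    probability-weighted Z-expectation on ``obs_wire``.
    """
    total = 0.0
    for outcome, branch in ((0, branch0), (1, branch1)):
        proj = np.diag([1.0, 0.0] if outcome == 0 else [0.0, 1.0])
        collapsed = dense_1q(proj, measured, n) @ amplitudes
        prob = float(np.real(np.conj(collapsed) @ collapsed))
        if prob == 0.0:
            continue
        collapsed = collapsed / np.sqrt(prob)
        u = dense_1q(gate_matrix(GateSpec("U3", (target,), tuple(branch))), target, n)
        total += prob * dense_expect_z(u @ collapsed, obs_wire, n)
    return total


def random_state(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=2 ** n) + 1j * rng.normal(size=2 ** n)
    return v / np.linalg.norm(v)


GATE_POOL = ("U3", "RY", "RZ", "RX", "IsingXX", "CNOT", "COND_U3")


def random_gate(rng: np.random.Generator, n: int, kinds=GATE_POOL) -> GateSpec:
    if n < 2:
        kinds = tuple(k for k in kinds if k in ("U3", "RY", "RZ", "RX"))
    kind = kinds[rng.integers(len(kinds))]
    n_params = {"U3": 3, "RY": 1, "RZ": 1, "RX": 1, "IsingXX": 1, "CNOT": 0, "COND_U3": 6}[kind]
    arity = 1 if kind in ("U3", "RY", "RZ", "RX") else 2
    wires = tuple(rng.choice(n, size=arity, replace=False))
    params = tuple(rng.uniform(-np.pi, np.pi, size=n_params))
    return GateSpec(kind, wires, params)


def random_circuit(
    rng: np.random.Generator, n: int, n_gates: int, readout=None, kinds=GATE_POOL
) -> Circuit:
    gates = tuple(random_gate(rng, n, kinds) for _ in range(n_gates))
    if readout is None:
        readout = tuple(range(min(2, n)))
    return Circuit(n, gates, readout)
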