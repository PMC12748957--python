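"""Batched dense statevector primitives.

This module is internal. It implements gate matrices (with analytic
parameter derivatives), application of 1- and 2-qubit gates to batched
amplitude vectors, an adjoint-mode differentiation pass, and compilation
of small circuits into explicit unitaries (used by the model fast paths).

Conventions
-----------
* Qubit 0 is the *most significant* bit of the computational basis index,
  so reshaping an amplitude vector to ``(2,) * n`` puts qubit ``k`` on
  tensor axis ``k``.
* States are arrays of shape ``batch_shape + (2**n,)``; any number of
  leading batch axes is allowed and gate matrices broadcast against them.
* Parameter derivatives follow directly from the closed-form matrices:
  for a gate ``M(theta)`` the returned ``dM`` is the elementwise
  derivative, so ``d<Z>/dtheta = 2 Re <lam| dM |psi>`` in the adjoint
  pass below.
"""

from __future__ import annotations

from typing import Callable, NamedTuple, Sequence

import numpy as np

from .errors import ContractError, UnsupportedGateError

# ---------------------------------------------------------------------------
# gate matrices (batched over the leading dims of the angle arrays)
# ---------------------------------------------------------------------------


def _mat2(a, b, c, d) -> np.ndarray:
    a, b, c, d = np.broadcast_arrays(
        *[np.asarray(v, dtype=complex) for v in (a, b, c, d)]
    )
    return np.stack([np.stack([a, b], axis=-1), np.stack([c, d], axis=-1)], axis=-2)


def ry_mat(phi):
    c, s = np.cos(np.asarray(phi) / 2), np.sin(np.asarray(phi) / 2)
    return _mat2(c, -s, s, c)


def ry_dmat(phi):
    c, s = np.cos(np.asarray(phi) / 2) / 2, np.sin(np.asarray(phi) / 2) / 2
    return (_mat2(-s, -c, c, -s),)


def rz_mat(phi):
    e = np.exp(-1j * np.asarray(phi) / 2)
    z = np.zeros_like(e)
    return _mat2(e, z, z, np.conj(e))


def rz_dmat(phi):
    e = np.exp(-1j * np.asarray(phi) / 2)
    z = np.zeros_like(e)
    return (_mat2(-0.5j * e, z, z, 0.5j * np.conj(e)),)


def rx_mat(phi):
    c, s = np.cos(np.asarray(phi) / 2), np.sin(np.asarray(phi) / 2)
    return _mat2(c, -1j * s, -1j * s, c)


def rx_dmat(phi):
    c, s = np.cos(np.asarray(phi) / 2) / 2, np.sin(np.asarray(phi) / 2) / 2
    return (_mat2(-s, -1j * c, -1j * c, -s),)


def u3_mat(theta, phi, delta):
    c, s = np.cos(np.asarray(theta) / 2), np.sin(np.asarray(theta) / 2)
    ep, ed = np.exp(1j * np.asarray(phi)), np.exp(1j * np.asarray(delta))
    return _mat2(c, -ed * s, ep * s, ed * ep * c)


def u3_dmat(theta, phi, delta):
    c, s = np.cos(np.asarray(theta) / 2), np.sin(np.asarray(theta) / 2)
    ep, ed = np.exp(1j * np.asarray(phi)), np.exp(1j * np.asarray(delta))
    z = np.zeros_like(ep)
    d_theta = _mat2(-s / 2, -ed * c / 2, ep * c / 2, -ed * ep * s / 2)
    d_phi = _mat2(z, z, 1j * ep * s, 1j * ed * ep * c)
    d_delta = _mat2(z, -1j * ed * s, z, 1j * ed * ep * c)
    return (d_theta, d_phi, d_delta)


def _mat4_from_blocks(shape, assign: Callable[[np.ndarray], None]) -> np.ndarray:
    out = np.zeros(shape + (4, 4), dtype=complex)
    assign(out)
    return out


def xx_mat(phi):
    phi = np.asarray(phi)
    c = np.cos(phi / 2)
    m = -1j * np.sin(phi / 2)

    def fill(out):
        for i in range(4):
            out[..., i, i] = c
            out[..., i, 3 - i] = m

    return _mat4_from_blocks(np.shape(phi), fill)


def xx_dmat(phi):
    phi = np.asarray(phi)
    c = -np.sin(phi / 2) / 2
    m = -0.5j * np.cos(phi / 2)

    def fill(out):
        for i in range(4):
            out[..., i, i] = c
            out[..., i, 3 - i] = m

    return (_mat4_from_blocks(np.shape(phi), fill),)


def cnot_mat():
    m = np.zeros((4, 4), dtype=complex)
    m[0, 0] = m[1, 1] = 1.0
    m[2, 3] = m[3, 2] = 1.0
    return m


def cond_u3_mat(t0, p0, d0, t1, p1, d1):
    """Two-branch controlled U3 on wires (measured, target).

    Block-diagonal: U3(branch 0) acts on the target when the measured wire
    is |0>, U3(branch 1) when it is |1>. This is the deferred-measurement
    form of measurement-conditioned pooling and is unitary.
    """
    b0 = u3_mat(t0, p0, d0)
    b1 = u3_mat(t1, p1, d1)
    shape = np.broadcast_shapes(b0.shape[:-2], b1.shape[:-2])

    def fill(out):
        out[..., :2, :2] = b0
        out[..., 2:, 2:] = b1

    return _mat4_from_blocks(shape, fill)


def cond_u3_dmat(t0, p0, d0, t1, p1, d1):
    d_b0 = u3_dmat(t0, p0, d0)
    d_b1 = u3_dmat(t1, p1, d1)
    shape = np.broadcast_shapes(d_b0[0].shape[:-2], d_b1[0].shape[:-2])
    out = []
    for db in d_b0:
        out.append(_mat4_from_blocks(shape, lambda o, db=db: o.__setitem__((..., slice(0, 2), slice(0, 2)), db)))
    for db in d_b1:
        out.append(_mat4_from_blocks(shape, lambda o, db=db: o.__setitem__((..., slice(2, 4), slice(2, 4)), db)))
    return tuple(out)


class GateDef(NamedTuple):
    arity: int
    n_params: int
    mat: Callable[..., np.ndarray]
    dmat: Callable[..., tuple] | None


GATES: dict[str, GateDef] = {
    "U3": GateDef(1, 3, u3_mat, u3_dmat),
    "RY": GateDef(1, 1, ry_mat, ry_dmat),
    "RZ": GateDef(1, 1, rz_mat, rz_dmat),
    "RX": GateDef(1, 1, rx_mat, rx_dmat),
    "IsingXX": GateDef(2, 1, xx_mat, xx_dmat),
    "CNOT": GateDef(2, 0, lambda: cnot_mat(), None),
    "COND_U3": GateDef(2, 6, cond_u3_mat, cond_u3_dmat),
}


# ---------------------------------------------------------------------------
# batched gate application
# ---------------------------------------------------------------------------


def apply_1q(psi: np.ndarray, mat: np.ndarray, wire: int, n: int) -> np.ndarray:
    """Apply a (batched) 2x2 matrix to ``wire`` of ``psi`` (..., 2**n)."""
    b = psi.shape[:-1]
    a, c = 2 ** wire, 2 ** (n - wire - 1)
    t = psi.reshape(b + (a, 2, c))
    out = np.einsum("...ij,...ajc->...aic", mat, t)
    return out.reshape(out.shape[:-3] + (2 ** n,))


def apply_2q(psi: np.ndarray, mat: np.ndarray, wires: Sequence[int], n: int) -> np.ndarray:
    """Apply a (batched) 4x4 matrix to ordered ``wires`` of ``psi``.

    The first wire indexes the more significant bit of the 4x4 block
    (control for CNOT, measured wire for COND_U3).
    """
    w1, w2 = wires
    b = psi.shape[:-1]
    nb = len(b)
    t = psi.reshape(b + (2,) * n)
    t = np.moveaxis(t, (nb + w1, nb + w2), (nb + n - 2, nb + n - 1))
    t = t.reshape(b + (2 ** (n - 2), 4))
    t = np.einsum("...ij,...aj->...ai", mat, t)
    bb = t.shape[:-2]  # broadcasted batch
    nbb = len(bb)
    t = t.reshape(bb + (2,) * n)
    t = np.moveaxis(t, (nbb + n - 2, nbb + n - 1), (nbb + w1, nbb + w2))
    return np.ascontiguousarray(t.reshape(bb + (2 ** n,)))


def apply_gate_mat(psi, mat, wires, n):
    if len(wires) == 1:
        return apply_1q(psi, mat, wires[0], n)
    return apply_2q(psi, mat, wires, n)


# ---------------------------------------------------------------------------
# runtime ops: gates whose parameters are drawn from weight / input vectors
# ---------------------------------------------------------------------------


class RtOp(NamedTuple):
    """One gate in a runtime circuit.

    ``params`` is a tuple of ``(src, key)`` pairs, one per gate parameter:
    ``("w", i)`` reads weight ``i``, ``("x", i)`` reads input feature ``i``
    and ``("c", value)`` is a fixed constant (not differentiated).
    """

    kind: str
    wires: tuple
    params: tuple = ()


def _resolve(op: RtOp, w, x):
    vals = []
    for src, key in op.params:
        if src == "w":
            vals.append(w[..., key])
        elif src == "x":
            vals.append(x[..., key])
        else:
            vals.append(np.asarray(key, dtype=float))
    return vals


def _op_mat(op: RtOp, w, x):
    gd = GATES[op.kind]
    if gd.n_params == 0:
        return gd.mat()
    return gd.mat(*_resolve(op, w, x))


def rt_forward(ops: Sequence[RtOp], n: int, psi0: np.ndarray, w=None, x=None) -> np.ndarray:
    psi = psi0
    for op in ops:
        psi = apply_gate_mat(psi, _op_mat(op, w, x), op.wires, n)
    return psi


def z_diag(n: int, wire: int) -> np.ndarray:
    """Diagonal of the Pauli-Z observable on ``wire`` (+1 / -1 per basis state)."""
    idx = np.arange(2 ** n)
    bit = (idx >> (n - 1 - wire)) & 1
    return 1.0 - 2.0 * bit


def expect_z_batch(psi: np.ndarray, wires: Sequence[int], n: int) -> np.ndarray:
    probs = np.abs(psi) ** 2
    return np.stack([probs @ z_diag(n, w) for w in wires], axis=-1)


def _reduce_to(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` over broadcast axes so the result has batch shape ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def rt_vjp(
    ops: Sequence[RtOp],
    n: int,
    psi_final: np.ndarray,
    zc: np.ndarray,
    w=None,
    x=None,
    n_w: int = 0,
    n_x: int = 0,
):
    """Adjoint-mode VJP through a runtime circuit.

    ``zc`` is the diagonal of the (Hermitian, real-diagonal) observable
    whose expectation is being differentiated — typically a cotangent-
    weighted sum of Pauli-Z diagonals, batched like ``psi_final``.

    Returns ``(gw, gx, lam0)`` where ``gw`` has shape
    ``w.shape[:-1] + (n_w,)`` (gradients summed over broadcast batch axes),
    ``gx`` has shape ``x.shape[:-1] + (n_x,)`` and ``lam0`` is the
    back-propagated observable vector at the circuit input, so the gradient
    of the expectation with respect to a *real* initial state is
    ``2 * Re(lam0)``.
    """
    lam = zc * psi_final
    psi = psi_final
    w_bshape = () if w is None else np.asarray(w).shape[:-1]
    x_bshape = () if x is None else np.asarray(x).shape[:-1]
    gw = np.zeros(w_bshape + (n_w,)) if n_w else None
    gx = np.zeros(x_bshape + (n_x,)) if n_x else None

    for op in reversed(ops):
        gd = GATES[op.kind]
        mat = _op_mat(op, w, x)
        mdag = np.conj(np.swapaxes(mat, -1, -2))
        psi = apply_gate_mat(psi, mdag, op.wires, n)
        if gd.n_params:
            needs = [src in ("w", "x") for src, _ in op.params]
            if any(needs):
                dmats = gd.dmat(*_resolve(op, w, x))
                for j, (src, key) in enumerate(op.params):
                    if not needs[j]:
                        continue
                    dv = apply_gate_mat(psi, dmats[j], op.wires, n)
                    g = 2.0 * np.real(np.sum(np.conj(lam) * dv, axis=-1))
                    if src == "w":
                        gw[..., key] += _reduce_to(g, w_bshape)
                    else:
                        gx[..., key] += _reduce_to(g, x_bshape)
        lam = apply_gate_mat(lam, mdag, op.wires, n)

    return gw, gx, lam


# ---------------------------------------------------------------------------
# circuit compilation (model fast paths)
# ---------------------------------------------------------------------------


def compile_unitary(ops: Sequence[RtOp], n: int, w=None, x=None) -> np.ndarray:
    """Full ``2**n x 2**n`` unitary of a runtime circuit.

    Batch axes of ``w`` broadcast into leading axes of the result; ``w``
    must be shaped so its batch dims do not collide with the internal
    basis-state batch (e.g. pass per-channel weights as ``(C, 1, P)``).
    """
    dim = 2 ** n
    eye = np.eye(dim, dtype=complex)
    res = rt_forward(ops, n, eye, w, x)  # res[..., j, :] = U e_j
    return np.swapaxes(res, -1, -2)


def compile_unitary_and_derivs(ops: Sequence[RtOp], n: int, w) -> tuple[np.ndarray, np.ndarray]:
    """Compile a weight-only circuit into ``U`` and per-parameter ``D_k``.

    ``D_k = dU/dw_k`` is assembled from prefix/suffix products, so the
    adjoint reduces to a single trace against a batch-accumulated outer
    product. ``w`` must carry an explicit broadcast axis for the basis
    batch, e.g. shape ``(C, 1, P)``; outputs are ``U: (C, dim, dim)`` and
    ``D: (C, P, dim, dim)``.
    """
    dim = 2 ** n
    bshape = tuple(s for s in np.asarray(w).shape[:-1] if s != 1)
    n_w = np.asarray(w).shape[-1]
    eye = np.eye(dim, dtype=complex)

    fulls, dfulls = [], []
    for op in ops:
        gd = GATES[op.kind]
        mat = _op_mat(op, w, None)
        fulls.append(np.swapaxes(apply_gate_mat(eye, mat, op.wires, n), -1, -2))
        entry = []
        if gd.n_params:
            dmats = gd.dmat(*_resolve(op, w, None))
            for j, (src, key) in enumerate(op.params):
                if src == "w":
                    entry.append(
                        (key, np.swapaxes(apply_gate_mat(eye, dmats[j], op.wires, n), -1, -2))
                    )
        dfulls.append(entry)

    L = len(ops)
    prefixes = [np.broadcast_to(eye, bshape + (dim, dim)).copy()]
    for k in range(L):
        prefixes.append(fulls[k] @ prefixes[k])
    U = prefixes[L]
    suffix = np.broadcast_to(eye, bshape + (dim, dim)).copy()
    D = np.zeros(bshape + (n_w, dim, dim), dtype=complex)
    for k in range(L - 1, -1, -1):
        for key, dfull in dfulls[k]:
            D[..., key, :, :] += suffix @ dfull @ prefixes[k]
        suffix = suffix @ fulls[k]
    return U, D


def check_known_kind(kind: str) -> GateDef:
    if kind not in GATES:
        raise UnsupportedGateError(f"unknown gate kind {kind!r}")
    return GATES[kind]


def check_wires(wires: Sequence[int], arity: int, n_qubits: int | None = None):
    if len(wires) != arity or len(set(wires)) != len(wires):
        raise ContractError(f"expected {arity} distinct wires, got {tuple(wires)}")
    for wr in wires:
        if wr < 0 or (n_qubits is not None and wr >= n_qubits):
            raise ContractError(f"wire {wr} out of range for {n_qubits} qubits")
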