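"""Quantum core: gate matrices, statevector application, embeddings,
readout, pooling and adjoint gradients — all checked against dense
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qfnirs as qf
from qfnirs import core
from qfnirs.errors import (
    CapacityError,
    ContractError,
    NormalizationError,
    RangeError,
    UnsupportedGateError,
)

from .oracles import (
    collapse_pool_expect_z,
    dense_circuit_unitary,
    dense_expect_z,
    fd_grad,
    random_circuit,
    random_gate,
    random_state,
)

INV2 = 1.0 / np.sqrt(2.0)


# ---------------------------------------------------------------------------
# gate matrices
# ---------------------------------------------------------------------------


class TestGateMatrix:
    def test_u3_zero_angles_is_identity(self):
        m = qf.gate_matrix(qf.GateSpec("U3", (0,), (0.0, 0.0, 0.0)))
        assert np.allclose(m, np.eye(2), atol=1e-15)

    def test_ry_half_pi_creates_equal_superposition(self):
        m = qf.gate_matrix(qf.GateSpec("RY", (0,), (np.pi / 2,)))
        assert np.allclose(m @ [1, 0], [INV2, INV2], atol=1e-12)

    def test_isingxx_pi_maps_00_to_minus_i_11(self):
        st0 = qf.QuantumState.zero(2)
        out = qf.apply_gate(st0, qf.GateSpec("IsingXX", (0, 1), (np.pi,)))
        expected = np.array([0, 0, 0, -1j])
        assert np.allclose(out.amplitudes, expected, atol=1e-12)

    def test_closed_form_entries(self):
        th, ph, de = 0.8, -0.5, 1.3
        m = qf.gate_matrix(qf.GateSpec("U3", (0,), (th, ph, de)))
        c, s = np.cos(th / 2), np.sin(th / 2)
        ref = np.array(
            [[c, -np.exp(1j * de) * s],
             [np.exp(1j * ph) * s, np.exp(1j * (de + ph)) * c]]
        )
        assert np.allclose(m, ref, atol=1e-15)
        mz = qf.gate_matrix(qf.GateSpec("RZ", (0,), (ph,)))
        assert np.allclose(np.diag(mz), [np.exp(-1j * ph / 2), np.exp(1j * ph / 2)])
        mx = qf.gate_matrix(qf.GateSpec("RX", (0,), (th,)))
        assert np.allclose(mx[0, 1], -1j * s) and np.allclose(mx[0, 0], c)
        cnot = qf.gate_matrix(qf.GateSpec("CNOT", (0, 1)))
        assert np.allclose(cnot[2:, 2:], [[0, 1], [1, 0]])
        assert np.allclose(cnot[:2, :2], np.eye(2))

    def test_every_gate_is_unitary_at_random_angles(self, rng):
        for _ in range(100):
            g = random_gate(rng, 2)
            m = qf.gate_matrix(g)
            assert np.abs(m @ m.conj().T - np.eye(m.shape[0])).max() <= 1e-12

    def test_unknown_kind_and_bad_param_count(self):
        with pytest.raises(UnsupportedGateError):
            qf.GateSpec("HADAMARD", (0,))
        with pytest.raises(ContractError):
            qf.GateSpec("RY", (0,), (0.1, 0.2))
        with pytest.raises(ContractError):
            qf.GateSpec("CNOT", (0, 0))


# ---------------------------------------------------------------------------
# gate application vs dense oracle
# ---------------------------------------------------------------------------


class TestApplyGate:
    def test_cnot_flips_target_when_control_set(self):
        amp = np.zeros(4)
        amp[2] = 1.0  # |10>
        out = qf.apply_gate(qf.QuantumState(2, amp), qf.GateSpec("CNOT", (0, 1)))
        assert np.allclose(out.amplitudes, [0, 0, 0, 1])

    def test_norm_preserved_over_long_random_circuit(self, rng):
        st = qf.QuantumState(3, random_state(rng, 3))
        for _ in range(50):
            st = qf.apply_gate(st, random_gate(rng, 3))
        assert abs(np.linalg.norm(st.amplitudes) - 1.0) <= 1e-10

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_engine_matches_dense_kronecker_oracle(self, rng, n):
        for _ in range(10):
            circ = random_circuit(rng, n, n_gates=12)
            psi0 = random_state(rng, n)
            st = qf.QuantumState(n, psi0)
            for g in circ.gates:
                st = qf.apply_gate(st, g)
            ref = dense_circuit_unitary(circ) @ psi0
            assert np.abs(st.amplitudes - ref).max() <= 1e-10

    def test_wire_out_of_range(self):
        with pytest.raises(ContractError):
            qf.apply_gate(qf.QuantumState.zero(2), qf.GateSpec("RY", (2,), (0.1,)))


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------


class TestEmbeddings:
    def test_angle_embed_zero_features_gives_ground_state(self):
        st = qf.angle_embed(np.zeros(3), 3)
        assert np.allclose(st.amplitudes, qf.QuantumState.zero(3).amplitudes)

    def test_angle_embed_pi_gives_excited_state_up_to_sign(self):
        st = qf.angle_embed([np.pi], 1)
        assert np.allclose(np.abs(st.amplitudes), [0, 1], atol=1e-12)

    def test_angle_embed_equals_ry_chain(self, rng):
        f = rng.uniform(0, np.pi, size=4)
        st = qf.angle_embed(f, 4)
        chain = qf.QuantumState.zero(4)
        for w, v in enumerate(f):
            chain = qf.apply_gate(chain, qf.GateSpec("RY", (w,), (v,)))
        assert np.abs(st.amplitudes - chain.amplitudes).max() <= 1e-12

    def test_angle_embed_rejects_out_of_range(self):
        with pytest.raises(RangeError):
            qf.angle_embed([0.1, -0.2, 0.3], 3)
        with pytest.raises(RangeError):
            qf.angle_embed([0.1, np.pi + 0.2, 0.3], 3)

    @pytest.mark.parametrize(
        "length,n_qubits,pad",
        [(250, 8, 6), (54, 6, 10), (4, 2, 0)],
    )
    def test_amplitude_embed_pad_counts(self, length, n_qubits, pad):
        st, pad_count = qf.amplitude_embed(np.ones(length), n_qubits)
        assert pad_count == pad
        assert abs(np.linalg.norm(st.amplitudes) - 1.0) <= 1e-12

    def test_amplitude_embed_normalizes(self):
        st, _ = qf.amplitude_embed([1.0, 1.0, 1.0, 1.0], 2)
        assert np.allclose(st.amplitudes, [0.5, 0.5, 0.5, 0.5])

    def test_amplitude_embed_errors(self):
        with pytest.raises(NormalizationError):
            qf.amplitude_embed(np.zeros(4), 2)
        with pytest.raises(CapacityError):
            qf.amplitude_embed(np.ones(5), 2)

    @given(st.lists(st.floats(0, np.pi), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=30)
    def test_angle_embed_norm_is_one(self, feats):
        state = qf.angle_embed(feats, 3)
        assert abs(np.linalg.norm(state.amplitudes) - 1.0) <= 1e-9


# ---------------------------------------------------------------------------
# readout
# ---------------------------------------------------------------------------


class TestExpectZ:
    def test_computational_basis(self):
        assert qf.expect_z(qf.QuantumState.zero(1), 0) == pytest.approx(1.0)
        amp = np.array([0.0, 1.0])
        assert qf.expect_z(qf.QuantumState(1, amp), 0) == pytest.approx(-1.0)

    def test_equal_superposition_is_zero(self):
        st = qf.QuantumState(1, np.array([INV2, INV2]))
        assert qf.expect_z(st, 0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_observable_sandwich(self, rng):
        for _ in range(20):
            amp = random_state(rng, 3)
            st = qf.QuantumState(3, amp)
            for w in range(3):
                assert qf.expect_z(st, w) == pytest.approx(
                    dense_expect_z(amp, w, 3), abs=1e-12
                )
            assert -1.0 <= qf.expect_z(st, 0) <= 1.0


# ---------------------------------------------------------------------------
# pooling (deferred measurement)
# ---------------------------------------------------------------------------


class TestPooling:
    def test_identity_branches_leave_state_unchanged(self, rng):
        amp = random_state(rng, 3)
        out = qf.pool_conditional_u3(qf.QuantumState(3, amp), 1, 0, np.zeros(6))
        assert np.abs(out.amplitudes - amp).max() <= 1e-12

    def test_definite_outcome_equals_unconditional_branch(self, rng):
        # measured wire pinned to |1>: pooling == plain U3(branch 1) on target
        b1 = rng.uniform(-np.pi, np.pi, 3)
        full = np.kron([0.0, 1.0], random_state(rng, 2))
        st = qf.QuantumState(3, full)
        pooled = qf.pool_conditional_u3(st, 0, 2, np.concatenate([rng.uniform(size=3), b1]))
        direct = qf.apply_gate(st, qf.GateSpec("U3", (2,), tuple(b1)))
        assert np.abs(pooled.amplitudes - direct.amplitudes).max() <= 1e-10

    def test_born_consistency_with_collapse_oracle(self, rng):
        for _ in range(25):
            amp = random_state(rng, 3)
            b0 = rng.uniform(-np.pi, np.pi, 3)
            b1 = rng.uniform(-np.pi, np.pi, 3)
            pooled = qf.pool_conditional_u3(
                qf.QuantumState(3, amp), 1, 0, np.concatenate([b0, b1])
            )
            for obs in (0, 2):  # every downstream wire except the measured one
                deferred = qf.expect_z(pooled, obs)
                explicit = collapse_pool_expect_z(amp, 3, 1, 0, b0, b1, obs)
                assert deferred == pytest.approx(explicit, abs=1e-10)

    def test_measured_equals_target_rejected(self):
        with pytest.raises(ContractError):
            qf.pool_conditional_u3(qf.QuantumState.zero(2), 1, 1, np.zeros(6))


# ---------------------------------------------------------------------------
# gradients (adjoint vs central finite differences)
# ---------------------------------------------------------------------------


class TestGradients:
    def test_constant_circuit_has_empty_gradient(self):
        circ = qf.Circuit(2, (qf.GateSpec("CNOT", (0, 1)),), (0,))
        vals, jac = qf.circuit_grad(circ)
        assert jac.shape == (1, 0)

    def test_single_ry_gradient_closed_form(self):
        # <Z> = cos(theta); d/dtheta at pi/2 = -1
        circ = qf.Circuit(1, (qf.GateSpec("RY", (0,), (np.pi / 2,)),), (0,))
        vals, jac = qf.circuit_grad(circ)
        assert jac[0, 0] == pytest.approx(-1.0, abs=1e-12)
        fd = fd_grad(lambda p: qf.circuit_expectations(circ, p)[0], np.array([np.pi / 2]))
        assert jac[0, 0] == pytest.approx(fd[0], rel=1e-5, abs=1e-7)

    def test_random_circuits_match_finite_differences(self, rng):
        for _ in range(5):
            circ = random_circuit(rng, 3, n_gates=8)
            w0 = circ.trainable_params()
            vals, jac = qf.circuit_grad(circ, w0)
            for r in range(len(circ.readout)):
                fd = fd_grad(lambda p: qf.circuit_expectations(circ, p)[r], w0)
                assert np.abs(jac[r] - fd).max() <= 1e-5 * max(1.0, np.abs(fd).max())

    def test_cotangent_pass_equals_jacobian_contraction(self, rng):
        circ = random_circuit(rng, 3, n_gates=6)
        w0 = circ.trainable_params()
        ct = rng.normal(size=len(circ.readout))
        vals, jac = qf.circuit_grad(circ, w0)
        vals2, g = qf.circuit_grad(circ, w0, cotangent=ct)
        assert np.abs(g - ct @ jac).max() <= 1e-12

    def test_frozen_parameters_are_skipped(self):
        g1 = qf.GateSpec("RY", (0,), (0.4,), (False,))
        g2 = qf.GateSpec("RZ", (0,), (0.2,))
        circ = qf.Circuit(1, (g1, g2), (0,))
        assert circ.n_trainable == 1
        _, jac = qf.circuit_grad(circ)
        assert jac.shape == (1, 1)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


class TestSerialization:
    def test_round_trip_is_exact(self, rng):
        circ = random_circuit(rng, 3, n_gates=7)
        back = core.circuit_from_text(core.circuit_to_text(circ))
        assert back.n_qubits == circ.n_qubits
        assert back.readout == circ.readout
        for a, b in zip(back.gates, circ.gates):
            assert (a.kind, a.wires, a.params, a.trainable) == (
                b.kind, b.wires, b.params, b.trainable
            )

    def test_bell_fixture(self, fixtures):
        out = core.run_circuit(fixtures["bell_circuit"])
        assert np.abs(out.amplitudes - fixtures["bell_amplitudes"]).max() <= 1e-12
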