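"""Architectures: parameter accounting, shape chains, fusion semantics,
compositional equivalence with the gate-by-gate core, and save/load."""

import numpy as np
import pytest

import qfnirs as qf
from qfnirs import models
from qfnirs.errors import (
    BuildVerificationError,
    ConfigError,
    ContractError,
    RangeError,
    ShapeError,
)

from .oracles import fd_grad


class TestParameterCounts:
    def test_aepqc_has_112_trainable_parameters(self):
        model = qf.build_aepqc()
        assert model.n_params == 112
        assert qf.count_params(qf.ModelSpec("AEPQC")) == 112
        assert len(model.param_labels) == 112

    def test_c_head_has_18_parameters(self):
        total = qf.count_params(qf.ModelSpec("QCNN", kernel="K1", fusion="c_head"))
        kernels_only = qf.count_params(qf.ModelSpec("QCNN", kernel="K1", fusion="avg"))
        assert total - kernels_only == 18

    def test_kernel_parameter_counts(self):
        # K1: 2 weights per wire; K2: 9 U3 parameters per wire + 3 entanglers
        assert models.kernel_ops("K1")[2] == 8
        assert models.kernel_ops("K2")[2] == 39

    def test_qcnn_totals(self):
        assert qf.count_params(qf.ModelSpec("QCNN", kernel="K1")) == 4 * 27 * 8 + 18
        assert qf.count_params(qf.ModelSpec("QCNN", kernel="K2")) == 4 * 27 * 39 + 18

    def test_param_count_guard_trips_on_broken_layout(self, monkeypatch):
        monkeypatch.setattr(models, "AEPQC_N_PARAMS", 100)
        with pytest.raises(BuildVerificationError):
            qf.build_aepqc()


class TestAEPQC:
    def test_accepts_250_features_and_bounds_scores(self, rng):
        model = qf.build_aepqc()
        w = model.init_weights(rng)
        x = rng.normal(size=250)
        scores = model.forward(x, w)
        assert scores.shape == (2,)
        assert np.all(np.abs(scores) <= 1.0)
        with pytest.raises(ShapeError):
            model.forward(rng.normal(size=249), w)

    def test_zero_weights_give_finite_deterministic_scores(self, rng):
        model = qf.build_aepqc()
        x = rng.normal(size=250)
        s1 = qf.aepqc_forward(x, np.zeros(112))
        s2 = qf.aepqc_forward(x, np.zeros(112))
        assert np.all(np.isfinite(s1))
        assert np.array_equal(s1, s2)

    def test_forward_matches_core_circuit_evaluation(self, rng):
        # the model's fast path against the public gate-by-gate API
        model = qf.build_aepqc()
        w = model.init_weights(rng)
        x = rng.normal(size=250)
        circ = model.to_circuit(w)
        init, pad = qf.amplitude_embed(x, 8)
        assert pad == 6
        ref = qf.circuit_expectations(circ, init_state=init)
        assert np.abs(model.forward(x, w) - ref).max() <= 1e-12

    def test_gradient_matches_finite_differences(self, rng):
        model = qf.build_aepqc()
        w = model.init_weights(rng)
        X = rng.normal(size=(3, 250))
        ct = rng.normal(size=(3, 2))
        scores, vjp = model.forward_with_vjp(X, w)
        g = vjp(ct)

        def f(p):
            return float(np.sum(ct * model.forward(X, p)))

        idx = rng.choice(112, size=20, replace=False)
        fd = fd_grad(f, w)
        assert np.abs(g[idx] - fd[idx]).max() <= 1e-6 * max(1.0, np.abs(fd).max())


class TestKernels:
    def test_k1_zero_weights_zero_features_reads_plus_one(self):
        out = qf.kernel_forward(np.zeros(4), np.zeros(8), "K1")
        assert np.allclose(out, [1.0, 1.0], atol=1e-12)

    @pytest.mark.parametrize("kind", ["K1", "K2"])
    def test_outputs_bounded(self, rng, kind):
        n = models.kernel_ops(kind)[2]
        for _ in range(5):
            out = qf.kernel_forward(
                rng.uniform(0, np.pi, 4), rng.uniform(-np.pi, np.pi, n), kind
            )
            assert out.shape == (2,)
            assert np.all(np.abs(out) <= 1.0 + 1e-12)

    def test_features_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            qf.kernel_forward([0.1, 0.2, 3.5, 0.4], np.zeros(8), "K1")

    @pytest.mark.parametrize("kind", ["K1", "K2"])
    def test_kernel_matches_hand_composed_core_ops(self, rng, kind):
        """Compositional oracle: kernel == angle embed + explicit gate chain."""
        ops, _, n_params = models.kernel_ops(kind)
        w = rng.uniform(-np.pi, np.pi, n_params)
        f = rng.uniform(0, np.pi, 4)
        st = qf.angle_embed(f, 4)
        for op in ops:
            params = tuple(w[key] if src == "w" else key for src, key in op.params)
            st = qf.apply_gate(st, qf.GateSpec(op.kind, op.wires, params))
        ref = np.array([qf.expect_z(st, 0), qf.expect_z(st, 2)])
        assert np.abs(qf.kernel_forward(f, w, kind) - ref).max() <= 1e-12


class TestQCNN:
    def test_temporal_chain_10_to_2(self):
        spec = qf.ModelSpec("QCNN", kernel="K1")
        assert spec.layer_lengths == (10, 8, 6, 4, 2)
        assert spec.n_layers == 4

    def test_per_layer_length_map(self):
        assert qf.ModelSpec("QCNN", kernel="K1", input_len=8).layer_lengths == (8, 6, 4, 2)

    def test_channel_scores_shape_and_range(self, rng):
        model = qf.QCNN(qf.ModelSpec("QCNN", kernel="K1"))
        w = model.init_weights(rng)
        X = rng.uniform(0, np.pi, size=(3, 27, 10))
        cs = model.channel_scores(X, w)
        assert cs.shape == (3, 27, 2)
        assert np.all(np.abs(cs) <= 1.0 + 1e-12)

    def test_forward_deterministic_and_bounded(self, rng):
        model = qf.QCNN(qf.ModelSpec("QCNN", kernel="K2", fusion="c_head"))
        w = model.init_weights(rng)
        X = rng.uniform(0, np.pi, size=(2, 27, 10))
        s1, s2 = model.forward(X, w), model.forward(X, w)
        assert np.array_equal(s1, s2)
        assert np.all(np.abs(s1) <= 1.0)

    def test_input_range_validated(self, rng):
        model = qf.QCNN(qf.ModelSpec("QCNN", kernel="K1"))
        w = model.init_weights(rng)
        with pytest.raises(RangeError):
            model.forward(np.full((1, 27, 10), -0.5), w)

    def test_toy_qcnn_equals_hand_composed_chain(self, rng):
        """2-channel, 4-feature toy: one kernel application per channel,
        then averaging — recomputed entirely with public core ops."""
        model = qf.QCNN(qf.ModelSpec("QCNN", kernel="K1", fusion="avg",
                                     n_channels=2, input_len=4))
        w = model.init_weights(rng)
        X = rng.uniform(0, np.pi, size=(2, 4))
        got = model.forward(X, w)
        per_channel = np.stack(
            [qf.kernel_forward(X[c], model.kernel_weights(w, 0)[c, 0], "K1")
             for c in range(2)]
        )
        assert np.abs(got - per_channel.mean(axis=0)).max() <= 1e-12

    def test_fusion_changes_only_the_fusion_stage(self, rng):
        X = None
        cs_ref = None
        rng0 = np.random.default_rng(7)
        w = qf.QCNN(qf.ModelSpec("QCNN", kernel="K1", fusion="avg")).init_weights(rng0)
        X = np.random.default_rng(8).uniform(0, np.pi, size=(2, 27, 10))
        for fusion in ("avg", "max", "amax"):
            model = qf.QCNN(qf.ModelSpec("QCNN", kernel="K1", fusion=fusion))
            cs = model.channel_scores(X, w[: model.n_params])
            if cs_ref is None:
                cs_ref = cs
            else:
                assert np.array_equal(cs, cs_ref)  # bit-identical upstream
            assert np.array_equal(model.forward(X, w[: model.n_params]),
                                  qf.fuse(cs, fusion))

    @pytest.mark.parametrize("kind,fusion", [("K1", "c_head"), ("K2", "avg")])
    def test_gradient_matches_finite_differences(self, rng, kind, fusion):
        model = qf.QCNN(qf.ModelSpec("QCNN", kernel=kind, fusion=fusion,
                                     n_channels=3, input_len=6))
        w = model.init_weights(rng)
        X = rng.uniform(0.1, np.pi - 0.1, size=(4, 3, 6))
        ct = rng.normal(size=(4, 2))
        scores, vjp = model.forward_with_vjp(X, w)
        g = vjp(ct)

        def f(p):
            return float(np.sum(ct * model.forward(X, p)))

        fd = fd_grad(f, w, eps=1e-5)
        assert np.abs(g - fd).max() <= 1e-6 * max(1.0, np.abs(fd).max())


class TestPublicWrappers:
    def test_qcnn_forward_single_window(self, rng):
        spec = qf.ModelSpec("QCNN", kernel="K1", fusion="avg")
        model = qf.QCNN(spec)
        w = model.init_weights(np.random.default_rng(3))
        X = rng.uniform(0, np.pi, size=(27, 10))
        got = qf.qcnn_forward(X, w, kernel="K1", fusion="avg")
        assert got.shape == (2,)
        assert np.array_equal(got, model.forward(X, w))


class TestCHead:
    def test_pad_count_is_ten(self):
        _, pad = qf.amplitude_embed(np.ones(54), 6)
        assert pad == 10

    def test_zero_weights_equal_raw_embedded_readout(self, rng):
        x = rng.normal(size=54)
        out = qf.c_head_forward(x, np.zeros(18))
        st, _ = qf.amplitude_embed(x, 6)
        # zero rotations are identities; CNOT ring still acts, so compose it
        for wire in range(6):
            st = qf.apply_gate(st, qf.GateSpec("CNOT", (wire, (wire + 1) % 6)))
        ref = np.array([qf.expect_z(st, 0), qf.expect_z(st, 1)])
        assert np.abs(out - ref).max() <= 1e-12

    def test_rejects_wrong_length(self):
        with pytest.raises(ShapeError):
            qf.c_head_forward(np.ones(53), np.zeros(18))


class TestFuse:
    def test_amax_keeps_sign_of_largest_magnitude(self):
        cs = np.array([[0.2, 0.2], [-0.9, 0.1], [0.5, -0.3]])
        assert np.allclose(qf.fuse(cs, "amax"), [-0.9, -0.3])

    def test_avg_of_identical_rows_is_that_row(self):
        cs = np.tile([[0.3, -0.4]], (5, 1))
        assert np.allclose(qf.fuse(cs, "avg"), [0.3, -0.4])

    def test_max_dominates_avg_elementwise(self, rng):
        cs = rng.uniform(-1, 1, size=(27, 2))
        assert np.all(qf.fuse(cs, "max") >= qf.fuse(cs, "avg") - 1e-15)

    def test_permutation_invariance(self, rng):
        cs = rng.uniform(-1, 1, size=(27, 2))
        perm = rng.permutation(27)
        for mode in ("avg", "max", "amax"):
            assert np.allclose(qf.fuse(cs, mode), qf.fuse(cs[perm], mode))

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            qf.fuse(np.zeros((0, 2)), "avg")


class TestSpecAndIO:
    def test_aepqc_forbids_fusion(self):
        with pytest.raises(ConfigError):
            qf.ModelSpec("AEPQC", fusion="avg")

    def test_save_load_round_trip_is_bit_exact(self, rng, tmp_path):
        spec = qf.ModelSpec("QCNN", kernel="K2", fusion="c_head")
        w = qf.QCNN(spec).init_weights(rng)
        path = tmp_path / "model.json"
        qf.save_model(path, spec, w)
        spec2, w2 = qf.load_model(path)
        assert spec2 == spec
        assert np.array_equal(w, w2)
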