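import numpy as np
import pytest

from mmdtl.network import (
    ArchitectureSpec,
    TransferMap,
    backward,
    default_architectures,
    forward,
    forward_backward_input,
    init_weights,
    transfer_weights,
)


class TestInitWeights:
    def test_deterministic_for_same_seed(self, toy_stage1_arch):
        w1 = init_weights(toy_stage1_arch, 42)
        w2 = init_weights(toy_stage1_arch, 42)
        for a, b in zip(w1.layers, w2.layers):
            np.testing.assert_array_equal(a.W, b.W)

    def test_seed_sensitivity(self, toy_stage1_arch):
        w1 = init_weights(toy_stage1_arch, 1)
        w2 = init_weights(toy_stage1_arch, 2)
        assert any(np.any(a.W != b.W) for a, b in zip(w1.layers, w2.layers))

    def test_shapes_follow_architecture(self, small_archs):
        for key in ("stage1", "stage2", "stage3"):
            arch = small_archs[key]
            w = init_weights(arch, 0)
            dims = arch.weight_layer_dims()
            assert len(w.layers) == len(dims)
            for layer, (fi, fo, _a, _b) in zip(w.layers, dims):
                assert layer.W.shape == (fo, fi)
                assert layer.b.shape == (fo,)

    def test_biases_zero(self, toy_weights):
        for layer in toy_weights.layers:
            np.testing.assert_array_equal(layer.b, 0.0)


class TestArchitectureInvariants:
    def test_stage1_must_have_five_layers(self):
        with pytest.raises(ValueError, match="stage1"):
            ArchitectureSpec("stage1", [6, 4, 2], ["relu"], [False])

    def test_stage2_must_be_mirror_symmetric(self):
        with pytest.raises(ValueError, match="mirror"):
            ArchitectureSpec(
                "stage2", [6, 5, 4, 3, 2, 3, 4, 6, 6],
                ["relu"] * 7 + ["sigmoid"], [False] * 8,
            )

    def test_stage2_output_must_be_sigmoid(self):
        with pytest.raises(ValueError, match="sigmoid"):
            ArchitectureSpec(
                "stage2", [6, 5, 4, 3, 2, 3, 4, 5, 6],
                ["relu"] * 8, [False] * 8,
            )

    def test_clinical_fusion_needs_fusion_layer(self):
        with pytest.raises(ValueError, match="fusion"):
            ArchitectureSpec(
                "stage3", [6, 5, 4, 3, 2, 4, 2], ["relu"] * 5, [False] * 5,
                task_count=2, clinical_width=3,
            )


class TestTransferWeights:
    def test_full_map_copies_everything(self, toy_stage1_arch):
        src = init_weights(toy_stage1_arch, 1)
        tmap = TransferMap([(i, i) for i in range(4)])
        dst = transfer_weights(src, toy_stage1_arch, tmap, seed=99)
        for a, b in zip(src.layers, dst.layers):
            np.testing.assert_array_equal(a.W, b.W)
            np.testing.assert_array_equal(a.b, b.b)

    def test_empty_map_equals_fresh_init(self, toy_stage1_arch):
        src = init_weights(toy_stage1_arch, 1)
        dst = transfer_weights(src, toy_stage1_arch, TransferMap([]), seed=5)
        fresh = init_weights(toy_stage1_arch, 5)
        for a, b in zip(dst.layers, fresh.layers):
            np.testing.assert_array_equal(a.W, b.W)

    def test_default_stage1_to_stage2_map(self, small_archs):
        w1 = init_weights(small_archs["stage1"], 3)
        w2 = transfer_weights(
            w1, small_archs["stage2"], small_archs["map_s1_to_s2"], seed=4
        )
        for i in range(3):  # encoder layers copied
            np.testing.assert_array_equal(w1.layers[i].W, w2.layers[i].W)
        fresh = init_weights(small_archs["stage2"], 4)
        for i in range(3, len(w2.layers)):  # bottleneck + decoder fresh
            np.testing.assert_array_equal(w2.layers[i].W, fresh.layers[i].W)

    def test_shape_mismatch_names_both_layers(self, small_archs):
        w1 = init_weights(small_archs["stage1"], 0)
        with pytest.raises(ValueError, match="source layer 0 .* destination layer 1"):
            transfer_weights(
                w1, small_archs["stage2"], TransferMap([(0, 1)]), seed=0
            )

    def test_transfer_preserves_forward_output(self, toy_stage1_arch, rng):
        src = init_weights(toy_stage1_arch, 1)
        tmap = TransferMap([(i, i) for i in range(4)])
        dst = transfer_weights(src, toy_stage1_arch, tmap, seed=99)
        X = rng.normal(size=(5, 6))
        np.testing.assert_array_equal(
            forward(src, toy_stage1_arch, X), forward(dst, toy_stage1_arch, X)
        )


class TestForward:
    def test_zero_weights_give_half_probability(self, toy_stage1_arch, toy_weights):
        for layer in toy_weights.layers:
            layer.W[:] = 0.0
            layer.b[:] = 0.0
        p = forward(toy_weights, toy_stage1_arch, np.ones(6))
        assert p[0] == pytest.approx(0.5, abs=1e-12)

    def test_probabilities_normalized_under_random_weights(self, rng):
        arch = ArchitectureSpec(
            "stage3", [5, 6, 5, 4, 3, 4, 2], ["relu"] * 5, [True] * 5, task_count=3
        )
        for draw in range(50):
            w = init_weights(arch, draw)
            X = rng.normal(size=(7, 5)) * 3
            p = forward(w, arch, X, mode="train")
            assert np.all((p >= 0) & (p <= 1))

    def test_hand_computed_two_unit_network(self):
        # 2-2-2-2-2 relu chain, no batch norm, weights written out by hand
        arch = ArchitectureSpec(
            "stage1", [2, 2, 2, 2, 2], ["relu", "relu", "relu"], [False] * 3
        )
        w = init_weights(arch, 0)
        mats = [
            np.array([[1.0, -1.0], [0.5, 0.5]]),
            np.array([[2.0, 0.0], [0.0, 1.0]]),
            np.array([[1.0, 1.0], [-1.0, 0.0]]),
            np.array([[1.0, 0.0], [0.0, 1.0]]),
        ]
        for layer, m in zip(w.layers, mats):
            layer.W[:] = m
            layer.b[:] = 0.0
        x = np.array([1.0, 2.0])
        h1 = np.maximum(mats[0] @ x, 0)          # [0, 1.5]
        h2 = np.maximum(mats[1] @ h1, 0)         # [0, 1.5]
        h3 = np.maximum(mats[2] @ h2, 0)         # [1.5, 0]
        logits = mats[3] @ h3                    # [1.5, 0]
        expect = np.exp(logits) / np.exp(logits).sum()
        p = forward(w, arch, x)
        assert p[0] == pytest.approx(expect[1], abs=1e-10)

    def test_dimension_mismatch_rejected(self, toy_stage1_arch, toy_weights):
        with pytest.raises(ValueError, match="input width"):
            forward(toy_weights, toy_stage1_arch, np.ones(5))

    def test_autoencoder_output_width_matches_input(self, small_archs, rng):
        w = init_weights(small_archs["stage2"], 0)
        X = rng.uniform(0, 1, size=(4, 45))
        out = forward(w, small_archs["stage2"], X)
        assert out.shape == (4, 45)
        assert np.all((out > 0) & (out < 1))  # sigmoid output


class TestGradients:
    def _loss(self, w, arch, X, y):
        p = np.clip(forward(w, arch, X, mode="train")[:, 0], 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def test_parameter_gradients_match_finite_differences(
        self, toy_stage1_arch, rng
    ):
        arch, w = toy_stage1_arch, init_weights(toy_stage1_arch, 3)
        X = rng.normal(size=(6, 6))
        y = rng.integers(0, 2, 6).astype(float)
        probs, caches = forward(w, arch, X, mode="train", return_cache=True)
        p = probs[:, 0]
        dZ = (np.column_stack([1 - p, p]) - np.column_stack([1 - y, y])) / len(y)
        grads, _, _ = backward(w, arch, caches, dZ_heads=[dZ])
        eps = 1e-6
        for li in (0, 1, 3):
            arr = w.layers[li].W
            for flat in range(0, arr.size, max(1, arr.size // 4)):
                idx = np.unravel_index(flat, arr.shape)
                wp, wm = w.copy(), w.copy()
                wp.layers[li].W[idx] += eps
                wm.layers[li].W[idx] -= eps
                num = (self._loss(wp, arch, X, y) - self._loss(wm, arch, X, y)) / (2 * eps)
                assert grads[li]["dW"][idx] == pytest.approx(
                    num, rel=1e-4, abs=1e-9
                )

    def test_input_gradient_matches_finite_differences(self, toy_stage1_arch):
        arch = toy_stage1_arch
        w = init_weights(arch, 11)
        w.provenance = "stage1"
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 6))
        _, dX, _ = forward_backward_input(w, arch, X, None, 0)
        eps = 1e-6
        for j in range(6):
            Xp, Xm = X.copy(), X.copy()
            Xp[1, j] += eps
            Xm[1, j] -= eps
            num = (forward(w, arch, Xp)[1, 0] - forward(w, arch, Xm)[1, 0]) / (2 * eps)
            assert dX[1, j] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_clinical_fusion_gradient_flows_to_clinical_block(self, rng):
        arch = ArchitectureSpec(
            "stage3", [5, 6, 5, 4, 3, 4, 2], ["relu"] * 5, [False] * 5,
            task_count=2, clinical_width=3, fusion_layer=3,
        )
        w = init_weights(arch, 2)
        w.provenance = "stage3"
        X = rng.normal(size=(4, 5))
        clin = rng.normal(size=(4, 3))
        p, dX, dC = forward_backward_input(w, arch, X, clin, 1)
        assert dX.shape == (4, 5)
        assert dC.shape == (4, 3)
        eps = 1e-6
        cp, cm = clin.copy(), clin.copy()
        cp[2, 1] += eps
        cm[2, 1] -= eps
        num = (
            forward(w, arch, X, cp)[2, 1] - forward(w, arch, X, cm)[2, 1]
        ) / (2 * eps)
        assert dC[2, 1] == pytest.approx(num, rel=1e-4, abs=1e-9)
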