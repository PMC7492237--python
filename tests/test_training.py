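import numpy as np
import pytest

from mmdtl.features import SubjectRecord
from mmdtl.network import ArchitectureSpec, forward, init_weights
from mmdtl.training import (
    TaskWeights,
    TrainingConfig,
    early_stop_check,
    sgd_epoch,
    stage1_loss,
    stage2_loss,
    stage3_loss,
    train_stage1,
    train_stage2,
    train_stage3,
)
from tests.conftest import make_records

LN2 = float(np.log(2.0))


def brute_stage1(p, y, eps=1e-7):
    """Per-sample sum oracle for the supervised cross-entropy."""
    total = 0.0
    for pi, yi in zip(p, y):
        pi = min(max(pi, eps), 1 - eps)
        total += yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
    return -total / len(p)


def brute_stage2(X, Xh, eps=1e-7):
    """Double-sum oracle for the reconstruction cross-entropy."""
    m, n = X.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            xh = min(max(Xh[i, j], eps), 1 - eps)
            total += X[i, j] * np.log(xh) + (1 - X[i, j]) * np.log(1 - xh)
    return -total / (m * n)


def brute_stage3(P, Y, beta, alpha, eps=1e-7):
    """Triple-sum oracle for the weighted multi-task cross-entropy."""
    m, C = Y.shape
    total = 0.0
    for c in range(C):
        for i in range(m):
            p = min(max(P[i, c], eps), 1 - eps)
            total += alpha[c] * beta[i, c] * (
                Y[i, c] * np.log(p) + (1 - Y[i, c]) * np.log(1 - p)
            )
    return -total / (m * C)


def _identity_prob_net(n_feat, task_count=1):
    """A classifier whose positive-class logit equals a weighted input sum."""
    arch = ArchitectureSpec(
        "stage1", [n_feat, n_feat, n_feat, n_feat, 2],
        ["linear", "linear", "linear"], [False] * 3,
    )
    w = init_weights(arch, 0)
    for layer in w.layers[:3]:
        layer.W[:] = np.eye(n_feat)
        layer.b[:] = 0
    return arch, w


class TestStageLosses:
    def test_stage1_half_probabilities_give_ln2(self, toy_stage1_arch, toy_weights):
        for layer in toy_weights.layers:
            layer.W[:] = 0
            layer.b[:] = 0
        X = np.random.default_rng(0).normal(size=(8, 6))
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0], float)
        assert stage1_loss(toy_weights, toy_stage1_arch, X, y) == pytest.approx(
            LN2, abs=1e-9
        )

    def test_stage1_matches_brute_force(self, toy_stage1_arch, rng):
        w = init_weights(toy_stage1_arch, 5)
        X = rng.normal(size=(3, 6))
        y = np.array([1.0, 0.0, 1.0])
        p = forward(w, toy_stage1_arch, X)[:, 0]
        assert stage1_loss(w, toy_stage1_arch, X, y) == pytest.approx(
            brute_stage1(p, y), abs=1e-12
        )

    def test_stage2_entropy_floor_at_half(self, small_archs):
        w = init_weights(small_archs["stage2"], 0)
        for layer in w.layers:
            layer.W[:] = 0
            layer.b[:] = 0
        X = np.full((3, 45), 0.5)
        assert stage2_loss(w, small_archs["stage2"], X) == pytest.approx(
            LN2, abs=1e-9
        )

    def test_stage2_matches_double_sum_oracle(self, small_archs, rng):
        w = init_weights(small_archs["stage2"], 1)
        X = rng.uniform(0, 1, size=(2, 45))
        Xh = forward(w, small_archs["stage2"], X)
        assert stage2_loss(w, small_archs["stage2"], X) == pytest.approx(
            brute_stage2(X, Xh), abs=1e-12
        )

    def test_stage2_rejects_unrescaled_input(self, small_archs):
        w = init_weights(small_archs["stage2"], 0)
        with pytest.raises(ValueError, match="rescaled"):
            stage2_loss(w, small_archs["stage2"], np.full((2, 45), -0.5))

    def test_stage3_single_task_unit_weights_reduces_to_stage1(self, rng):
        arch3 = ArchitectureSpec(
            "stage3", [6, 5, 4, 3, 2, 2, 2], ["relu"] * 5, [False] * 5, task_count=1
        )
        w = init_weights(arch3, 2)
        X = rng.normal(size=(5, 6))
        y = np.array([1, 0, 0, 1, 0], float)
        p = forward(w, arch3, X)
        l3 = stage3_loss(
            w, arch3, X, y[:, None], np.ones((5, 1)), np.ones(1)
        )
        assert l3 == pytest.approx(brute_stage1(p[:, 0], y), abs=1e-12)

    def test_stage3_matches_triple_sum_oracle(self, rng):
        arch3 = ArchitectureSpec(
            "stage3", [6, 5, 4, 3, 2, 4, 2], ["relu"] * 5, [False] * 5, task_count=2
        )
        w = init_weights(arch3, 3)
        X = rng.normal(size=(4, 6))
        Y = rng.integers(0, 2, (4, 2)).astype(float)
        beta = 1.0 + rng.random((4, 2)) * 3
        alpha = np.array([1.0, 2.5])
        P = forward(w, arch3, X)
        assert stage3_loss(w, arch3, X, Y, beta, alpha) == pytest.approx(
            brute_stage3(P, Y, beta, alpha), abs=1e-12
        )

    def test_stage3_invariant_to_task_permutation(self, rng):
        arch3 = ArchitectureSpec(
            "stage3", [6, 5, 4, 3, 2, 6, 2], ["relu"] * 5, [False] * 5, task_count=3
        )
        w = init_weights(arch3, 4)
        X = rng.normal(size=(5, 6))
        Y = rng.integers(0, 2, (5, 3)).astype(float)
        beta = 1.0 + rng.random((5, 3))
        alpha = np.array([1.0, 2.0, 0.5])
        base = stage3_loss(w, arch3, X, Y, beta, alpha)
        # permuting the task axis everywhere (including head weights) is a relabeling
        perm = [2, 0, 1]
        w2 = w.copy()
        heads = w.layers[-3:]
        for slot, src in enumerate(perm):
            w2.layers[len(w.layers) - 3 + slot] = heads[src].copy()
        got = stage3_loss(
            w2, arch3, X, Y[:, perm], beta[:, perm], alpha[perm]
        )
        assert got == pytest.approx(base, abs=1e-12)


class TestTaskWeights:
    def test_published_prevalence_gives_beta_5_6(self):
        y = np.array([1] * 5 + [0] * 28)
        beta = TaskWeights().beta_for(y)
        assert beta[0] == pytest.approx(28 / 5)  # = 5.6
        assert beta[-1] == 1.0

    def test_single_class_split_rejected(self):
        with pytest.raises(ValueError, match="minority"):
            TaskWeights().beta_for(np.zeros(10))

    def test_beta_disabled_gives_ones(self):
        np.testing.assert_array_equal(
            TaskWeights(use_beta=False).beta_for(np.array([0, 1, 1])), 1.0
        )


class TestEarlyStop:
    def test_literal_plateau_rule(self):
        assert early_stop_check([0.5, 0.4, 0.4, 0.4, 0.4], 3, 0.0)

    def test_strictly_decreasing_never_stops(self):
        losses = list(np.linspace(1.0, 0.1, 30))
        for k in range(1, 31):
            assert not early_stop_check(losses[:k], 3, 0.0)

    def test_tolerance_semantics(self):
        assert early_stop_check([0.4, 0.4001, 0.4002, 0.4001], 3, 1e-3)
        assert not early_stop_check([0.4, 0.4001, 0.402, 0.4001], 3, 1e-3)

    def test_requires_an_observation(self):
        with pytest.raises(ValueError):
            early_stop_check([], 3, 0.0)


class TestSgd:
    def test_zero_learning_rate_leaves_weights_unchanged(self, toy_stage1_arch, rng):
        w = init_weights(toy_stage1_arch, 0)
        before = [layer.W.copy() for layer in w.layers]
        X = rng.normal(size=(8, 6))
        y = rng.integers(0, 2, 8).astype(float)

        def loss_grad(w, arch, batch):
            probs, caches = forward(w, arch, batch["X"], mode="train",
                                    return_cache=True)
            p = probs[:, 0]
            dZ = (np.column_stack([1 - p, p])
                  - np.column_stack([1 - batch["y"], batch["y"]])) / len(p)
            from mmdtl.network import backward
            grads, _, _ = backward(w, arch, caches, dZ_heads=[dZ])
            return 0.0, grads

        cfg = TrainingConfig(learning_rate=0.0, batch_size=4, seed=0)
        sgd_epoch(w, toy_stage1_arch, {"X": X, "y": y}, loss_grad, cfg, epoch=0)
        for b, layer in zip(before, w.layers):
            np.testing.assert_array_equal(b, layer.W)

    def test_full_batch_step_equals_analytic_gradient(self):
        # one linear parameter theta on loss -log sigmoid(theta*x) for y=1:
        # dJ/dtheta = (p - 1) * x; check the SGD update reproduces it
        arch = ArchitectureSpec(
            "stage1", [1, 1, 1, 1, 2], ["linear"] * 3, [False] * 3
        )
        w = init_weights(arch, 0)
        for layer in w.layers[:3]:
            layer.W[:] = 1.0
        w.layers[3].W[:] = np.array([[0.0], [1.0]])  # logit_pos = theta-path * x
        x = np.array([[2.0]])
        y = np.array([1.0])
        p = forward(w, arch, x)[0, 0]
        expect_grad = (p - 1.0) * 2.0  # d(-log p)/d(head weight) via chain

        def loss_grad(w, arch, batch):
            probs, caches = forward(w, arch, batch["X"], mode="train",
                                    return_cache=True)
            pp = probs[:, 0]
            dZ = (np.column_stack([1 - pp, pp]) - np.column_stack([0.0 * pp + 0, pp * 0 + 1]))
            from mmdtl.network import backward
            grads, _, _ = backward(w, arch, caches, dZ_heads=[dZ])
            return 0.0, grads

        lr = 0.1
        head_before = w.layers[3].W[1, 0]
        cfg = TrainingConfig(learning_rate=lr, batch_size=1, seed=0,
                             max_grad_norm=None)
        sgd_epoch(w, arch, {"X": x, "y": y}, loss_grad, cfg, epoch=0)
        assert w.layers[3].W[1, 0] - head_before == pytest.approx(
            -lr * expect_grad, rel=1e-10
        )

    def test_identical_seeds_identical_trajectories(self):
        records = make_records(24, 6, seed=1, cohort="source")
        arch = ArchitectureSpec(
            "stage1", [15, 8, 6, 4, 2], ["relu"] * 3, [True] * 3
        )
        cfg = TrainingConfig(batch_size=8, max_epochs=4, seed=3)
        _, tr1 = train_stage1(records, arch, cfg)
        _, tr2 = train_stage1(records, arch, cfg)
        assert tr1.train_losses == tr2.train_losses
        assert tr1.val_losses == tr2.val_losses


class TestStageDrivers:
    def test_stage1_learns_separable_data(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(40):
            y = i % 2
            x = np.tanh(rng.normal(0.8 * (2 * y - 1), 0.3, 15))
            records.append(
                SubjectRecord(f"s{i}", "a", "source", x, labels={"t": y})
            )
        arch = ArchitectureSpec(
            "stage1", [15, 8, 6, 4, 2], ["relu"] * 3, [True] * 3
        )
        cfg = TrainingConfig(batch_size=8, max_epochs=20, seed=0)
        w, trace = train_stage1(records, arch, cfg)
        assert trace.val_losses[-1] < trace.val_losses[0]
        assert w.provenance == "stage1"

    def test_stage2_descends_on_heldout_reconstruction(self, small_archs):
        # intermediate data must carry latent structure for the autoencoder
        # to learn anything transferable; pure noise would only overfit
        from mmdtl.synthetic import SyntheticConfig, generate_intermediate_cohort
        from mmdtl.training import stacked_inputs
        from mmdtl.network import transfer_weights

        cfg_syn = SyntheticConfig(n_roi=10, n_intermediate=70, seed=0)
        inter = generate_intermediate_cohort(cfg_syn, 0)
        records, held = inter[:60], inter[60:]
        w1, _ = train_stage1(
            make_records(30, 10, seed=3, cohort="source"),
            small_archs["stage1"],
            TrainingConfig(batch_size=8, max_epochs=3, seed=0),
        )
        cfg = TrainingConfig(batch_size=8, max_epochs=80, learning_rate=0.2,
                             weight_decay=0.01, seed=0)
        Xh = stacked_inputs(held)
        w_init = transfer_weights(
            w1, small_archs["stage2"], small_archs["map_s1_to_s2"], 0
        )
        before = stage2_loss(w_init, small_archs["stage2"], Xh)
        w2, _trace = train_stage2(
            records, w1, small_archs["stage2"], small_archs["map_s1_to_s2"], cfg
        )
        after = stage2_loss(w2, small_archs["stage2"], Xh)
        assert after < before

    def test_stage3_bit_identical_given_same_seed(self, small_archs):
        records = make_records(20, 10, seed=5, n_pos=6)
        cfg = TrainingConfig(batch_size=4, max_epochs=3, seed=9)
        w_a, _ = train_stage3(records, None, small_archs["stage3"], None, cfg)
        w_b, _ = train_stage3(records, None, small_archs["stage3"], None, cfg)
        for a, b in zip(w_a.layers, w_b.layers):
            np.testing.assert_array_equal(a.W, b.W)
            np.testing.assert_array_equal(a.b, b.b)

    def test_stage3_beta_raises_minority_sensitivity(self):
        # directional property over 10 seeds on an imbalanced separable toy
        rng = np.random.default_rng(7)
        wins = []
        arch = ArchitectureSpec(
            "stage3", [10, 8, 6, 4, 3, 3, 2], ["relu"] * 5, [True] * 5, task_count=1
        )
        for s in range(10):
            recs = []
            for i in range(30):
                y = int(i < 6)
                x = np.tanh(rng.normal(0.5 * (2 * y - 1), 0.8, 10))
                recs.append(SubjectRecord(f"s{i}", "a", "target", x,
                                          labels={"t": y}))
            sens = {}
            for use_beta in (True, False):
                cfg = TrainingConfig(batch_size=4, max_epochs=10, seed=s)
                w, _ = train_stage3(
                    recs, None, arch, None, cfg,
                    task_weights=TaskWeights(use_beta=use_beta),
                )
                from mmdtl.training import stacked_inputs

                p = forward(w, arch, stacked_inputs(recs))[:, 0]
                y_true = np.array([r.labels["t"] for r in recs])
                sens[use_beta] = np.mean(p[y_true == 1] >= 0.5)
            wins.append(sens[True] - sens[False])
        assert np.mean(wins) > 0
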