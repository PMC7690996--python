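"""SPD network: layer algebra, manifold optimization, gradient correctness."""

import numpy as np
import pytest
from scipy.linalg import expm

from frpsonet.spdnet import (SPDNetClassifier, SPDNetConfig, bimap,
                             class_weights, init_params, logeig,
                             orthogonality_defect, reeig, spdnet_forward,
                             spdnet_loss_and_grads, stiefel_retract,
                             stiefel_step, train_spdnet)
from conftest import rand_spd


class TestBiMap:
    rng = np.random.default_rng(0)

    def test_identity_weight_is_identity_map(self):
        X = rand_spd(self.rng, 5)
        np.testing.assert_allclose(bimap(X, np.eye(5)), X)

    def test_permutation_weight_permutes(self):
        X = rand_spd(self.rng, 4)
        P = np.eye(4)[[2, 0, 3, 1]].T
        np.testing.assert_allclose(bimap(X, P), X[[2, 0, 3, 1]][:, [2, 0, 3, 1]])

    def test_identity_input_maps_to_identity(self):
        W = stiefel_retract(self.rng.standard_normal((6, 6)))
        np.testing.assert_allclose(bimap(np.eye(6), W), np.eye(6), atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            bimap(np.eye(4), np.eye(5))


class TestReEig:
    def test_above_floor_unchanged(self):
        rng = np.random.default_rng(1)
        X = rand_spd(rng, 5, jitter=1.0)
        np.testing.assert_allclose(reeig(X, 1e-4), X, atol=1e-10)

    def test_small_eigenvalue_clamped(self):
        eps = 0.1
        np.testing.assert_allclose(reeig(np.diag([eps / 2, 2 * eps]), eps),
                                   np.diag([eps, 2 * eps]), atol=1e-12)

    def test_zero_matrix_becomes_eps_identity(self):
        np.testing.assert_allclose(reeig(np.zeros((3, 3)), 1e-2), 1e-2 * np.eye(3))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            reeig(np.array([[1.0, 2.0], [0.0, 1.0]]), 1e-4)


class TestLogEig:
    def test_identity_maps_to_zero(self):
        L, flat = logeig(np.eye(4))
        np.testing.assert_allclose(L, 0.0, atol=1e-12)
        assert flat.shape == (16,)

    def test_diagonal_example(self):
        L, _ = logeig(np.diag([np.e, np.e ** 2]))
        np.testing.assert_allclose(L, np.diag([1.0, 2.0]), atol=1e-12)

    def test_expm_round_trip(self):
        rng = np.random.default_rng(2)
        X = rand_spd(rng, 6)
        L, _ = logeig(X)
        np.testing.assert_allclose(expm(L), X, atol=1e-8)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            logeig(np.diag([1.0, -1.0]))


class TestStiefel:
    rng = np.random.default_rng(3)

    def test_zero_gradient_fixed_point(self):
        W = stiefel_retract(self.rng.standard_normal((8, 8)))
        np.testing.assert_allclose(stiefel_step(W, np.zeros_like(W), 0.1), W,
                                   atol=1e-10)

    def test_retraction_restores_orthogonality(self):
        W = stiefel_retract(self.rng.standard_normal((8, 8)))
        for _ in range(5):
            W = stiefel_step(W, self.rng.standard_normal(W.shape), 0.05)
            assert orthogonality_defect(W) <= 1e-8

    def test_ascent_on_trace_objective(self):
        # maximizing trace(W^T A W): supply the gradient of f = -trace(W^T A W)
        A = rand_spd(self.rng, 6, jitter=0.1)
        W = stiefel_retract(self.rng.standard_normal((6, 3)))
        values = [np.trace(W.T @ A @ W)]
        for _ in range(20):
            W = stiefel_step(W, -2.0 * A @ W, 0.01)
            values.append(np.trace(W.T @ A @ W))
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_nonfinite_gradient_rejected(self):
        W = np.eye(3)
        with pytest.raises(ValueError, match="finite"):
            stiefel_step(W, np.full((3, 3), np.nan), 0.1)


class TestClassWeights:
    def test_imbalanced_odds(self):
        labels = np.array([0] * 6803 + [1] * 1015)
        w = class_weights(labels)
        assert w[0] == 1.0
        assert w[1] == pytest.approx(6803 / 1015)

    def test_balanced_is_unit(self):
        np.testing.assert_allclose(class_weights(np.array([0, 1, 0, 1])), [1.0, 1.0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            class_weights(np.zeros(10, dtype=int))

    def test_all_majority_batch_weight_is_one(self):
        # weighted loss on an all-majority batch equals the unweighted loss
        rng = np.random.default_rng(4)
        X = np.stack([rand_spd(rng, 4) for _ in range(6)])
        y = np.zeros(6, dtype=int)
        params = init_params(4, 1, 2, rng)
        w = np.array([1.0, 5.0])
        lw, _ = spdnet_loss_and_grads(X, y, params, 1e-4, w)
        lu, _ = spdnet_loss_and_grads(X, y, params, 1e-4, np.ones(2))
        assert lw == pytest.approx(lu)


class TestForward:
    rng = np.random.default_rng(5)

    def test_probabilities_sum_to_one(self):
        X = np.stack([rand_spd(self.rng, 8) for _ in range(5)])
        params = init_params(8, 2, 2, self.rng)
        p = spdnet_forward(X, params, 1e-4)
        assert p.shape == (5, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert (p >= 0).all()

    def test_deterministic(self):
        X = rand_spd(self.rng, 6)
        params = init_params(6, 2, 2, np.random.default_rng(0))
        np.testing.assert_array_equal(spdnet_forward(X, params, 1e-4),
                                      spdnet_forward(X, params, 1e-4))

    def test_zero_upstream_gradient_gives_zero_parameter_gradients(self):
        # a loss already at its exact minimum propagates null gradients
        X = np.stack([rand_spd(self.rng, 4) for _ in range(4)])
        params = init_params(4, 1, 2, self.rng)
        p, _ = spdnet_forward(X, params, 1e-4, return_cache=True)
        # construct weights that zero the upstream signal
        _, grads = spdnet_loss_and_grads(X, np.zeros(4, dtype=int), params, 1e-4,
                                         np.array([0.0, 1.0]))
        for dW in grads["Ws"]:
            np.testing.assert_allclose(dW, 0.0, atol=1e-12)
        np.testing.assert_allclose(grads["A"], 0.0, atol=1e-12)


@pytest.mark.parametrize("seed", [0, 1])
def test_gradients_match_finite_differences(seed):
    """Analytic gradients through both BiRe blocks + LogEig + softmax."""
    rng = np.random.default_rng(seed)
    d, n = 5, 6
    X = np.stack([rand_spd(rng, d) for _ in range(n)])
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    params = init_params(d, 2, 2, rng)
    w = np.array([1.0, 3.0])
    _, grads = spdnet_loss_and_grads(X, y, params, 1e-4, w)
    h = 1e-6
    for li in range(2):
        W = params["Ws"][li]
        check = [(0, 0), (1, 3), (4, 2)]
        for idx in check:
            orig = W[idx]
            W[idx] = orig + h
            lp, _ = spdnet_loss_and_grads(X, y, params, 1e-4, w)
            W[idx] = orig - h
            lm, _ = spdnet_loss_and_grads(X, y, params, 1e-4, w)
            W[idx] = orig
            num = (lp - lm) / (2 * h)
            assert num == pytest.approx(grads["Ws"][li][idx], rel=1e-4, abs=1e-9)


class TestTraining:
    @staticmethod
    def _two_cluster_data(rng, n=120, d=8):
        A = rand_spd(rng, d, jitter=0.2)
        B = rand_spd(rng, d, jitter=0.2)
        X, y = [], []
        for i in range(n):
            lab = i % 2
            base = A if lab else B
            noise = 0.05 * rand_spd(rng, d, jitter=0.0)
            X.append(base + noise + 0.05 * np.eye(d))
            y.append(lab)
        return np.stack(X), np.array(y)

    def test_separable_clusters_learned(self):
        rng = np.random.default_rng(6)
        X, y = self._two_cluster_data(rng)
        # nearest-mean oracle confirms the clusters are separable at all
        mean0, mean1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
        d0 = np.linalg.norm(X - mean0, axis=(1, 2))
        d1 = np.linalg.norm(X - mean1, axis=(1, 2))
        oracle_acc = ((d1 < d0).astype(int) == y).mean()
        assert oracle_acc > 0.95
        clf = SPDNetClassifier(max_epochs=60, random_state=0)
        clf.fit(X, y)
        from frpsonet.evaluation import auc

        assert auc(clf.predict_proba(X)[:, 1], y) > 0.95

    def test_best_validation_weights_restored(self):
        rng = np.random.default_rng(7)
        X, y = self._two_cluster_data(rng, n=60, d=5)
        cfg = SPDNetConfig(max_epochs=15)
        params, hist = train_spdnet(X[:40], y[:40], cfg, validation=(X[40:], y[40:]),
                                    rng=np.random.default_rng(1))
        p = spdnet_forward(X[40:], params, cfg.eps)
        from frpsonet.spdnet import _weighted_ce

        w = class_weights(y[:40])
        assert _weighted_ce(p, y[40:], w) == pytest.approx(min(hist.val_loss))

    def test_fixed_seed_identical_history(self):
        rng = np.random.default_rng(8)
        X, y = self._two_cluster_data(rng, n=40, d=4)
        runs = []
        for _ in range(2):
            _, hist = train_spdnet(X[:30], y[:30], SPDNetConfig(max_epochs=5),
                                   validation=(X[30:], y[30:]),
                                   rng=np.random.default_rng(3))
            runs.append(hist.val_loss)
        assert runs[0] == runs[1]

    def test_manifold_closure_during_training(self):
        rng = np.random.default_rng(9)
        X, y = self._two_cluster_data(rng, n=40, d=6)
        clf = SPDNetClassifier(max_epochs=10, random_state=0).fit(X, y)
        for W in clf.params_["Ws"]:
            assert orthogonality_defect(W) <= 1e-8

    def test_single_class_rejected(self):
        rng = np.random.default_rng(10)
        X = np.stack([rand_spd(rng, 4) for _ in range(10)])
        with pytest.raises(ValueError):
            SPDNetClassifier(max_epochs=1).fit(X, np.zeros(10, dtype=int))


def test_orthogonal_conjugation_invariance():
    """Rotating all inputs by a fixed orthogonal Q and the first-layer weight
    by Q reproduces the training losses exactly (the W's absorb Q)."""
    rng = np.random.default_rng(11)
    d, n = 5, 12
    X = np.stack([rand_spd(rng, d) for _ in range(n)])
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    Q = stiefel_retract(rng.standard_normal((d, d)))
    Xq = Q @ X @ Q.T
    params = init_params(d, 2, 2, np.random.default_rng(0))
    params_q = {"Ws": [Q @ params["Ws"][0], params["Ws"][1].copy()],
                "A": params["A"].copy(), "b": params["b"].copy()}
    w = np.ones(2)
    losses, losses_q = [], []
    for _ in range(10):
        l1, g1 = spdnet_loss_and_grads(X, y, params, 1e-4, w)
        l2, g2 = spdnet_loss_and_grads(Xq, y, params_q, 1e-4, w)
        losses.append(l1)
        losses_q.append(l2)
        for i in range(2):
            params["Ws"][i] = stiefel_step(params["Ws"][i], g1["Ws"][i], 1e-2)
            params_q["Ws"][i] = stiefel_step(params_q["Ws"][i], g2["Ws"][i], 1e-2)
        params["A"] -= 1e-2 * g1["A"]
        params_q["A"] -= 1e-2 * g2["A"]
    np.testing.assert_allclose(losses, losses_q, rtol=1e-8)
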