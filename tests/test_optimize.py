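"""Stochastic mode gradients, Adam updates, and per-block fitting."""

import numpy as np
import pytest

from countcp import AdamState, FitConfig, KruskalModel, RegularizerConfig, SparseCountTensor, adam_step, fit_block, mode_gradient, poisson_loss
from countcp.optimize import ADAM_EPS

from conftest import brute_force_angular, dense_from_model, dense_from_tensor, dense_poisson_loss, random_tensor


def dense_objective(X_dense, model, reg, labels=None, theta=None):
    """Independent dense evaluation of the full fitting objective."""
    obj = dense_poisson_loss(X_dense, dense_from_model(model))
    for A in model.factors:
        obj += reg.beta_angular * brute_force_angular(A, reg.angular_threshold)
        obj += 0.5 * reg.beta_l2 * float((A ** 2).sum())
    if labels is not None and theta is not None and reg.beta_supervision > 0:
        A0 = model.factors[0]
        R = A0.shape[1]
        for i, lab in enumerate(labels):
            if lab < 0:
                continue
            y = 1.0 if lab == 1 else -1.0
            margin = y * (A0[i] @ theta[:R] + theta[R])
            obj += reg.beta_supervision * float(np.logaddexp(0.0, -margin))
    return obj


def fd_mode_gradient(X_dense, model, mode, reg, labels=None, theta=None, h=1e-6):
    A = model.factors[mode]
    g = np.zeros_like(A)
    for i in range(A.shape[0]):
        for r in range(A.shape[1]):
            step = h * max(1.0, abs(A[i, r]))
            up, dn = model.copy(), model.copy()
            up.factors[mode][i, r] += step
            dn.factors[mode][i, r] -= step
            g[i, r] = (
                dense_objective(X_dense, up, reg, labels, theta)
                - dense_objective(X_dense, dn, reg, labels, theta)
            ) / (2 * step)
    return g


def full_ranges(shape):
    return [(0, s) for s in shape]


class TestFitConfig:
    def test_rejects_bad_rank(self):
        with pytest.raises(ValueError):
            FitConfig(rank=0)

    def test_rejects_negative_inner_iters(self):
        with pytest.raises(ValueError):
            FitConfig(rank=2, inner_iters=-1)

    def test_allows_zero_epochs_and_iterations(self):
        FitConfig(rank=2, inner_iters=0, max_epochs=0)

    def test_rejects_unknown_step_scaling(self):
        with pytest.raises(ValueError):
            FitConfig(rank=2, step_scaling="bogus")


class TestAdamStep:
    def test_zero_gradient_leaves_params_and_advances_counter(self):
        state = AdamState.zeros((2, 3))
        params = np.full((2, 3), 0.4)
        new_state, new_params = adam_step(state, np.zeros((2, 3)), params, 0.1)
        np.testing.assert_array_equal(new_params, params)
        assert new_state.t == 1

    def test_first_step_magnitude_is_learning_rate(self):
        # with constant gradient g, the bias-corrected first step is
        # -lr * g / (|g| + eps), i.e. about -lr in the gradient direction
        state = AdamState.zeros(3)
        params = np.array([1.0, 1.0, 1.0])
        g = np.array([0.3, 2.0, -0.7])
        _, new_params = adam_step(state, g, params, 0.05)
        expected = params - 0.05 * g / (np.abs(g) + ADAM_EPS)
        np.testing.assert_allclose(new_params, expected, rtol=1e-9)

    def test_params_clipped_to_nonnegative(self):
        state = AdamState.zeros(2)
        _, new_params = adam_step(state, np.array([1.0, 1.0]), np.array([0.01, 0.5]), 0.1)
        assert np.all(new_params >= 0)
        assert new_params[0] == 0.0

    def test_inputs_not_mutated(self):
        state = AdamState.zeros(2)
        params = np.array([0.5, 0.5])
        adam_step(state, np.array([1.0, -1.0]), params, 0.1)
        np.testing.assert_array_equal(params, [0.5, 0.5])
        assert state.t == 0 and not state.m.any()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            adam_step(AdamState.zeros(2), np.zeros(3), np.zeros(3), 0.1)


class TestModeGradient:
    def test_saturated_fully_observed_block_has_zero_gradient(self):
        # m = x = 2 at every cell of a fully observed block: the exact
        # linear term cancels the full-batch ratio term in every mode
        shape = (3, 4, 2)
        factors = [np.full((shape[0], 1), 2.0), np.ones((shape[1], 1)), np.ones((shape[2], 1))]
        model = KruskalModel(np.ones(1), factors)
        idx = np.array(list(np.ndindex(*shape)), dtype=np.int64)
        X = SparseCountTensor(shape, idx, np.full(len(idx), 2, dtype=np.int64))
        for mode in range(3):
            g = mode_gradient(X, model, mode, full_ranges(shape))
            np.testing.assert_allclose(g, 0.0, atol=1e-10)

    def test_full_batch_matches_dense_finite_differences(self, rng):
        shape = (5, 4, 3)
        X = random_tensor(rng, shape, density=0.6)
        factors = [rng.uniform(0.2, 1.0, size=(I, 3)) for I in shape]
        model = KruskalModel(np.ones(3), factors)
        reg = RegularizerConfig(beta_angular=0.05, beta_l2=0.03,
                                beta_supervision=0.07, angular_threshold=0.2)
        labels = rng.integers(0, 2, size=shape[0])
        labels[0] = -1  # one unlabeled entity
        theta = rng.normal(size=4)
        Xd = dense_from_tensor(X)
        for mode in range(3):
            g = mode_gradient(X, model, mode, full_ranges(shape), reg=reg,
                              labels=labels, theta=theta)
            fd = fd_mode_gradient(Xd, model, mode, reg, labels, theta)
            np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-7)

    def test_sub_block_gradient_matches_restricted_finite_differences(self, rng):
        # gradient over a strict sub-block equals FD of the block-restricted loss
        shape = (6, 5, 4)
        ranges = [(2, 5), (0, 3), (1, 4)]
        factors = [rng.uniform(0.2, 1.0, size=(I, 2)) for I in shape]
        model = KruskalModel(np.ones(2), factors)
        D = np.zeros(shape)
        D[2:5, 0:3, 1:4] = rng.integers(0, 5, size=(3, 3, 3))
        idx = np.argwhere(D > 0)
        X = SparseCountTensor(shape, idx.astype(np.int64), D[tuple(idx.T)].astype(np.int64))
        reg = RegularizerConfig(beta_angular=0.0, beta_l2=0.0, beta_supervision=0.0)

        def block_loss(model_):
            M = dense_from_model(model_)[2:5, 0:3, 1:4]
            return dense_poisson_loss(D[2:5, 0:3, 1:4], M)

        for mode in range(3):
            g = mode_gradient(X, model, mode, ranges, reg=reg)
            lo, hi = ranges[mode]
            fd = np.zeros((hi - lo, 2))
            for i in range(lo, hi):
                for r in range(2):
                    step = 1e-6
                    up, dn = model.copy(), model.copy()
                    up.factors[mode][i, r] += step
                    dn.factors[mode][i, r] -= step
                    fd[i - lo, r] = (block_loss(up) - block_loss(dn)) / (2 * step)
            np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-6)

    def test_minibatch_estimator_is_unbiased(self, rng):
        shape = (6, 5, 4)
        X = random_tensor(rng, shape, density=0.6)
        factors = [rng.uniform(0.2, 1.0, size=(I, 2)) for I in shape]
        model = KruskalModel(np.ones(2), factors)
        reg = RegularizerConfig(beta_angular=0.0, beta_supervision=0.0)
        exact = mode_gradient(X, model, 0, full_ranges(shape), reg=reg)
        batch = max(2, X.nnz // 4)
        acc = np.zeros_like(exact)
        draws = 2000
        sampler = np.random.default_rng(7)
        for _ in range(draws):
            pos = sampler.integers(0, X.nnz, size=batch)
            acc += mode_gradient(X, model, 0, full_ranges(shape), reg=reg, minibatch=pos)
        mean = acc / draws
        scale = np.abs(exact).max()
        np.testing.assert_allclose(mean, exact, atol=0.02 * scale)

    def test_block_with_empty_range_gets_zero_gradient(self, rng):
        shape = (4, 4, 4)
        X_block = SparseCountTensor(shape, np.empty((0, 3), dtype=np.int64),
                                    np.empty(0, dtype=np.int64))
        factors = [rng.uniform(size=(4, 2)) for _ in range(3)]
        model = KruskalModel(np.ones(2), factors)
        # one mode's range is empty, so the block holds no cells; zero the
        # penalties so only the (empty) Poisson term contributes
        reg = RegularizerConfig(beta_angular=0.0, beta_supervision=0.0)
        g = mode_gradient(X_block, model, 0, [(0, 2), (2, 2), (0, 4)], reg=reg)
        np.testing.assert_array_equal(g, 0.0)

    def test_nonzero_free_block_keeps_exact_linear_term(self, rng):
        shape = (4, 4, 4)
        X_block = SparseCountTensor(shape, np.empty((0, 3), dtype=np.int64),
                                    np.empty(0, dtype=np.int64))
        factors = [rng.uniform(0.2, 1.0, size=(4, 2)) for _ in range(3)]
        model = KruskalModel(np.ones(2), factors)
        ranges = [(0, 2), (1, 3), (0, 4)]
        reg = RegularizerConfig(beta_angular=0.0, beta_supervision=0.0)
        g = mode_gradient(X_block, model, 0, ranges, reg=reg)
        expected = (model.factors[1][1:3].sum(axis=0)
                    * model.factors[2][0:4].sum(axis=0))
        np.testing.assert_allclose(g, np.tile(expected, (2, 1)), rtol=1e-12)


class TestFitBlock:
    @staticmethod
    def _instance(rng, shape=(6, 5, 4), rank=2):
        X = random_tensor(rng, shape, density=0.5)
        factors = [rng.uniform(0.2, 1.0, size=(I, rank)) for I in shape]
        return X, KruskalModel(np.ones(rank), factors)

    def test_zero_inner_iterations_leave_model_unchanged(self, rng):
        X, model = self._instance(rng)
        config = FitConfig(rank=2, inner_iters=0)
        slices, _ = fit_block(X, model, full_ranges(X.shape), config,
                              np.random.default_rng(0))
        for n, A in enumerate(model.factors):
            np.testing.assert_array_equal(slices[n], A)

    def test_seeded_runs_are_bit_identical(self, rng):
        X, model = self._instance(rng)
        config = FitConfig(rank=2, inner_iters=5, learning_rate=0.01, batch_size=4)
        out1, st1 = fit_block(X, model.copy(), full_ranges(X.shape), config,
                              np.random.default_rng(42))
        out2, st2 = fit_block(X, model.copy(), full_ranges(X.shape), config,
                              np.random.default_rng(42))
        for n in out1:
            np.testing.assert_array_equal(out1[n], out2[n])
            np.testing.assert_array_equal(st1[n].m, st2[n].m)

    def test_rows_outside_block_untouched(self, rng):
        X, model = self._instance(rng)
        ranges = [(0, 3), (1, 4), (0, 2)]
        inside = np.all(
            [(X.indices[:, n] >= lo) & (X.indices[:, n] < hi)
             for n, (lo, hi) in enumerate(ranges)],
            axis=0,
        )
        X_block = SparseCountTensor(X.shape, X.indices[inside], X.values[inside])
        before = [A.copy() for A in model.factors]
        config = FitConfig(rank=2, inner_iters=3, learning_rate=0.05)
        slices, _ = fit_block(X_block, model, ranges, config,
                              np.random.default_rng(1))
        # fit_block must not mutate the input model at all
        for A, B in zip(model.factors, before):
            np.testing.assert_array_equal(A, B)
        for n, (lo, hi) in enumerate(ranges):
            assert slices[n].shape == (hi - lo, 2)

    def test_full_batch_descent_on_fixed_instance(self, rng):
        X, model = self._instance(rng)
        reg = RegularizerConfig(beta_angular=0.0, beta_supervision=0.0)
        config = FitConfig(rank=2, regularizers=reg, inner_iters=1,
                           learning_rate=0.01, batch_size=X.nnz,
                           step_scaling="none")
        losses = [poisson_loss(X, model)]
        adam = None
        for step in range(200):
            slices, adam = fit_block(X, model, full_ranges(X.shape), config,
                                     np.random.default_rng(step), adam=adam)
            for n in slices:
                model.factors[n][:, :] = slices[n]
            losses.append(poisson_loss(X, model))
        deltas = np.diff(losses)
        assert losses[-1] < losses[0]
        assert np.mean(deltas <= 1e-12) >= 0.95

    def test_constraints_hold_after_fit_block(self, rng):
        X, model = self._instance(rng)
        reg = RegularizerConfig(simplex_modes=(1,), simplex_radius=0.8,
                                hard_threshold_k=3)
        config = FitConfig(rank=2, regularizers=reg, inner_iters=8,
                           learning_rate=0.05, batch_size=8)
        slices, _ = fit_block(X, model, full_ranges(X.shape), config,
                              np.random.default_rng(3))
        for n, sl in slices.items():
            assert np.all(sl >= 0)
        for r in range(2):
            col = slices[1][:, r]
            assert col.sum() <= 0.8 + 1e-12
            assert np.count_nonzero(col) <= 3
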