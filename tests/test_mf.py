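"""Matrix-factorization imputation: predictions, updates, training."""

import numpy as np
import pytest

from distimpute.matrix import MaskedDistanceMatrix
from distimpute.mf import (
    FactorPair,
    MFConfig,
    mf_impute,
    mf_predict,
    mf_train,
    mf_update_entry,
)

from conftest import random_masked_matrix


class TestPredict:
    def test_rank_one_product(self):
        f = FactorPair(np.array([[0.5], [0.5]]), np.array([[0.5], [0.5]]))
        assert mf_predict(f, 1, 0) == pytest.approx(0.25)

    def test_zero_factor_predicts_zero(self, rng):
        f = FactorPair(np.zeros((4, 4)), rng.random((4, 4)))
        assert all(mf_predict(f, i, j) == 0.0 for i in range(4) for j in range(4))

    def test_matches_bruteforce_summation(self, rng):
        n = 6
        f = FactorPair(rng.random((n, n)), rng.random((n, n)))
        for i in range(n):
            for j in range(n):
                brute = sum(f.x[i, k] * f.y[j, k] for k in range(n))
                assert mf_predict(f, i, j) == pytest.approx(brute, rel=1e-12)


class TestUpdateEntry:
    def test_hand_computed_single_step(self):
        # x=y=0.5, r=1: e=0.75, both coordinates move to 0.50148
        f = FactorPair(np.array([[0.0], [0.5]]), np.array([[0.5], [0.0]]))
        out = mf_update_entry(f, 1, 0, 1.0, MFConfig(k=1))
        assert out.x[1, 0] == pytest.approx(0.50148, abs=1e-12)
        assert out.y[0, 0] == pytest.approx(0.50148, abs=1e-12)

    def test_zero_error_zero_beta_is_fixed_point(self, rng):
        x = rng.random((3, 2))
        y = rng.random((3, 2))
        r = float(x[2] @ y[0])
        out = mf_update_entry(FactorPair(x, y), 2, 0, r, MFConfig(beta=0.0))
        assert np.allclose(out.x, x) and np.allclose(out.y, y)

    def test_upper_triangle_rejected(self, rng):
        f = FactorPair(rng.random((3, 3)), rng.random((3, 3)))
        with pytest.raises(ValueError):
            mf_update_entry(f, 0, 2, 1.0, MFConfig())

    @pytest.mark.parametrize("beta", [0.0, 0.02])
    def test_update_matches_finite_difference_gradient(self, rng, beta):
        # per-entry objective: (r - x.y)^2 + (beta/2)(|x|^2 + |y|^2);
        # the update step must equal -alpha * central-difference gradient
        h = 1e-5
        for _ in range(25):
            k = int(rng.integers(1, 5))
            x = rng.random(k) + 0.5
            y = rng.random(k) + 0.5
            r = float(rng.random() * 2)

            def obj(xv, yv):
                e = r - xv @ yv
                return e * e + beta / 2 * (xv @ xv + yv @ yv)

            cfg = MFConfig(alpha=0.002, beta=beta, k=k)
            f = FactorPair(
                np.vstack([np.zeros(k), x]), np.vstack([y, np.zeros(k)])
            )
            out = mf_update_entry(f, 1, 0, r, cfg)
            step_x = (out.x[1] - x) / cfg.alpha
            step_y = (out.y[0] - y) / cfg.alpha
            for idx in range(k):
                ex = np.eye(k)[idx] * h
                gx = (obj(x + ex, y) - obj(x - ex, y)) / (2 * h)
                gy = (obj(x, y + ex) - obj(x, y - ex)) / (2 * h)
                assert step_x[idx] == pytest.approx(-gx, rel=1e-6)
                assert step_y[idx] == pytest.approx(-gy, rel=1e-6)


class TestTrain:
    def test_rank_one_fit_converges_to_observed_value(self):
        # N=2, one observed value, beta=0: SGD on a single rank-1 entry
        # must drive the squared error below tol and the prediction to v
        v = 0.7
        m = MaskedDistanceMatrix(("a", "b"), np.array([[0.0, v], [v, 0.0]]))
        f = mf_train(m, MFConfig(beta=0.0, seed=1))
        assert f.converged
        assert np.all(np.diff(f.error_trace) <= 1e-12)
        assert mf_predict(f, 1, 0) == pytest.approx(v, abs=1e-3)

    def test_bit_identical_trace_for_same_seed(self, rng):
        m = random_masked_matrix(rng, 6, 3)
        cfg = MFConfig(max_iter=300, seed=9)
        a = mf_train(m, cfg)
        b = mf_train(m, cfg)
        assert np.array_equal(a.error_trace, b.error_trace)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_full_rank_interpolates_complete_matrix(self, rng):
        m = random_masked_matrix(rng, 8, 0)
        f = mf_train(m, MFConfig(beta=0.0, k=8, seed=4))
        assert f.error_trace[-1] < 1e-3

    def test_error_trace_decreases_on_unit_scale(self, rng):
        m = random_masked_matrix(rng, 10, 5)
        f = mf_train(m, MFConfig(max_iter=500, seed=2))
        assert f.error_trace[-1] <= f.error_trace[0]

    def test_all_missing_rejected(self):
        n = 4
        mask = ~np.eye(n, dtype=bool)
        m = MaskedDistanceMatrix(
            tuple("abcd"), np.zeros((n, n)), mask
        )
        with pytest.raises(ValueError):
            mf_train(m, MFConfig())


class TestImpute:
    def test_complete_input_returned_unchanged(self, rng):
        m = random_masked_matrix(rng, 6, 0)
        out = mf_impute(m, MFConfig(seed=0))
        assert np.array_equal(out.values, m.values)

    def test_contract_on_random_masked_inputs(self, rng):
        for _ in range(5):
            m = random_masked_matrix(rng, 8, int(rng.integers(1, 10)))
            out = mf_impute(m, MFConfig(max_iter=300, seed=11))
            assert out.is_complete
            assert np.array_equal(out.values, out.values.T)
            assert np.all(out.values >= 0)
            assert np.all(out.values.diagonal() == 0)
            # observed entries bit-exact
            assert np.array_equal(out.values[~m.mask], m.values[~m.mask])

    def test_seed_determinism_end_to_end(self, rng):
        m = random_masked_matrix(rng, 7, 4)
        a = mf_impute(m, MFConfig(max_iter=300, seed=5))
        b = mf_impute(m, MFConfig(max_iter=300, seed=5))
        assert np.array_equal(a.values, b.values)
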