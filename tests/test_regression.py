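"""FIR regression construction, simulation and elastic-net augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import toeplitz_rows_bruteforce
from vo2fir.kernels import KernelSpec, build_kernel, upper_cholesky_of_inverse
from vo2fir.regression import (
    FIRModel,
    SampledSignal,
    augment,
    build_regressor,
    restore,
    simulate_fir,
)


def step_signal(off: int, on: int) -> SampledSignal:
    return SampledSignal(values=np.r_[np.zeros(off), np.ones(on)])


class TestBuildRegressor:
    def test_small_example(self):
        u = SampledSignal(values=[1, 2, 3, 4])
        y = SampledSignal(values=[10, 20, 30, 40])
        prob = build_regressor(u, y, 2)
        assert np.array_equal(prob.Y, [30, 40])
        assert np.array_equal(prob.Phi, [[2, 1], [3, 2]])

    def test_single_row_at_maximal_order(self):
        u = SampledSignal(values=[1.0, 2.0, 3.0])
        y = SampledSignal(values=[4.0, 5.0, 6.0])
        prob = build_regressor(u, y, 2)
        assert prob.N == 1
        assert np.array_equal(prob.Phi, [[2.0, 1.0]])
        assert np.array_equal(prob.Y, [6.0])

    def test_insufficient_data_raises(self):
        u = SampledSignal(values=np.ones(5))
        with pytest.raises(ValueError, match="insufficient data"):
            build_regressor(u, u, 5)

    def test_step_input_matches_bruteforce_rows(self, rng):
        u = step_signal(180, 300)
        y = SampledSignal(values=rng.normal(size=480))
        prob = build_regressor(u, y, 120)
        Y0, Phi0 = toeplitz_rows_bruteforce(u.values, y.values, 120)
        assert np.array_equal(prob.Y, Y0)
        assert np.array_equal(prob.Phi, Phi0)
        # each row sum counts the ones inside its lag window
        assert np.array_equal(prob.Phi.sum(axis=1), Phi0.sum(axis=1))

    def test_noise_free_fir_data_satisfies_y_equals_phi_g(self, rng):
        g = rng.normal(size=12)
        u = SampledSignal(values=rng.normal(size=60))
        y = simulate_fir(FIRModel(g=g), u)
        prob = build_regressor(u, y, 12)
        assert np.allclose(prob.Y, prob.Phi @ g, atol=1e-12)


class TestSimulateFir:
    def test_unit_delay_identity(self):
        g = np.zeros(10)
        g[0] = 1.0
        u = step_signal(0, 8)
        y = simulate_fir(FIRModel(g=g), u)
        assert np.array_equal(y.values, np.r_[0.0, np.ones(7)])

    def test_zero_coefficients_give_zero_output(self):
        u = step_signal(2, 6)
        y = simulate_fir(FIRModel(g=np.zeros(4)), u)
        assert np.array_equal(y.values, np.zeros(8))

    def test_first_order_plant_convolution_matches_recursion(self):
        # exact: with m = M-1 the FIR truncation drops nothing for a
        # step applied inside the record
        k, p, M = 15.0, np.exp(-0.1), 120
        g = k * (1 - p) * p ** np.arange(M - 1)
        u = step_signal(10, M - 10)
        y = simulate_fir(FIRModel(g=g), u).values
        y_rec = np.zeros(M)
        for n in range(1, M):
            y_rec[n] = p * y_rec[n - 1] + k * (1 - p) * u.values[n - 1]
        assert np.allclose(y, y_rec, atol=1e-10)

    def test_noise_requires_generator(self):
        u = step_signal(1, 3)
        with pytest.raises(ValueError, match="generator"):
            simulate_fir(FIRModel(g=[1.0]), u, noise_sd=1.0)

    def test_noise_is_reproducible(self):
        u = step_signal(1, 50)
        a = simulate_fir(FIRModel(g=[1.0, 0.5]), u, 0.3, np.random.default_rng(5))
        b = simulate_fir(FIRModel(g=[1.0, 0.5]), u, 0.3, np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)


class TestAugmentRestore:
    def test_gamma_zero_leaves_rows_unchanged(self, rng):
        prob = build_regressor(
            SampledSignal(values=rng.normal(size=9)),
            SampledSignal(values=rng.normal(size=9)),
            3,
        )
        aug = augment(prob, np.eye(3), 0.0)
        assert np.allclose(aug.Phistar[:6], prob.Phi)
        assert np.allclose(aug.Phistar[6:], 0.0)
        assert np.array_equal(aug.Ystar[6:], np.zeros(3))

    def test_scalar_example(self):
        prob = build_regressor(
            SampledSignal(values=[2.0, 0.0]), SampledSignal(values=[1.0, 5.0]), 1
        )
        aug = augment(prob, np.eye(1), 3.0)
        assert np.allclose(aug.Phistar, 0.5 * np.array([[2.0], [np.sqrt(3.0)]]))

    def test_augmented_residual_identity(self, rng, random_pd):
        """||Y* - Phi* theta*||^2 with theta* = sqrt(1+g) theta equals the
        original residual plus the quadratic kernel penalty, so the augmented
        L1 cost at theta* equals the kernelized elastic-net cost at theta."""
        m, N, gamma, alpha = 5, 12, 3.7, 2.0
        Phi = rng.normal(size=(N, m))
        Y = rng.normal(size=N)
        from vo2fir.regression import RegressionProblem

        prob = RegressionProblem(Y=Y, Phi=Phi, m=m)
        R = upper_cholesky_of_inverse(random_pd(m))
        aug = augment(prob, R, gamma)
        for _ in range(10):
            th = rng.normal(size=m)
            th_star = np.sqrt(1 + gamma) * th
            lhs = np.sum((aug.Ystar - aug.Phistar @ th_star) ** 2)
            rhs = np.sum((Y - Phi @ th) ** 2) + gamma * np.sum((R @ th) ** 2)
            assert np.isclose(lhs, rhs, rtol=1e-10)
            cost5 = lhs + alpha / np.sqrt(1 + gamma) * np.abs(th_star).sum()
            cost4 = rhs + alpha * np.abs(th).sum()
            assert np.isclose(cost5, cost4, rtol=1e-10)

    @given(
        gamma=st.floats(0.0, 50.0),
        scale=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_restore_inverts_scaling(self, gamma, scale):
        th = scale * np.arange(1.0, 5.0)
        assert np.allclose(restore(np.sqrt(1 + gamma) * th, gamma), th)

    def test_restore_examples(self):
        assert np.allclose(restore(np.array([2.0]), 0.0), [2.0])
        assert np.allclose(restore(np.array([2.0]), 3.0), [1.0])


class TestSampledSignalIO:
    def test_csv_roundtrip(self, tmp_path):
        sig = SampledSignal(values=[1.5, 2.5, -3.0], ts=1.0, t0=10.0)
        path = tmp_path / "sig.csv"
        sig.to_csv(path)
        back = SampledSignal.from_csv(path)
        assert np.allclose(back.values, sig.values)
        assert back.t0 == 10.0 and back.ts == 1.0

    def test_nonuniform_csv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,value\n0,1\n1,2\n5,3\n")
        with pytest.raises(ValueError, match="uniformly"):
            SampledSignal.from_csv(path)

    def test_fir_csv_roundtrip(self, tmp_path):
        fir = FIRModel(g=[0.5, -0.25, 0.1])
        path = tmp_path / "fir.csv"
        fir.to_csv(path)
        assert np.allclose(FIRModel.from_csv(path).g, fir.g)
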