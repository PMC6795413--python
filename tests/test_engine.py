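"""TLM/adjoint construction, Jacobians and the verification tests."""

import numpy as np
import pytest

from dualda import dual as dm
from dualda.engine import (
    JacobianSizeError,
    ModelFunction,
    adjoint_bruteforce,
    adjoint_multidual,
    build_jacobian,
    dot_product_test,
    evaluate_model,
    evaluate_tlm,
    evaluate_tlm_with_real,
    taylor_test,
)


def linear_model(A):
    A = np.asarray(A, float)

    def fn(x):
        return [sum(A[i, j] * x[j] for j in range(A.shape[1]))
                for i in range(A.shape[0])]

    return ModelFunction(fn, A.shape[0], name="linear")


def smooth_model(n, seed=0):
    """A coupled nonlinear map using the full overloaded function set."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n)) * 0.3

    def fn(x):
        mixed = [sum(A[i, j] * x[j] for j in range(n)) for i in range(n)]
        return [
            dm.exp(0.1 * m) + dm.sin(x[i]) * 0.5 + x[i] / (2.0 + dm.tanh(m))
            for i, m in enumerate(mixed)
        ]

    return ModelFunction(fn, n, name="smooth")


def fd_jacobian(model, x, step=1e-6):
    """Central-difference oracle, step 1e-6*(1+|x_i|) per component."""
    n = model.n
    J = np.empty((n, n))
    for i in range(n):
        h = step * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (evaluate_model(model, xp) - evaluate_model(model, xm)) / (2 * h)
    return J


class TestEvaluateTlm:
    def test_linear_model_gives_matrix_vector_product(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((4, 4))
        m = linear_model(A)
        x, u = rng.standard_normal(4), rng.standard_normal(4)
        assert evaluate_tlm(m, x, u) == pytest.approx(A @ u, rel=1e-14)

    def test_elementwise_polynomial_derivative(self):
        # f(x) = 2(x-1)^2 + 3, f'(3) = 8
        m = ModelFunction(lambda x: [2.0 * (v - 1.0) ** 2 + 3.0 for v in x], 1)
        assert evaluate_tlm(m, [3.0], [1.0])[0] == 8.0

    def test_zero_seed_gives_zero(self):
        m = smooth_model(5)
        out = evaluate_tlm(m, np.ones(5), np.zeros(5))
        assert np.all(out == 0.0)

    def test_real_part_bitwise_equals_plain_evaluation(self):
        m = smooth_model(6, seed=3)
        x = np.random.default_rng(4).standard_normal(6)
        plain = evaluate_model(m, x)
        real, _ = evaluate_tlm_with_real(m, x, np.ones(6))
        assert np.array_equal(plain, real)

    def test_linearity_in_the_seed(self):
        m = smooth_model(5, seed=5)
        rng = np.random.default_rng(6)
        x, u, v = (rng.standard_normal(5) for _ in range(3))
        lhs = evaluate_tlm(m, x, 2.0 * u - 3.0 * v)
        rhs = 2.0 * evaluate_tlm(m, x, u) - 3.0 * evaluate_tlm(m, x, v)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestAdjoints:
    def test_bruteforce_on_linear_model_is_transpose(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((5, 5))
        m = linear_model(A)
        x, w = rng.standard_normal(5), rng.standard_normal(5)
        assert adjoint_bruteforce(m, x, w) == pytest.approx(A.T @ w, rel=1e-13)

    def test_zero_adjoint_seed_gives_zero(self):
        m = smooth_model(4)
        assert np.all(adjoint_bruteforce(m, np.ones(4), np.zeros(4)) == 0.0)

    def test_bruteforce_matches_finite_difference_transpose(self):
        m = smooth_model(3, seed=8)
        rng = np.random.default_rng(9)
        x, w = rng.standard_normal(3), rng.standard_normal(3)
        expected = fd_jacobian(m, x).T @ w
        assert adjoint_bruteforce(m, x, w) == pytest.approx(expected, rel=1e-6)

    def test_multidual_matches_bruteforce_bitwise(self):
        m = smooth_model(7, seed=10)
        rng = np.random.default_rng(11)
        x, w = rng.standard_normal(7), rng.standard_normal(7)
        assert np.array_equal(
            adjoint_multidual(m, x, w), adjoint_bruteforce(m, x, w)
        )

    def test_chunked_multidual_matches_full(self):
        m = smooth_model(6, seed=12)
        rng = np.random.default_rng(13)
        x, w = rng.standard_normal(6), rng.standard_normal(6)
        full = adjoint_multidual(m, x, w)
        assert np.array_equal(adjoint_multidual(m, x, w, chunk_size=2), full)

    def test_call_counts_n_versus_one(self):
        n = 5
        m = smooth_model(n, seed=14)
        x = np.random.default_rng(15).standard_normal(n)
        m.counter.reset()
        adjoint_bruteforce(m, x, np.ones(n))
        assert m.counter.dual_calls == n
        m.counter.reset()
        adjoint_multidual(m, x, np.ones(n))
        assert m.counter.multidual_calls == 1
        assert m.counter.evaluator_calls == 1


class TestJacobian:
    def test_identity_model(self):
        m = ModelFunction(lambda x: list(x), 3, name="identity")
        J = build_jacobian(m, np.zeros(3)).dense()
        assert np.array_equal(J, np.eye(3))

    def test_elementwise_polynomial_diagonal(self):
        m = ModelFunction(lambda x: [2.0 * (v - 1.0) ** 2 + 3.0 for v in x], 2)
        J = build_jacobian(m, np.array([3.0, 0.0])).dense()
        # f'(x) = 4(x-1): diag(8, -4)
        assert np.array_equal(J, np.diag([8.0, -4.0]))

    def test_matches_finite_differences_on_random_smooth_model(self):
        m = smooth_model(8, seed=16)
        x = np.random.default_rng(17).standard_normal(8)
        J = build_jacobian(m, x).dense()
        assert J == pytest.approx(fd_jacobian(m, x), rel=1e-6, abs=1e-8)

    def test_size_cap_is_enforced(self):
        m = ModelFunction(lambda x: list(x), 10)
        with pytest.raises(JacobianSizeError, match="matrix-free"):
            build_jacobian(m, np.zeros(10), max_size=5)


class TestDotProduct:
    def test_linear_model_discrepancy_at_rounding_level(self):
        A = np.random.default_rng(18).standard_normal((6, 6))
        m = linear_model(A)
        rep = dot_product_test(m, np.zeros(6), trials=5, seed=0)
        assert rep.passed and rep.max_discrepancy < 1e-13

    def test_corrupted_adjoint_fails(self):
        """Negative control: one sign flip must be detected."""
        A = np.random.default_rng(19).standard_normal((4, 4))
        m = linear_model(A)

        def bad_adjoint(x, w):
            out = adjoint_multidual(m, x, w)
            out[0] = -out[0]
            return out

        rep = dot_product_test(m, np.zeros(4), trials=5, seed=0,
                               adjoint=bad_adjoint)
        assert not rep.passed

    def test_report_table_has_one_row_per_trial(self):
        m = linear_model(np.eye(3))
        rep = dot_product_test(m, np.zeros(3), trials=4, seed=1)
        assert len(rep.to_frame()) == 4


class TestTaylor:
    @staticmethod
    def quadratic(x):
        H = np.diag([2.0, 0.5, 3.0])
        return 0.5 * float(x @ H @ x), H @ x

    def test_exact_gradient_passes(self):
        rep = taylor_test(self.quadratic, np.array([1.0, -2.0, 0.5]),
                          np.array([0.3, 1.0, -0.7]))
        assert rep.passed and rep.slope >= 1.9

    def test_wrong_gradient_slope_collapses_to_one(self):
        """Negative control: a 1% gradient error gives first-order remainder."""

        def wrong(x):
            j, g = self.quadratic(x)
            return j, 1.01 * g

        rep = taylor_test(wrong, np.array([1.0, -2.0, 0.5]),
                          np.array([0.3, 1.0, -0.7]))
        assert rep.slope < 1.5

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            taylor_test(self.quadratic, np.zeros(3), np.zeros(3))
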