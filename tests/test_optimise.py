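"""Dispatch table, minimisation driver, Jacobians, and confidence intervals."""

import numpy as np
import pytest

from femfit.forward_models import ForwardModel, ForwardOutput, OutputKind
from femfit.objective import (
    Aggregation,
    Comparison,
    ErrorForm,
    Observation,
    ObjectiveSpec,
)
from femfit.optimise import (
    OptimisationResult,
    OptimiserOptions,
    ParameterSet,
    confidence_intervals,
    minimise,
    numerical_jacobian,
    select_method,
    write_history,
)

DIFF_SCALAR = ObjectiveSpec(error_form=ErrorForm.DIFFERENCE)
DIFF_VECTOR = ObjectiveSpec(
    comparison=Comparison.DIRECT,
    error_form=ErrorForm.DIFFERENCE,
    aggregation=Aggregation.CONCATENATED_RESIDUALS,
)


def vector_model(name, fn):
    return ForwardModel(name, OutputKind.LIST, lambda p: ForwardOutput.from_list(fn(p)))


def scalar_model(name, fn):
    return ForwardModel(name, OutputKind.SCALAR, lambda p: ForwardOutput.scalar(fn(p)))


class TestSelectMethod:
    @pytest.mark.parametrize(
        "n,kind,bounded,expected",
        [
            (1, "scalar", True, "brent"),
            (1, "scalar", False, "brent"),
            (2, "scalar", True, "l-bfgs-b"),
            (2, "scalar", False, "cg"),
            (2, "functional", True, "trf"),
            (3, "functional", False, "lm"),
        ],
    )
    def test_table_cells(self, n, kind, bounded, expected):
        assert select_method(n, kind, bounded) == expected

    def test_univariate_functional_is_undefined(self):
        with pytest.raises(ValueError, match="univariate functional"):
            select_method(1, "functional", True)


class TestMinimise:
    def quadratic_pair(self):
        # observation 3.0 with difference residual -> objective |x - 3|
        return [(scalar_model("q", lambda p: p[0]), Observation("q", 3.0))]

    def test_brent_quadratic(self):
        ps = ParameterSet(("x",), bounds=((0.0, 10.0),))
        res = minimise(self.quadratic_pair(), DIFF_SCALAR, ps,
                       OptimiserOptions(x_tol=1e-10))
        assert res.method == "brent"
        assert res.final_params[0] == pytest.approx(3.0, abs=1e-6)
        assert res.n_evaluations >= res.n_iterations

    def test_newton_by_explicit_name(self):
        # two residuals make the RMS objective smooth: sqrt(((x-3)^2 + 1) / 2)
        ps = ParameterSet(("x",), initial=[1.0], bounds=((0.0, 10.0),))
        pairs = [
            (scalar_model("q", lambda p: p[0]), Observation("q", 3.0)),
            (scalar_model("r", lambda p: 1.0), Observation("r", 0.0)),
        ]
        res = minimise(pairs, DIFF_SCALAR, ps, OptimiserOptions(x_tol=1e-9),
                       method="newton")
        assert res.method == "newton"
        assert res.final_params[0] == pytest.approx(3.0, rel=1e-4)

    def test_levenberg_marquardt_linear_residuals(self):
        pairs = [(vector_model("lin", lambda p: [p[0], p[1], p[0] + p[1]]),
                  Observation("lin", np.array([1.0, 2.0, 3.0])))]
        ps = ParameterSet(("a", "b"), initial=[0.3, 0.3])
        res = minimise(pairs, DIFF_VECTOR, ps)
        assert res.method == "lm"
        np.testing.assert_allclose(res.final_params, [1.0, 2.0], atol=1e-8)
        assert res.objective_value == pytest.approx(0.0, abs=1e-10)

    def test_lm_matches_normal_equations(self):
        # overdetermined inconsistent linear system: y ~ a*x + b
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.1, 0.9, 2.2, 2.8])
        pairs = [(vector_model("fit", lambda p: p[0] * x + p[1]),
                  Observation("fit", y))]
        ps = ParameterSet(("a", "b"), initial=[0.5, 0.5])
        res = minimise(pairs, DIFF_VECTOR, ps, OptimiserOptions(x_tol=1e-12))
        A = np.column_stack([x, np.ones_like(x)])
        expected = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(res.final_params, expected, rtol=1e-8)

    def test_normal_termination_on_f_tol(self):
        ps = ParameterSet(("x",), bounds=((0.0, 10.0),))
        res = minimise(self.quadratic_pair(), DIFF_SCALAR, ps,
                       OptimiserOptions(f_tol=0.5))
        assert res.termination == "objective_tol"
        assert res.objective_value <= 0.5

    def test_bounds_respected_by_every_probe(self):
        queried = []

        def f(p):
            queried.append(np.copy(p))
            return (p[0] - 1.0) ** 2 + (p[1] - 2.0) ** 2

        pairs = [(scalar_model("b", f), Observation("b", 0.0))]
        bounds = ((0.5, 1.6), (0.5, 1.8))
        ps = ParameterSet(("a", "b"), initial=[1.0, 1.0], bounds=bounds)
        res = minimise(pairs, DIFF_SCALAR, ps)
        assert res.method == "l-bfgs-b"
        pts = np.array(queried)
        for k, (lo, hi) in enumerate(bounds):
            assert np.all(pts[:, k] >= lo - 1e-12)
            assert np.all(pts[:, k] <= hi + 1e-12)
        # a's optimum is interior, b's is clipped at its upper bound
        np.testing.assert_allclose(res.final_params, [1.0, 1.8], atol=1e-6)

    def test_trf_probes_stay_in_bounds(self):
        queried = []

        def f(p):
            queried.append(np.copy(p))
            return [p[0] - 1.0, p[1] - 2.0]

        pairs = [(vector_model("b", f), Observation("b", np.zeros(2)))]
        bounds = ((0.1, 5.0), (0.1, 5.0))
        ps = ParameterSet(("a", "b"), initial=[0.5, 0.5], bounds=bounds)
        res = minimise(pairs, DIFF_VECTOR, ps)
        assert res.method == "trf"
        pts = np.array(queried)
        assert np.all(pts >= 0.1 - 1e-12) and np.all(pts <= 5.0 + 1e-12)
        np.testing.assert_allclose(res.final_params, [1.0, 2.0], rtol=1e-6)

    def test_best_so_far_monotone(self):
        ps = ParameterSet(("x",), bounds=((0.0, 10.0),))
        res = minimise(self.quadratic_pair(), DIFF_SCALAR, ps,
                       OptimiserOptions(history=True))
        values = [v for _, _, v in res.history]
        running = np.minimum.accumulate(values)
        assert np.all(np.diff(running) <= 0 + 1e-15)

    def test_objective_exception_captured_as_failure(self):
        calls = {"n": 0}

        def f(p):
            calls["n"] += 1
            if calls["n"] > 3:
                raise RuntimeError("solver exploded")
            return (p[0] - 3.0) ** 2

        pairs = [(scalar_model("x", f), Observation("x", 0.0))]
        ps = ParameterSet(("x",), initial=[1.0], bounds=((0.0, 10.0),))
        res = minimise(pairs, DIFF_SCALAR, ps, method="newton")
        assert res.termination == "failure"
        assert "solver exploded" in res.message

    def test_objective_value_recheckable(self):
        from femfit.objective import evaluate_group

        ps = ParameterSet(("x",), bounds=((0.0, 10.0),))
        pairs = self.quadratic_pair()
        res = minimise(pairs, DIFF_SCALAR, ps)
        again = evaluate_group(res.final_params, pairs, DIFF_SCALAR)
        assert res.objective_value == pytest.approx(again.value, rel=1e-12)


class TestNumericalJacobian:
    def test_linear_residual(self):
        J = numerical_jacobian(lambda x: np.array([2.0 * x[0]]), [1.0], 1e-6)
        assert J.shape == (1, 1)
        assert J[0, 0] == pytest.approx(2.0, abs=1e-5)

    def test_product_partials(self):
        J = numerical_jacobian(lambda x: np.array([x[0] * x[1]]), [2.0, 3.0], 1e-6)
        np.testing.assert_allclose(J, [[3.0, 2.0]], atol=1e-5)

    def test_constant_residuals_zero(self):
        J = numerical_jacobian(lambda x: np.array([1.0, 2.0]), [0.5, 0.5], 1e-6)
        np.testing.assert_array_equal(J, np.zeros((2, 2)))

    def test_scalar_objective_gives_gradient(self):
        g = numerical_jacobian(lambda x: float(x[0] ** 2 + 3 * x[1]), [1.0, 0.0], 1e-7)
        assert g.shape == (2,)
        np.testing.assert_allclose(g, [2.0, 3.0], atol=1e-5)

    def test_backward_difference_at_upper_bound(self):
        probes = []

        def f(x):
            probes.append(float(x[0]))
            assert x[0] <= 2.0, "probe crossed the upper bound"
            return np.array([x[0] ** 2])

        J = numerical_jacobian(f, [2.0], 1e-6, bounds=((0.0, 2.0),))
        assert J[0, 0] == pytest.approx(4.0, abs=1e-4)
        assert max(probes) <= 2.0

    def test_failed_probe_flags_column(self):
        def f(x):
            if x[1] != 0.5:
                return np.array([np.nan, np.nan])
            return np.array([x[0], x[0]])

        J = numerical_jacobian(f, [1.0, 0.5], 1e-6)
        assert np.all(np.isnan(J[:, 1])) and np.all(np.isfinite(J[:, 0]))


class TestConfidenceIntervals:
    def line_result(self, y, x=np.array([1.0, 2.0, 3.0])):
        a_hat = float(x @ y / (x @ x))  # closed-form least squares
        r = a_hat * x - y
        return OptimisationResult(
            parameter_names=("a",),
            final_params=np.array([a_hat]),
            objective_value=float(np.sqrt(np.mean(r**2))),
            n_iterations=1,
            n_evaluations=1,
            termination="objective_tol",
            message="",
            method="lm",
            jacobian=x.reshape(-1, 1),
            residuals=r,
        )

    def test_perfect_fit_zero_width(self):
        res = self.line_result(np.array([1.0, 2.0, 3.0]))
        rep = confidence_intervals(res, 3)
        lo, hi = rep.intervals[0]
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)
        assert rep.residual_variance == 0.0

    def test_matches_closed_form_covariance(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.1, 1.9, 3.1])
        res = self.line_result(y)
        rep = confidence_intervals(res, 3)
        a_hat = x @ y / (x @ x)
        s2 = np.sum((a_hat * x - y) ** 2) / (3 - 1)
        assert rep.covariance[0, 0] == pytest.approx(s2 / np.sum(x**2), rel=1e-10)
        assert rep.intervals[0][0] <= a_hat <= rep.intervals[0][1]

    def test_doubling_residuals_quadruples_covariance(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.1, 1.9, 3.1])
        res = self.line_result(y)
        base = confidence_intervals(res, 3).covariance[0, 0]
        import dataclasses

        doubled = dataclasses.replace(res, residuals=2.0 * res.residuals)
        assert confidence_intervals(doubled, 3).covariance[0, 0] == pytest.approx(
            4.0 * base, rel=1e-12
        )

    def test_singular_jtj_reports_direction(self):
        res = OptimisationResult(
            parameter_names=("a", "b"),
            final_params=np.array([1.0, 1.0]),
            objective_value=0.1,
            n_iterations=1,
            n_evaluations=1,
            termination="objective_tol",
            message="",
            method="lm",
            jacobian=np.array([[1.0, 1.0], [2.0, 2.0]]),  # rank 1: only a+b seen
            residuals=np.array([0.1, -0.1]),
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            confidence_intervals(res, 2 + 1)

    def test_needs_more_observations_than_params(self):
        res = self.line_result(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            confidence_intervals(res, 1)


class TestWriteHistory:
    def test_row_count_matches_iterations(self, tmp_path):
        def f(p):
            return (p[0] - 1.0) ** 2 + (p[1] - 2.0) ** 2

        pairs = [(scalar_model("h", f), Observation("h", 0.0))]
        ps = ParameterSet(("a", "b"), initial=[0.2, 0.2], bounds=((0.0, 5.0), (0.0, 5.0)))
        res = minimise(pairs, DIFF_SCALAR, ps, OptimiserOptions(history=True))
        path = tmp_path / "history.txt"
        write_history(res, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "iter\ta\tb\tobjective"
        # initial point is iteration 0, then one row per accepted iterate
        assert len(lines) - 1 == res.n_iterations + 1

    def test_rerun_overwrites(self, tmp_path):
        def f(p):
            return (p[0] - 1.0) ** 2

        pairs = [(scalar_model("h", f), Observation("h", 0.0))]
        ps = ParameterSet(("a",), bounds=((0.0, 5.0),))
        res = minimise(pairs, DIFF_SCALAR, ps, OptimiserOptions(history=True))
        path = tmp_path / "history.txt"
        write_history(res, path)
        first = path.read_text()
        write_history(res, path)
        assert path.read_text() == first

    def test_history_disabled_raises(self):
        res = OptimisationResult(
            parameter_names=("a",),
            final_params=np.array([1.0]),
            objective_value=0.0,
            n_iterations=0,
            n_evaluations=1,
            termination="objective_tol",
            message="",
            method="brent",
        )
        with pytest.raises(ValueError, match="history"):
            write_history(res, "/tmp/never-written.txt")
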