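"""Optimiser dispatch, minimisation driver, and confidence intervals.

The method table mirrors the calibration tool's contract: the nature of the
objective (scalar vs residual vector), the number of parameters, and the
presence of bounds jointly determine the algorithm —

=============  ==================  ======================
parameters     scalar objective    functional objective
=============  ==================  ======================
constrained    L-BFGS-B            trust-region reflective
unconstrained  conjugate gradient  Levenberg-Marquardt
univariate     Brent (bounded or not); functional: undefined
=============  ==================  ======================

All algorithms are scipy.optimize implementations except the
finite-difference Newton method, a comparison harness selectable only by
explicit name.  Every objective evaluation (including finite-difference
probes) is counted; optional per-iteration histories are written as plain
tab-separated text.  Confidence intervals combine the residuals with the
Jacobian (Gauss-Newton) or the objective Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .objective import (
    Aggregation,
    Comparison,
    GroupObjective,
    ObjectiveSpec,
)

__all__ = [
    "ParameterSet",
    "OptimiserOptions",
    "OptimisationResult",
    "ConfidenceReport",
    "select_method",
    "minimise",
    "numerical_jacobian",
    "confidence_intervals",
    "write_history",
]

TABLE_METHODS = ("brent", "l-bfgs-b", "cg", "trf", "lm")
EXTRA_METHODS = ("newton",)


@dataclass(frozen=True)
class ParameterSet:
    """Named parameters with initial values and optional box bounds.

    ``initial`` may be omitted only for univariate scalar problems (Brent
    brackets its own minimum).  A lower bound of 0 encodes the positivity
    constraint common to material parameters.
    """

    names: tuple[str, ...]
    initial: np.ndarray | None = None
    bounds: tuple[tuple[float | None, float | None], ...] | None = None

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        if self.initial is not None:
            init = np.asarray(self.initial, dtype=float)
            object.__setattr__(self, "initial", init)
            if init.size != len(names):
                raise ValueError("one initial value per parameter required")
        if self.bounds is not None:
            bounds = tuple(
                (None if lo is None else float(lo), None if hi is None else float(hi))
                for lo, hi in self.bounds
            )
            object.__setattr__(self, "bounds", bounds)
            if len(bounds) != len(names):
                raise ValueError("one bounds pair per parameter required")
            for k, (lo, hi) in enumerate(bounds):
                if lo is not None and hi is not None and lo >= hi:
                    raise ValueError(f"empty bound interval for '{names[k]}'")
                if self.initial is not None:
                    x = self.initial[k]
                    if (lo is not None and x < lo) or (hi is not None and x > hi):
                        raise ValueError(
                            f"initial value of '{names[k]}' outside its bounds"
                        )

    @property
    def n(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class OptimiserOptions:
    """Termination and stepping controls shared by all methods.

    f_tol is the absolute objective threshold for *normal termination*
    (e.g. "stop once the normalised RMS falls below 0.1"); None disables
    it so the algorithm's native criteria govern.  x_tol and g_tol are
    passed to the underlying algorithm's parameter-variation and gradient
    criteria; fd_step is the numerical-gradient step.  ``seed`` exists for
    fixture generation only — every optimizer here is deterministic.
    """

    max_iterations: int = 200
    f_tol: float | None = None
    x_tol: float = 1.0e-8
    g_tol: float = 1.0e-8
    fd_step: float = 1.0e-6
    history: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for name in ("x_tol", "g_tol", "fd_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.f_tol is not None and self.f_tol <= 0:
            raise ValueError("f_tol must be positive when given")


@dataclass
class OptimisationResult:
    """Everything a calibration run returns.

    ``objective_value`` is the scalar group objective at ``final_params``
    (for functional objectives, the RMS of the residual vector) and is
    re-checkable by evaluating the group objective there.  ``residuals``
    holds the concatenated per-point residual vector at the optimum, used
    for confidence intervals.  ``history`` records (iteration, params,
    objective) tuples when enabled.
    """

    parameter_names: tuple[str, ...]
    final_params: np.ndarray
    objective_value: float
    n_iterations: int
    n_evaluations: int
    termination: str
    message: str
    method: str
    jacobian: np.ndarray | None = None
    hessian: np.ndarray | None = None
    residuals: np.ndarray | None = None
    history: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "parameter_names": list(self.parameter_names),
            "final_params": arr(self.final_params),
            "objective_value": self.objective_value,
            "n_iterations": self.n_iterations,
            "n_evaluations": self.n_evaluations,
            "termination": self.termination,
            "message": self.message,
            "method": self.method,
            "jacobian": arr(self.jacobian),
            "hessian": arr(self.hessian),
            "residuals": arr(self.residuals),
            "history": [
                {"iteration": int(i), "params": arr(p), "objective": float(v)}
                for i, p, v in self.history
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OptimisationResult":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        return cls(
            parameter_names=tuple(d["parameter_names"]),
            final_params=np.asarray(d["final_params"], dtype=float),
            objective_value=float(d["objective_value"]),
            n_iterations=int(d["n_iterations"]),
            n_evaluations=int(d["n_evaluations"]),
            termination=d["termination"],
            message=d["message"],
            method=d["method"],
            jacobian=arr(d.get("jacobian")),
            hessian=arr(d.get("hessian")),
            residuals=arr(d.get("residuals")),
            history=[
                (int(h["iteration"]), np.asarray(h["params"], dtype=float), float(h["objective"]))
                for h in d.get("history", [])
            ],
        )


@dataclass(frozen=True)
class ConfidenceReport:
    """Parameter covariance and two-sided confidence intervals."""

    covariance: np.ndarray
    intervals: tuple[tuple[float, float], ...]
    residual_variance: float
    level: float

    def to_dict(self) -> dict:
        return {
            "covariance": np.asarray(self.covariance).tolist(),
            "intervals": [list(iv) for iv in self.intervals],
            "residual_variance": self.residual_variance,
            "level": self.level,
        }


def select_method(n_params: int, objective_kind: str, bounded: bool) -> str:
    """Pick the dispatch-table algorithm for a calibration problem.

    A univariate functional objective has no table entry and raises.
    """
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    if objective_kind not in ("scalar", "functional"):
        raise ValueError(f"unknown objective kind '{objective_kind}'")
    if n_params == 1:
        if objective_kind == "functional":
            raise ValueError(
                "univariate functional objective has no dispatch entry; "
                "use a scalar objective or add a parameter"
            )
        return "brent"
    if objective_kind == "scalar":
        return "l-bfgs-b" if bounded else "cg"
    return "trf" if bounded else "lm"


class _NormalTermination(Exception):
    """Raised by the objective wrapper when value <= f_tol (normal stop)."""


class _CountingObjective:
    """Wraps a GroupObjective: counts evaluations, tracks the best point,
    logs every evaluation, and enforces the absolute f_tol threshold."""

    def __init__(self, group: GroupObjective, f_tol: float | None) -> None:
        self.group = group
        self.f_tol = f_tol
        self.n_evaluations = 0
        self.eval_log: list[tuple[np.ndarray, float]] = []
        self.best_x: np.ndarray | None = None
        self.best_f = np.inf

    def _record(self, x: np.ndarray, value: float) -> None:
        self.n_evaluations += 1
        x = np.atleast_1d(np.asarray(x, dtype=float)).copy()
        self.eval_log.append((x, value))
        if value < self.best_f:
            self.best_f, self.best_x = value, x
        if self.f_tol is not None and value <= self.f_tol:
            raise _NormalTermination

    def scalar(self, x) -> float:
        out = self.group(np.atleast_1d(x))
        value = out.value if out.value is not None else float(
            np.sqrt(np.mean(out.residuals**2))
        )
        self._record(x, value)
        return value

    def residuals(self, x) -> np.ndarray:
        out = self.group(np.atleast_1d(x))
        res = out.residuals
        self._record(x, float(np.sqrt(np.mean(res**2))))
        return res

    def quiet_scalar(self, x) -> float:
        """Diagnostic evaluation: not counted, no normal-termination check."""
        out = self.group(np.atleast_1d(x))
        if out.value is not None:
            return out.value
        return float(np.sqrt(np.mean(out.residuals**2)))


def numerical_jacobian(
    objective: Callable[[np.ndarray], float | np.ndarray],
    params: Sequence[float],
    fd_step: float,
    bounds: Sequence[tuple[float | None, float | None]] | None = None,
) -> np.ndarray:
    """Forward-difference Jacobian (vector objective) or gradient (scalar).

    Probes respect bounds by switching to a backward difference at an
    active upper bound.  A non-finite probe marks its column/entry NaN —
    the caller decides how to proceed.
    """
    x0 = np.atleast_1d(np.asarray(params, dtype=float))
    f0 = np.asarray(objective(x0), dtype=float)
    scalar = f0.ndim == 0
    m = 1 if scalar else f0.size
    p = x0.size
    J = np.zeros((m, p))
    for j in range(p):
        h = fd_step
        hi = None if bounds is None else bounds[j][1]
        if hi is not None and x0[j] + h > hi:
            h = -fd_step  # backward difference at an active upper bound
        x = x0.copy()
        x[j] += h
        fj = np.asarray(objective(x), dtype=float)
        col = (fj - f0) / h
        if not np.all(np.isfinite(col)):
            col = np.full(m, np.nan)
        J[:, j] = col
    return J.ravel() if scalar else J


def _numerical_hessian(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    step: float,
    bounds=None,
) -> np.ndarray:
    """Central-difference Hessian of a scalar function.

    With bounds, the stencil centre is shifted inward so no probe leaves
    the feasible box (small bias, diagnostics only).
    """
    p = x0.size
    H = np.zeros((p, p))
    h = np.maximum(step, step * np.abs(x0))
    if bounds is not None:
        x0 = x0.copy()
        for k, (lo, hi) in enumerate(bounds):
            lo = -np.inf if lo is None else lo
            hi = np.inf if hi is None else hi
            # 2h reaches exactly the bound; a touch more absorbs rounding
            x0[k] = np.clip(x0[k], lo + 2.125 * h[k], hi - 2.125 * h[k])
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


_LBFGSB_TERMINATION = (
    ("REL_REDUCTION_OF_F", "objective_tol"),
    ("RELATIVE REDUCTION OF F", "objective_tol"),
    ("PROJECTED GRADIENT", "gradient_tol"),
)

_LSQ_STATUS = {
    0: "max_iterations",
    1: "gradient_tol",
    2: "objective_tol",
    3: "parameter_tol",
    4: "parameter_tol",
}


def _newton_univariate(
    f: Callable[[float], float],
    x0: float,
    bounds: tuple[float | None, float | None] | None,
    options: OptimiserOptions,
):
    """Finite-difference Newton iteration on a univariate scalar objective.

    Comparison harness only: not part of the dispatch table.
    """
    lo = -np.inf if bounds is None or bounds[0] is None else bounds[0]
    hi = np.inf if bounds is None or bounds[1] is None else bounds[1]
    h = options.fd_step
    x = float(np.clip(x0, lo, hi))
    iters = []
    termination, message = "max_iterations", "iteration limit reached"
    for it in range(options.max_iterations):
        fp = (f(x + h) - f(x - h)) / (2.0 * h)
        fpp = (f(x + h) - 2.0 * f(x) + f(x - h)) / h**2
        if fpp > 0 and np.isfinite(fp) and np.isfinite(fpp):
            step = -fp / fpp
        else:
            step = -np.sign(fp) * max(10.0 * h, 1e-3 * max(abs(x), 1.0))
        # damp the step: plain Newton diverges where the objective
        # flattens (f'' -> 0) far from the minimum
        fx = f(x)
        x_new = float(np.clip(x + step, lo, hi))
        for _ in range(40):
            if f(x_new) <= fx or abs(x_new - x) < options.x_tol:
                break
            step *= 0.5
            x_new = float(np.clip(x + step, lo, hi))
        iters.append(x_new)
        if abs(x_new - x) < options.x_tol:
            x = x_new
            termination, message = "parameter_tol", "Newton step below x_tol"
            break
        x = x_new
    return x, len(iters), termination, message, iters


def minimise(
    pairs,
    spec: ObjectiveSpec,
    params: ParameterSet,
    options: OptimiserOptions | None = None,
    method: str | None = None,
) -> OptimisationResult:
    """Run the dispatched (or explicitly named) algorithm on a group objective.

    The initial point is logged as iteration 0; for methods exposing a
    scipy iteration callback, history then holds one row per accepted
    iterate, otherwise one row per objective evaluation.
    """
    options = options or OptimiserOptions()
    group = GroupObjective(pairs, spec)
    kind = "functional" if spec.is_functional else "scalar"
    bounded = params.bounds is not None
    if method is None:
        method = select_method(params.n, kind, bounded)
    if method not in TABLE_METHODS + EXTRA_METHODS:
        raise ValueError(f"unknown method '{method}'")
    if method in ("trf", "lm") and kind == "scalar":
        raise ValueError(f"method '{method}' needs a functional objective")
    if method in ("l-bfgs-b", "cg", "newton", "brent") and kind == "functional":
        raise ValueError(f"method '{method}' needs a scalar objective")
    if params.initial is None and not (method in ("brent",) and params.n == 1):
        raise ValueError("initial values required except for univariate Brent")

    wrapped = _CountingObjective(group, options.f_tol)
    callback_rows: list[np.ndarray] = []

    x0 = None if params.initial is None else np.atleast_1d(params.initial)
    if x0 is not None:
        f0 = wrapped.quiet_scalar(x0)
    termination, message, final_x, n_iter = "failure", "", None, 0

    try:
        if method == "brent":
            if bounded:
                lo, hi = params.bounds[0]
                if lo is None or hi is None:
                    raise ValueError("bounded Brent requires finite bounds")
                res = optimize.minimize_scalar(
                    lambda t: wrapped.scalar([t]),
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": options.x_tol, "maxiter": options.max_iterations},
                )
            else:
                kwargs = {}
                if x0 is not None:
                    kwargs["bracket"] = (float(x0[0]) * 0.5, float(x0[0]) * 1.5)
                res = optimize.minimize_scalar(
                    lambda t: wrapped.scalar([t]),
                    method="brent",
                    options={"xtol": options.x_tol, "maxiter": options.max_iterations},
                    **kwargs,
                )
            final_x = np.atleast_1d(res.x)
            n_iter = int(getattr(res, "nit", res.nfev))
            if res.success:
                termination, message = "parameter_tol", str(res.message)
            else:
                termination, message = "max_iterations", str(res.message)
        elif method == "newton":
            x, n_iter, termination, message, iterates = _newton_univariate(
                lambda t: wrapped.scalar([t]),
                float(x0[0]),
                None if params.bounds is None else params.bounds[0],
                options,
            )
            final_x = np.atleast_1d(x)
            callback_rows.extend(np.atleast_1d(xi) for xi in iterates)
        elif method in ("l-bfgs-b", "cg"):
            scipy_opts = {"maxiter": options.max_iterations, "gtol": options.g_tol}
            if method == "l-bfgs-b":
                scipy_opts["ftol"] = options.x_tol
                scipy_opts["eps"] = options.fd_step
            else:
                scipy_opts["eps"] = options.fd_step
            res = optimize.minimize(
                wrapped.scalar,
                x0,
                method={"l-bfgs-b": "L-BFGS-B", "cg": "CG"}[method],
                bounds=params.bounds if method == "l-bfgs-b" else None,
                callback=lambda xk: callback_rows.append(np.copy(xk)),
                options=scipy_opts,
            )
            final_x = np.atleast_1d(res.x)
            n_iter = int(getattr(res, "nit", 0))
            msg = str(res.message)
            if res.success:
                termination = "gradient_tol"
                for needle, label in _LBFGSB_TERMINATION:
                    if needle in msg.upper():
                        termination = label
                        break
            elif "ITERATION" in msg.upper() or "MAXIMUM" in msg.upper():
                termination = "max_iterations"
            else:
                termination = "failure"
            message = msg
        else:  # trf / lm
            lsq_kwargs = {
                "method": method,
                "xtol": options.x_tol,
                "ftol": options.x_tol,
                "gtol": options.g_tol,
                "diff_step": options.fd_step,
                "max_nfev": options.max_iterations * max(10, 3 * params.n),
            }
            if method == "trf" and bounded:
                lower = [(-np.inf if lo is None else lo) for lo, _ in params.bounds]
                upper = [(np.inf if hi is None else hi) for _, hi in params.bounds]
                lsq_kwargs["bounds"] = (lower, upper)
            elif method == "lm" and bounded:
                raise ValueError("Levenberg-Marquardt does not support bounds")
            res = optimize.least_squares(wrapped.residuals, x0, **lsq_kwargs)
            final_x = np.atleast_1d(res.x)
            n_iter = int(getattr(res, "nfev", wrapped.n_evaluations))
            termination = _LSQ_STATUS.get(int(res.status), "failure")
            message = str(res.message)
    except _NormalTermination:
        final_x = wrapped.best_x
        termination = "objective_tol"
        message = f"objective fell below f_tol = {options.f_tol} (normal termination)"
        n_iter = max(len(callback_rows), 1)
    except Exception as exc:  # objective raised: abort with captured message
        if wrapped.best_x is None:
            raise
        final_x = wrapped.best_x
        termination, message = "failure", f"{type(exc).__name__}: {exc}"
        n_iter = max(len(callback_rows), 1)

    final_x = np.atleast_1d(np.asarray(final_x, dtype=float))

    def safe_quiet(x: np.ndarray) -> float:
        try:
            return wrapped.quiet_scalar(x)
        except Exception:
            return float("nan")

    final_value = safe_quiet(final_x)
    if not np.isfinite(final_value):
        final_value = wrapped.best_f

    # diagnostics at the optimum: concatenated residual vector + Jacobian/Hessian
    diag_spec = ObjectiveSpec(
        comparison=Comparison.DIRECT,
        error_form=spec.error_form,
        aggregation=Aggregation.CONCATENATED_RESIDUALS,
        normalisation_reference=spec.normalisation_reference,
    )
    diag_group = GroupObjective(pairs, diag_spec)

    def diag_residuals(x):
        out = diag_group(x)
        return out.residuals if out.residuals is not None else np.full(1, np.nan)

    jacobian = None
    hessian = None
    try:
        residuals = diag_residuals(final_x)
        if not np.all(np.isfinite(residuals)):
            residuals = None
    except Exception:
        residuals = None
    if residuals is not None:
        try:
            jacobian = np.atleast_2d(
                numerical_jacobian(diag_residuals, final_x, options.fd_step, params.bounds)
            )
            if not np.all(np.isfinite(jacobian)):
                jacobian = None
        except Exception:
            jacobian = None
    try:
        hessian = _numerical_hessian(
            safe_quiet, final_x, max(options.fd_step, 1e-5), params.bounds
        )
        if not np.all(np.isfinite(hessian)):
            hessian = None
    except Exception:
        hessian = None

    history: list[tuple[int, np.ndarray, float]] = []
    if options.history:
        if x0 is not None:
            history.append((0, x0.copy(), f0))
        elif wrapped.eval_log:
            x_first, f_first = wrapped.eval_log[0]
            history.append((0, x_first, f_first))
        if callback_rows:
            for k, xk in enumerate(callback_rows, start=1):
                history.append((k, np.atleast_1d(xk), safe_quiet(xk)))
        else:
            # no iteration callback: log one row per objective evaluation
            rows = wrapped.eval_log[1:] if x0 is None else wrapped.eval_log
            for k, (xk, fk) in enumerate(rows, start=1):
                history.append((k, xk, fk))

    return OptimisationResult(
        parameter_names=params.names,
        final_params=final_x,
        objective_value=final_value,
        n_iterations=int(n_iter),
        n_evaluations=int(wrapped.n_evaluations),
        termination=termination,
        message=message,
        method=method,
        jacobian=jacobian,
        hessian=hessian,
        residuals=residuals,
        history=history,
    )


def confidence_intervals(
    result: OptimisationResult, n_observations: int, level: float = 0.95
) -> ConfidenceReport:
    """Covariance and Student-t confidence intervals at the optimum.

    Residual variance s^2 = SSR / (n - p); covariance is s^2 (J^T J)^-1
    when a residual Jacobian is available, else 2 s^2 H^-1 from the scalar
    objective Hessian.  A rank-deficient J^T J raises, reporting the
    unidentifiable parameter combination (null-space direction).
    """
    p = result.final_params.size
    n = int(n_observations)
    if n <= p:
        raise ValueError("need more observations than parameters")
    if result.residuals is None and result.hessian is None:
        raise ValueError("result carries neither residuals nor Hessian")
    if not (0 < level < 1):
        raise ValueError("confidence level must lie in (0, 1)")

    ssr = float(np.sum(result.residuals**2)) if result.residuals is not None else (
        result.objective_value**2 * n
    )
    s2 = ssr / (n - p)

    if result.jacobian is not None:
        J = np.atleast_2d(result.jacobian)
        jtj = J.T @ J
        u_svd, s_svd, vt = np.linalg.svd(jtj)
        if s_svd[-1] <= max(s_svd[0], 1.0) * 1e-12:
            direction = ", ".join(
                f"{c:+.3f}*{name}"
                for c, name in zip(vt[-1], result.parameter_names)
            )
            raise ValueError(
                f"J^T J is singular; unidentifiable combination: {direction}"
            )
        cov = s2 * np.linalg.inv(jtj)
    else:
        H = np.atleast_2d(result.hessian)
        try:
            cov = 2.0 * s2 * np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"objective Hessian is singular: {exc}") from exc

    tq = float(stats.t.ppf(0.5 * (1.0 + level), n - p))
    half = tq * np.sqrt(np.clip(np.diag(cov), 0.0, None))
    intervals = tuple(
        (float(est - h), float(est + h))
        for est, h in zip(result.final_params, half)
    )
    return ConfidenceReport(
        covariance=cov, intervals=intervals, residual_variance=s2, level=level
    )


def write_history(result: OptimisationResult, path) -> None:
    """Write the iteration history as tab-separated text (overwrite, never
    append): header row, then iteration index, parameter values, objective."""
    if not result.history:
        raise ValueError("result has no history (was history enabled?)")
    header = "iter\t" + "\t".join(result.parameter_names) + "\tobjective"
    lines = [header]
    for it, x, f in result.history:
        vals = "\t".join(format(v, ".12g") for v in np.atleast_1d(x))
        lines.append(f"{it}\t{vals}\t{format(f, '.12g')}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
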