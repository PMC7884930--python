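"""Objective construction: model-vs-experiment residuals and group aggregation.

A calibration compares each specimen's forward-model output with its paired
experimental observation.  Scalars compare directly; lists elementwise;
curves are first resampled onto a common grid (the denser grid within the
x-overlap).  Residuals may be plain differences or relative errors, and a
group of specimens is reduced either to one RMS scalar (for scalar-objective
optimizers) or to one concatenated residual vector (for least-squares
optimizers).  A specimen whose solver failed is excluded from aggregation —
failure is data here, never an exception — so calibration proceeds whenever
at least one specimen converged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .forward_models import Curve, ForwardModel, ForwardOutput, OutputKind

__all__ = [
    "Comparison",
    "ErrorForm",
    "Aggregation",
    "NormalisationReference",
    "Observation",
    "ObjectiveSpec",
    "ObjectiveValue",
    "GroupObjective",
    "interpolate_to_common_grid",
    "compare",
    "evaluate_group",
]

# penalty returned when every specimen in the group fails to solve
_PENALTY_SCALE = 1.0e6


class Comparison(str, enum.Enum):
    DIRECT = "direct"
    LEAST_SQUARES = "least_squares"


class ErrorForm(str, enum.Enum):
    DIFFERENCE = "difference"
    RELATIVE = "relative"


class Aggregation(str, enum.Enum):
    RMS_OVER_MODELS = "rms_over_models"
    CONCATENATED_RESIDUALS = "concatenated_residuals"


class NormalisationReference(str, enum.Enum):
    EXPERIMENTAL_VALUE = "experimental_value"
    MAX_EXPERIMENTAL = "max_experimental"


@dataclass(frozen=True)
class Observation:
    """Experimental observation paired with a model by shared basename."""

    name: str
    payload: float | np.ndarray | Curve

    @property
    def kind(self) -> OutputKind:
        if isinstance(self.payload, Curve):
            return OutputKind.CURVE
        if np.ndim(self.payload) == 0:
            return OutputKind.SCALAR
        return OutputKind.LIST


@dataclass(frozen=True)
class ObjectiveSpec:
    """How residuals are formed and aggregated across the specimen group.

    ``least_squares`` comparison pairs with the scalar ``rms_over_models``
    aggregation (scalar-objective optimizers); ``direct`` comparison pairs
    with ``concatenated_residuals`` (vector-residual optimizers).
    """

    comparison: Comparison = Comparison.LEAST_SQUARES
    error_form: ErrorForm = ErrorForm.RELATIVE
    aggregation: Aggregation = Aggregation.RMS_OVER_MODELS
    normalisation_reference: NormalisationReference = (
        NormalisationReference.EXPERIMENTAL_VALUE
    )

    def __post_init__(self) -> None:
        scalar = self.aggregation is Aggregation.RMS_OVER_MODELS
        if scalar and self.comparison is not Comparison.LEAST_SQUARES:
            raise ValueError("rms_over_models requires least_squares comparison")
        if not scalar and self.comparison is not Comparison.DIRECT:
            raise ValueError("concatenated_residuals requires direct comparison")

    @property
    def is_functional(self) -> bool:
        """True when the objective is a residual vector, not a scalar."""
        return self.aggregation is Aggregation.CONCATENATED_RESIDUALS


@dataclass(frozen=True)
class ObjectiveValue:
    """One group-objective evaluation: scalar or residual vector plus counts."""

    value: float | None
    residuals: np.ndarray | None
    n_contributing: int
    n_failed: int

    @property
    def payload(self):
        return self.value if self.residuals is None else self.residuals


def interpolate_to_common_grid(
    model: Curve, experiment: Curve
) -> tuple[np.ndarray, np.ndarray]:
    """Resample both curves onto a common grid so y-values compare as lists.

    The target grid is the x-grid of whichever curve has more samples inside
    the x-overlap of the two curves (ties go to the experimental grid),
    restricted to that overlap; the other curve is linearly interpolated
    onto it.  No extrapolation ever occurs.
    """
    lo = max(model.x[0], experiment.x[0])
    hi = min(model.x[-1], experiment.x[-1])
    if lo >= hi:
        raise ValueError(
            f"curves have no x-overlap (model [{model.x[0]}, {model.x[-1]}], "
            f"experiment [{experiment.x[0]}, {experiment.x[-1]}])"
        )
    in_m = (model.x >= lo) & (model.x <= hi)
    in_e = (experiment.x >= lo) & (experiment.x <= hi)
    model_denser = int(in_m.sum()) > int(in_e.sum())
    target = model if model_denser else experiment
    other = experiment if model_denser else model
    grid = target.x[(target.x >= lo) & (target.x <= hi)]
    if grid.size < 2:
        raise ValueError("fewer than 2 samples in the curve overlap")
    y_target = target.y[(target.x >= lo) & (target.x <= hi)]
    y_other = np.interp(grid, other.x, other.y)
    if model_denser:
        return y_target, y_other
    return y_other, y_target


def _payload_arrays(
    model_out: ForwardOutput, observation: Observation
) -> tuple[np.ndarray, np.ndarray]:
    if model_out.kind is not observation.kind:
        raise ValueError(
            f"specimen '{observation.name}': model output kind "
            f"{model_out.kind.value} does not match observation kind "
            f"{observation.kind.value}"
        )
    if model_out.kind is OutputKind.SCALAR:
        return np.atleast_1d(float(model_out.value)), np.atleast_1d(
            float(observation.payload)
        )
    if model_out.kind is OutputKind.LIST:
        y_m = np.asarray(model_out.value, dtype=float)
        y_e = np.asarray(observation.payload, dtype=float)
        if y_m.size != y_e.size:
            raise ValueError(
                f"specimen '{observation.name}': list lengths differ "
                f"({y_m.size} vs {y_e.size})"
            )
        return y_m, y_e
    return interpolate_to_common_grid(model_out.value, observation.payload)


def compare(
    model_out: ForwardOutput, observation: Observation, spec: ObjectiveSpec
) -> np.ndarray:
    """Residual vector for one specimen (model minus experiment).

    In relative form each residual is divided by the normalisation
    reference: the per-point experimental value, or the specimen's maximum
    absolute experimental value.  A zero reference is an error naming the
    offending point.
    """
    if model_out.failed:
        raise ValueError(f"specimen '{observation.name}': model output is failed")
    y_model, y_exp = _payload_arrays(model_out, observation)
    res = y_model - y_exp
    if spec.error_form is ErrorForm.DIFFERENCE:
        return res
    if spec.normalisation_reference is NormalisationReference.MAX_EXPERIMENTAL:
        ref = np.full_like(y_exp, np.max(np.abs(y_exp)))
    else:
        ref = y_exp
    zero = np.flatnonzero(ref == 0)
    if zero.size:
        raise ValueError(
            f"specimen '{observation.name}': zero normalisation reference at "
            f"point index {int(zero[0])}"
        )
    return res / ref


class GroupObjective:
    """Callable group objective over (ForwardModel, Observation) pairs.

    Pairs are evaluated in filename-sorted order so concatenated residual
    vectors are deterministic regardless of input order.  When every model
    fails, a large finite penalty is returned (1e6 times the last successful
    objective value, or 1e6 on a first evaluation) so gradient-based
    optimizers retreat instead of crashing.
    """

    def __init__(
        self,
        pairs: Sequence[tuple[ForwardModel, Observation]],
        spec: ObjectiveSpec,
    ) -> None:
        if not pairs:
            raise ValueError("at least one model/observation pair required")
        for model, obs in pairs:
            if model.kind is not obs.kind:
                raise ValueError(
                    f"specimen '{model.name}': model kind {model.kind.value} "
                    f"does not match observation kind {obs.kind.value}"
                )
        self.pairs = sorted(pairs, key=lambda p: p[0].name)
        self.spec = spec
        self._last_scalar: float | None = None
        self._last_len: int = 1

    def _penalty(self) -> ObjectiveValue:
        base = _PENALTY_SCALE * (self._last_scalar if self._last_scalar else 1.0)
        n = len(self.pairs)
        if self.spec.is_functional:
            return ObjectiveValue(None, np.full(self._last_len, base), 0, n)
        return ObjectiveValue(base, None, 0, n)

    def __call__(self, params: Sequence[float]) -> ObjectiveValue:
        p = np.asarray(params, dtype=float)
        per_model: list[np.ndarray] = []
        n_failed = 0
        for model, obs in self.pairs:
            out = model(p)
            if out.failed:
                n_failed += 1
                continue
            per_model.append(compare(out, obs, self.spec))
        if not per_model:
            return self._penalty()
        n_contributing = len(per_model)
        if self.spec.is_functional:
            residuals = np.concatenate(per_model)
            self._last_len = residuals.size
            self._last_scalar = float(np.sqrt(np.mean(residuals**2)))
            return ObjectiveValue(None, residuals, n_contributing, n_failed)
        value = float(np.sqrt(np.mean([np.mean(r**2) for r in per_model])))
        self._last_scalar = value
        return ObjectiveValue(value, None, n_contributing, n_failed)


def evaluate_group(
    params: Sequence[float],
    pairs: Sequence[tuple[ForwardModel, Observation]],
    spec: ObjectiveSpec,
) -> ObjectiveValue:
    """One-shot group-objective evaluation (fresh penalty state)."""
    return GroupObjective(pairs, spec)(params)
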