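"""Forward models mapping material parameters to measurable specimen responses.

Three desk-scale structural models cover the response types met in inverse
FE calibration of spinal tissue:

* a chain of uniaxial bone elements whose moduli follow a linear
  greyscale-to-elasticity mapping, observed through a single apparent
  stiffness (scalar);
* a fibre-reinforced (Gasser-Ogden-Holzapfel) soft-tissue specimen in
  uniaxial compression/tension, observed through its nonlinear
  force-displacement curve;
* a stack of annulus lamellae coupled by interface springs, observed through
  the radial displacements of a list of tracked points.

Each model honours the same contract: a parameter vector goes in, a
:class:`ForwardOutput` comes out.  Solver breakdowns (singular systems,
overflow) are reported through the output's ``failed`` flag rather than an
exception, so a group calibration can continue as long as at least one
specimen's model converges.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OutputKind",
    "Curve",
    "ForwardOutput",
    "ForwardModel",
    "GreyscaleLattice",
    "GreyscaleMapping",
    "GOHParams",
    "GOHFixedParams",
    "InterfaceLattice",
    "InterfaceStiffness",
    "greyscale_apparent_stiffness",
    "goh_strain_energy",
    "goh_force_displacement",
    "interface_displacements",
    "make_greyscale_model",
    "make_goh_model",
    "make_interface_model",
]

# exp() argument beyond this is treated as solver overflow, not an exception
_EXP_OVERFLOW = 500.0


class OutputKind(str, enum.Enum):
    SCALAR = "scalar"
    LIST = "list"
    CURVE = "curve"


@dataclass(frozen=True)
class Curve:
    """Paired (x, y) samples with strictly increasing abscissa.

    Used for force-displacement records: ``x`` is typically displacement in
    mm and ``y`` load in N, but any strictly increasing abscissa is valid.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("curve x and y must be 1-D arrays of equal length")
        if x.size < 2:
            raise ValueError("curve needs at least 2 samples")
        if not np.all(np.diff(x) > 0):
            raise ValueError("curve x must be strictly increasing")

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class ForwardOutput:
    """Result of one forward-model run: a scalar, a list, or a curve.

    ``failed`` is the solver-failure sentinel: when set, the payload is
    ``None`` and consumers must skip this model rather than raise.
    """

    kind: OutputKind
    value: float | np.ndarray | Curve | None
    failed: bool = False

    @classmethod
    def scalar(cls, value: float) -> "ForwardOutput":
        return cls(OutputKind.SCALAR, float(value))

    @classmethod
    def from_list(cls, values: Sequence[float]) -> "ForwardOutput":
        return cls(OutputKind.LIST, np.asarray(values, dtype=float))

    @classmethod
    def from_curve(cls, curve: Curve) -> "ForwardOutput":
        return cls(OutputKind.CURVE, curve)

    @classmethod
    def failure(cls, kind: OutputKind) -> "ForwardOutput":
        return cls(kind, None, failed=True)


@dataclass(frozen=True)
class ForwardModel:
    """Named specimen model: callable mapping a parameter vector to output.

    ``name`` pairs the model with its experimental observation (same
    basename); ``kind`` declares the output type so observation payloads can
    be validated before any optimisation starts.
    """

    name: str
    kind: OutputKind
    fn: Callable[[np.ndarray], ForwardOutput]

    def __call__(self, params: Sequence[float]) -> ForwardOutput:
        return self.fn(np.asarray(params, dtype=float))


# ---------------------------------------------------------------------------
# Case 1: greyscale-mapped bone elasticity, apparent stiffness output
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GreyscaleLattice:
    """Chain of uniaxial elements with per-element normalised greyscale.

    greyscales: normalised CT greyscale per element, each in (0, 1].
    lengths/areas: element geometry in mm and mm^2.
    displacement: prescribed axial end displacement in mm.
    """

    greyscales: np.ndarray
    lengths: np.ndarray
    areas: np.ndarray
    displacement: float

    def __post_init__(self) -> None:
        gs = np.asarray(self.greyscales, dtype=float)
        ln = np.asarray(self.lengths, dtype=float)
        ar = np.asarray(self.areas, dtype=float)
        for name, arr in (("greyscales", gs), ("lengths", ln), ("areas", ar)):
            object.__setattr__(self, name, arr)
            if arr.ndim != 1 or arr.size != gs.size:
                raise ValueError("lattice arrays must be 1-D and equal length")
        if gs.size < 1:
            raise ValueError("lattice needs at least one element")
        if np.any(gs <= 0) or np.any(gs > 1):
            raise ValueError("greyscales must lie in (0, 1]")
        if np.any(ln <= 0) or np.any(ar <= 0):
            raise ValueError("element geometry must be strictly positive")
        if self.displacement == 0:
            raise ValueError("prescribed displacement must be nonzero")


@dataclass(frozen=True)
class GreyscaleMapping:
    """Linear greyscale-to-modulus mapping: E_i = slope * GS_i (MPa)."""

    slope: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("mapping slope must be positive")


def greyscale_apparent_stiffness(
    lattice: GreyscaleLattice, mapping: GreyscaleMapping
) -> ForwardOutput:
    """Apparent stiffness (N/mm) of the element chain under end displacement.

    Assembles the 1-D linear-elastic system, applies the prescribed end
    displacement, and returns reaction force / displacement.  Exactly linear
    in ``mapping.slope``.  Singular or non-finite systems yield a failed
    output, never an exception.
    """
    with np.errstate(over="ignore"):
        moduli = mapping.slope * lattice.greyscales
        k_el = moduli * lattice.areas / lattice.lengths  # N/mm per element
    if not np.all(np.isfinite(k_el)) or np.any(k_el <= 0):
        return ForwardOutput.failure(OutputKind.SCALAR)

    n_el = k_el.size
    n_nodes = n_el + 1
    K = np.zeros((n_nodes, n_nodes))
    for e, k in enumerate(k_el):
        K[e : e + 2, e : e + 2] += k * np.array([[1.0, -1.0], [-1.0, 1.0]])

    # node 0 fixed, last node prescribed; interior nodes free
    u = np.zeros(n_nodes)
    u[-1] = lattice.displacement
    free = np.arange(1, n_el)
    try:
        if free.size:
            rhs = -K[np.ix_(free, [0, n_el])] @ u[[0, n_el]]
            u[free] = np.linalg.solve(K[np.ix_(free, free)], rhs)
    except np.linalg.LinAlgError:
        return ForwardOutput.failure(OutputKind.SCALAR)
    reaction = K[-1] @ u
    stiffness = reaction / lattice.displacement
    if not np.isfinite(stiffness) or stiffness <= 0:
        return ForwardOutput.failure(OutputKind.SCALAR)
    return ForwardOutput.scalar(stiffness)


# ---------------------------------------------------------------------------
# Case 2: GOH fibre-reinforced specimen, force-displacement curve output
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GOHParams:
    """Calibrated fibre parameters: k1 (MPa) stiffness-like, k2 exponential."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("GOH fibre parameters k1, k2 must be positive")


@dataclass(frozen=True)
class GOHFixedParams:
    """Assumed-known components of the GOH model plus specimen geometry.

    c10: ground-matrix shear coefficient (MPa); kappa: fibre dispersion in
    [0, 1/3] (0 = perfectly aligned, 1/3 = isotropic); theta_deg: fibre
    angle to the loading axis; d_comp: compressibility coefficient, retained
    for API completeness but unused under the incompressible kinematics.
    """

    c10: float = 0.1
    kappa: float = 0.1
    theta_deg: float = 30.0
    d_comp: float = 0.0
    specimen_area: float = 600.0
    specimen_height: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0 / 3.0):
            raise ValueError("fibre dispersion kappa must lie in [0, 1/3]")
        if self.specimen_area <= 0 or self.specimen_height <= 0:
            raise ValueError("specimen geometry must be positive")


def _goh_invariants(stretch: np.ndarray, fixed: GOHFixedParams):
    """Isochoric invariants under incompressible uniaxial deformation.

    lambda_z = stretch, lambda_r = stretch**-1/2 (J = 1).  Both fibre
    families sit at +/- theta to the axis and see the same invariant.
    """
    lam = np.asarray(stretch, dtype=float)
    c2 = np.cos(np.radians(fixed.theta_deg)) ** 2
    s2 = 1.0 - c2
    i1 = lam**2 + 2.0 / lam
    i4 = lam**2 * c2 + s2 / lam
    di1 = 2.0 * lam - 2.0 / lam**2
    di4 = 2.0 * lam * c2 - s2 / lam**2
    return i1, i4, di1, di4


def goh_strain_energy(
    params: GOHParams, fixed: GOHFixedParams, stretch: float
) -> float:
    """GOH strain-energy density (MPa) at an axial stretch.

    Psi = c10 (I1b - 3) + k1/(2 k2) sum_alpha [exp(k2 <Eb_alpha>^2) - 1]
    with Eb_alpha = kappa (I1b - 3) + (1 - 3 kappa) (I4b_alpha - 1) and
    <.> the Macaulay bracket (fibres bear load in tension only).
    """
    i1, i4, _, _ = _goh_invariants(np.asarray(stretch), fixed)
    e = fixed.kappa * (i1 - 3.0) + (1.0 - 3.0 * fixed.kappa) * (i4 - 1.0)
    e_plus = np.maximum(e, 0.0)
    # expm1 keeps the k2 -> 0 limit (k1/2 * E^2 per family) numerically exact
    fibre = 2.0 * params.k1 / (2.0 * params.k2) * np.expm1(params.k2 * e_plus**2)
    return float(fixed.c10 * (i1 - 3.0) + fibre)


def goh_force_displacement(
    params: GOHParams,
    fixed: GOHFixedParams,
    displacements: Sequence[float],
) -> ForwardOutput:
    """Axial force-displacement curve of the GOH specimen.

    Homogeneous incompressible uniaxial kinematics: stretch = 1 + u/h.
    Force = Cauchy stress x current area = A0 * dPsi/dlambda; the curve
    passes through (0, 0) and is pointwise non-decreasing in k1.

    Non-physical parameters raise before evaluation; exp overflow at
    extreme k2 yields a failed output.
    """
    u = np.asarray(displacements, dtype=float)
    if u.size < 2 or u[0] != 0 or np.any(np.diff(u) <= 0) or np.any(u < 0):
        raise ValueError("displacements must increase strictly from 0")
    # parameter validation happens in GOHParams; re-run for raw tuples
    if not (params.k1 > 0 and params.k2 > 0):
        raise ValueError("GOH fibre parameters must be positive")

    lam = 1.0 + u / fixed.specimen_height
    i1, i4, di1, di4 = _goh_invariants(lam, fixed)
    kap = fixed.kappa
    e = kap * (i1 - 3.0) + (1.0 - 3.0 * kap) * (i4 - 1.0)
    e_plus = np.maximum(e, 0.0)
    de = kap * di1 + (1.0 - 3.0 * kap) * di4

    arg = params.k2 * e_plus**2
    if np.any(arg > _EXP_OVERFLOW):
        return ForwardOutput.failure(OutputKind.CURVE)
    # dPsi/dlambda; factor 2 for the two symmetric fibre families
    dpsi = fixed.c10 * di1 + 2.0 * params.k1 * np.exp(arg) * e_plus * de
    force = fixed.specimen_area * dpsi
    if not np.all(np.isfinite(force)):
        return ForwardOutput.failure(OutputKind.CURVE)
    return ForwardOutput.from_curve(Curve(u, force))


# ---------------------------------------------------------------------------
# Case 3: lamellar stack with interface springs, radial displacement output
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterfaceStiffness:
    """Interface stiffness pair: radial k_r and tangential k_t (N/mm)."""

    k_r: float
    k_t: float

    def __post_init__(self) -> None:
        if not (self.k_r > 0 and self.k_t > 0):
            raise ValueError("interface stiffnesses must be positive")


@dataclass(frozen=True)
class InterfaceLattice:
    """Stack of lamellae (node chains) joined by interface connectors.

    Nodes sit on a regular grid: lamella ``i`` at radius ``i * radial_gap``,
    node ``j`` at tangential position ``j * tangential_spacing``.  Each node
    carries radial and tangential displacement DOFs.  Within a lamella,
    springs of per-lamella stiffness resist relative motion of neighbouring
    nodes in both components (in-plane elasticity).  Between lamellae, k_r
    acts on the radial relative displacement of facing nodes, while k_t is
    mobilised through oblique connectors (node (i, j) to (i+1, j+1)), whose
    axis couples tangential stiffness into the radial response — without
    this coupling, radial observations carry no information on k_t.

    Lamella 0 is fully fixed; ``applied_forces`` are radial loads (N), one
    per node of the outermost lamella.  ``tracked_points`` are (lamella,
    node) pairs whose radial displacement is observed.
    """

    n_lamellae: int
    nodes_per_lamella: int
    lamella_stiffness: np.ndarray  # N/mm, one per lamella
    tracked_points: tuple
    applied_forces: np.ndarray  # N, one per outer-lamella node, radial
    radial_gap: float = 0.5  # mm
    tangential_spacing: float = 0.5  # mm

    def __post_init__(self) -> None:
        ks = np.asarray(self.lamella_stiffness, dtype=float)
        fs = np.asarray(self.applied_forces, dtype=float)
        object.__setattr__(self, "lamella_stiffness", ks)
        object.__setattr__(self, "applied_forces", fs)
        object.__setattr__(
            self, "tracked_points", tuple((int(i), int(j)) for i, j in self.tracked_points)
        )
        if self.n_lamellae < 2:
            raise ValueError("need at least 2 lamellae")
        if self.nodes_per_lamella < 1:
            raise ValueError("need at least 1 node per lamella")
        if ks.size != self.n_lamellae or np.any(ks <= 0):
            raise ValueError("one positive stiffness per lamella required")
        if fs.size != self.nodes_per_lamella:
            raise ValueError("one radial force per outer-lamella node required")
        if not self.tracked_points:
            raise ValueError("at least one tracked point required")
        for i, j in self.tracked_points:
            if not (0 <= i < self.n_lamellae and 0 <= j < self.nodes_per_lamella):
                raise ValueError(f"tracked point ({i}, {j}) outside lattice")
        if self.radial_gap <= 0 or self.tangential_spacing <= 0:
            raise ValueError("grid spacings must be positive")


def _interface_elements(lattice: InterfaceLattice, stiffness: InterfaceStiffness):
    """Element list: (node_a, node_b, stiffness, unit direction (r, t)).

    Per-component springs are encoded as axis-aligned directions; the
    oblique k_t connector carries its true geometric direction.
    """
    nl, m = lattice.n_lamellae, lattice.nodes_per_lamella
    dr, dt = lattice.radial_gap, lattice.tangential_spacing
    diag = np.array([dr, dt]) / np.hypot(dr, dt)
    elements = []
    for i in range(nl):
        k_lam = float(lattice.lamella_stiffness[i])
        for j in range(m - 1):
            a, b = i * m + j, i * m + j + 1
            elements.append((a, b, k_lam, (1.0, 0.0)))
            elements.append((a, b, k_lam, (0.0, 1.0)))
    for i in range(nl - 1):
        for j in range(m):
            a, b = i * m + j, (i + 1) * m + j
            elements.append((a, b, float(stiffness.k_r), (1.0, 0.0)))
            if j + 1 < m:
                b_diag = (i + 1) * m + j + 1
                elements.append((a, b_diag, float(stiffness.k_t), tuple(diag)))
            elif m == 1:
                # single-column stack: k_t acts as a plain tangential spring
                elements.append((a, b, float(stiffness.k_t), (0.0, 1.0)))
    return elements


def interface_displacements(
    lattice: InterfaceLattice, stiffness: InterfaceStiffness
) -> ForwardOutput:
    """Radial displacements (mm) at the tracked points, in stored order.

    Assembles the 2-DOF-per-node spring system, fixes lamella 0, applies the
    radial loads on the outer lamella, and solves.  Singular or non-finite
    systems yield a failed output.
    """
    nl, m = lattice.n_lamellae, lattice.nodes_per_lamella
    ndof = 2 * nl * m
    K = np.zeros((ndof, ndof))
    with np.errstate(over="ignore", invalid="ignore"):
        for a, b, k, (nr, nt) in _interface_elements(lattice, stiffness):
            n_vec = np.array([nr, nt])
            k_loc = k * np.outer(n_vec, n_vec)
            dofs = [2 * a, 2 * a + 1, 2 * b, 2 * b + 1]
            block = np.block([[k_loc, -k_loc], [-k_loc, k_loc]])
            K[np.ix_(dofs, dofs)] += block

    f = np.zeros(ndof)
    for j in range(m):
        f[2 * ((nl - 1) * m + j)] = lattice.applied_forces[j]

    fixed = np.arange(2 * m)  # lamella 0, both DOFs
    free = np.setdiff1d(np.arange(ndof), fixed)
    if not np.all(np.isfinite(K)):
        return ForwardOutput.failure(OutputKind.LIST)
    u = np.zeros(ndof)
    try:
        u[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
    except np.linalg.LinAlgError:
        return ForwardOutput.failure(OutputKind.LIST)
    if not np.all(np.isfinite(u)):
        return ForwardOutput.failure(OutputKind.LIST)
    radial = [u[2 * (i * m + j)] for i, j in lattice.tracked_points]
    return ForwardOutput.from_list(radial)


# ---------------------------------------------------------------------------
# ForwardModel factories (parameter-vector entry points used by calibration)
# ---------------------------------------------------------------------------


def make_greyscale_model(name: str, lattice: GreyscaleLattice) -> ForwardModel:
    """Model with parameter vector [slope]."""

    def fn(p: np.ndarray) -> ForwardOutput:
        if p[0] <= 0 or not np.isfinite(p[0]):
            return ForwardOutput.failure(OutputKind.SCALAR)
        return greyscale_apparent_stiffness(lattice, GreyscaleMapping(float(p[0])))

    return ForwardModel(name, OutputKind.SCALAR, fn)


def make_goh_model(
    name: str, fixed: GOHFixedParams, displacements: Sequence[float]
) -> ForwardModel:
    """Model with parameter vector [k1, k2]."""
    disp = np.asarray(displacements, dtype=float)

    def fn(p: np.ndarray) -> ForwardOutput:
        if np.any(p <= 0) or not np.all(np.isfinite(p)):
            return ForwardOutput.failure(OutputKind.CURVE)
        return goh_force_displacement(GOHParams(float(p[0]), float(p[1])), fixed, disp)

    return ForwardModel(name, OutputKind.CURVE, fn)


def make_interface_model(name: str, lattice: InterfaceLattice) -> ForwardModel:
    """Model with parameter vector [k_r, k_t]."""

    def fn(p: np.ndarray) -> ForwardOutput:
        if np.any(p <= 0) or not np.all(np.isfinite(p)):
            return ForwardOutput.failure(OutputKind.LIST)
        return interface_displacements(
            lattice, InterfaceStiffness(float(p[0]), float(p[1]))
        )

    return ForwardModel(name, OutputKind.LIST, fn)
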