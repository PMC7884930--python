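# Methods

This note documents the models, numerical choices, and known limitations of
`femfit`, in the spirit of a model-documentation page: what is computed, under
which assumptions, and what the synthetic test conditions do and do not show.

## Problem statement

Given N specimen pairs — a forward model ŷᵢ(θ) and an observation yᵢ of the
same kind (scalar, list, or curve) — find the parameter vector θ minimising
the group mismatch. All parameters handled here are material parameters and
physically positive, so calibrations are normally run with bounds whose lower
edge encodes positivity.

## Residuals and aggregation

- **Curve comparison.** Curves are compared on a common grid: the x-grid with
  more samples inside the x-overlap of the two curves wins (ties go to the
  experimental grid), restricted to the overlap; the other curve is linearly
  interpolated onto it. No extrapolation is ever performed — extrapolated
  loads are meaningless for calibration. Shared grids short-circuit to an
  exact (bit-identical) pass-through. Fewer than two overlap samples is an
  error naming the specimen.
- **Error forms.** `difference` (model − experiment) or `relative`, dividing
  by either the per-point experimental value or the specimen's maximum
  absolute experimental value. Per-point normalisation is appropriate for
  scalar stiffness data with large inter-specimen spread (it makes specimens
  commensurate); max-normalisation is the right choice for force–displacement
  curves that pass through zero (a per-point reference of 0 is an error by
  design, not silently skipped).
- **Aggregation.** `rms_over_models` = √(meanᵢ meanⱼ rᵢⱼ²) for scalar-objective
  optimizers; `concatenated_residuals` (filename-sorted, deterministic) for
  least-squares optimizers. Per-model weighting is uniform. The two modes are
  validated against the comparison enum (`least_squares` ↔ scalar RMS,
  `direct` ↔ vector residuals) because each optimizer family consumes exactly
  one of them.
- **Solver failure is data.** A forward model returns a `failed` output (never
  raises) on singular or overflowed systems. Failed specimens are excluded
  from the aggregation and counted; if *every* specimen fails, the objective
  returns a large finite penalty (10⁶ × the last successful objective value,
  or 10⁶ on a first evaluation) so line searches retreat. For functional
  objectives a mid-run failure changes the residual length, which
  least-squares drivers cannot tolerate; such runs end with
  `termination="failure"` rather than a wrong answer.

## Optimiser dispatch and termination

Dispatch by (number of parameters, objective kind, boundedness):
Brent (univariate scalar, bounded or not), L-BFGS-B (multivariate scalar,
bounded), conjugate gradient (multivariate scalar, unbounded), trust-region
reflective (multivariate functional, bounded), Levenberg–Marquardt
(multivariate functional, unbounded). A univariate functional objective has
no table entry and errors. All are the scipy.optimize implementations; the
finite-difference Newton method (explicit name `"newton"`, never dispatched)
is a comparison harness with step damping — undamped Newton diverges where
the objective flattens far from the minimum.

Termination controls: `f_tol` is an *absolute* objective threshold ("normal
termination", e.g. stop once normalised RMS < 0.1). scipy has no such
criterion, so the objective wrapper raises an internal signal when the value
crosses it; the best-so-far point is returned with
`termination="objective_tol"`. Default is `None` (disabled) so the
algorithm's native relative criteria (`x_tol`, `g_tol`, both default 1e-8,
`fd_step` 1e-6 for numerical gradients) govern; case-study-style thresholds
are plain config values. Every objective evaluation made during optimisation,
including finite-difference probes, is counted in `n_evaluations`;
post-termination diagnostics (final residual vector, Jacobian, Hessian) use a
separate non-counting evaluator. Iteration counts are the underlying
algorithm's native notion and are diagnostics, not a contract.

History convention: the initial point is logged as iteration 0. Methods with
a scipy iteration callback (L-BFGS-B, CG, and the Newton harness) log one row
per accepted iterate; Brent and the least-squares drivers expose no callback,
so history logs one row per objective evaluation. Histories and summaries are
plain text (tab-separated / JSON) and are overwritten, never appended.

## Confidence intervals

Residual variance s² = SSR/(n−p) from the concatenated residuals at the
optimum. Covariance = s²(JᵀJ)⁻¹ when a residual Jacobian is available
(forward differences, switching to backward at an active upper bound;
non-finite probes flag the column unusable), else 2s²H⁻¹ from a
central-difference Hessian of the scalar objective (stencil centre shifted
inward at bounds so no probe leaves the feasible box — a small, documented
bias, acceptable for a diagnostic). Intervals are estimate ±
t_{n−p,(1+level)/2}·√diag(cov), level 0.95 by default. A rank-deficient JᵀJ
raises with the null-space direction, i.e. the parameter combination the data
cannot identify. Zero residuals give zero-width intervals.

## Built-in forward models

The three models are deliberately desk-scale structural analogues of
image-based continuum FE models; they preserve the parameter→output character
of each calibration family (linear-in-parameter scalar; nonlinear
two-parameter curve; linear two-parameter list) with identical calibration
mathematics, while solving in microseconds.

- **Greyscale chain** (1 parameter). Uniaxial elements in series, modulus
  Eᵢ = slope·GSᵢ (GS normalised to (0,1]; the slope, MPa per unit greyscale,
  carries all scale). Assembled 1-D system under prescribed end displacement;
  output = reaction/displacement (N/mm), exactly linear in the slope.
- **GOH specimen** (2 parameters k₁ [MPa], k₂ [–]). Homogeneous
  incompressible uniaxial kinematics (J = 1, λ_r = λ_z^{−1/2}) instead of a
  meshed boundary-value problem: the closed-form stretch field allows an
  independent finite-difference oracle on the strain energy. Two symmetric
  fibre families at ±θ; dispersed fibre invariant
  Ē = κ(Ī₁−3) + (1−3κ)(Ī₄−1); the tension-only switch is a Macaulay bracket
  on Ē (the common convention). Force = A₀·dΨ/dλ (= Cauchy stress × current
  area). `expm1` keeps the k₂→0 limit exact; exp arguments beyond 500 are
  treated as solver overflow (failed output). The compressibility coefficient
  is retained in the fixed-parameter type for API completeness but unused
  under the incompressible assumption. Fixed constants default to c₁₀ = 0.1
  MPa, κ = 0.1, θ = 30°: fixture conventions in the physiological range for
  annulus tissue, not measurements.
- **Lamellar stack** (2 parameters k_r, k_t [N/mm]). Lamellae are node chains
  with per-lamella in-plane spring stiffness; lamella 0 is fixed, the outer
  lamella carries radial loads, and the radial displacements of 8–16 tracked
  points are observed. Facing nodes are coupled radially by k_r. The
  tangential stiffness is mobilised through oblique diagonal connectors
  (node (i,j)→(i+1,j+1)): with strictly per-component springs the stiffness
  matrix block-diagonalises and radial observations carry *no* information on
  k_t — the oblique-elastin geometry is what makes the two-parameter
  calibration identifiable from radial data, and is the physical picture of
  an interlamellar fibre network anyway. The applied radial load is graded
  across the outer nodes to excite shear. A single-column stack degenerates
  to plain radial/tangential springs (used by the hand-solvable series test).

## Synthetic specimen groups

The fixtures module emulates the study conditions the calibration families
target, fixed once:

| case | n | noise CoV | true parameters |
|---|---|---|---|
| bone_greyscale | 22 | 0.47 | slope = 3000 MPa/GS |
| osteodisc_goh | 6 | 0.05 | k₁ = 1.0 MPa, k₂ = 30.0 |
| interface_slice | 3 | 0.05 | k_r = 2.0, k_t = 1.0 N/mm |

Noise is one mean-preserving multiplicative lognormal factor per specimen
(σ² = ln(1+CoV²)): observations stay positive, and the quoted CoV is the
*between-specimen* scatter, which is what high-variance bone data exhibits.
Structural variation (element counts 8–12, greyscale fields U(0.5,0.9),
geometry ranges, lamella counts 4–6 and stiffness U(4,8) N/mm, 8–16 tracked
points) is drawn from documented uniform ranges so group calibration is a
genuine multi-model problem; the bone geometry ranges are sized so structural
scatter (~0.16 CoV) stays subordinate to the stated noise CoV. Identical
(recipe, seed) pairs give byte-identical files. The `osteodisc_goh` fixtures
use a 0–1.2 mm displacement grid (13 points, stretches up to ~1.17), giving
peak forces of a few hundred newtons for the default geometry.

What the synthetic conditions do **not** emulate: image-based 3-D anatomy and
meshing, measurement noise correlated along a curve, contact and boundary
artefacts, or model-form error (the generating model *is* the fitted model).
Passing recovery tests therefore demonstrates the correctness of the
calibration machinery — objective assembly, dispatch, convergence,
uncertainty — not the adequacy of any particular constitutive model for real
tissue.

## Numerical choices and degenerate inputs

- Curve x must be strictly increasing; violations are rejected at parse time
  with the line number.
- `.dat` files are written with 17 significant digits so read-back is exact.
- A tie in the interpolation sample count goes to the experimental grid.
- Grid-search cross-checks of the univariate calibration use 10⁴ + 1 points
  over the bound interval (10⁻⁴ resolution), small enough to run in seconds
  at the built-in model scale.
- Problem sizes throughout (≤ 22 specimens, ≤ 13-point curves, ≤ ~100 DOF
  lattices) are chosen so the full calibration suite runs in well under a
  minute; the mathematics is size-independent.

## Known limitations

- No global optimisation: all methods are local and gradient-based; poorly
  chosen starts on multimodal objectives converge to local minima.
- The scalar-objective covariance 2s²H⁻¹ treats the objective as an SSR;
  for the RMS objective this is an approximation — the Jacobian route is
  preferred whenever residuals are available.
- Functional (concatenated-residual) group calibration cannot survive a
  specimen that fails only for some parameter values mid-run (residual
  length changes); use the scalar aggregation when solver failures are
  expected.
- The adapter seam for real FE solvers is the `ForwardModel` contract (a
  callable parameter vector → output); no Abaqus/FEBio drivers are included.
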