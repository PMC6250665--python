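# Methods

`coro1d` computes Fractional Flow Reserve (FFR) along coronary centerline
trees with a one-dimensional blood-flow model under hyperemic conditions.
This note records the model, its assumptions, the numerical choices, and
what the synthetic test conditions do and do not demonstrate.

## Governing model

Each branch carries the 1D mass/momentum system with an algebraic tube law
(CGS units):

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dP/dx + 2 pi omega mu U / rho = 0
    P = P0 + beta (sqrt(A/A0) - 1)

with lumen area `A`, flow `Q`, mean velocity `U = Q/A`, pressure `P`, and
reference area `A0(x)` taken from the centerline geometry. Blood is
Newtonian with `rho = 1.05 g/cm^3`, `mu = 4 cP`. The friction coefficient
`omega` encodes the cross-sectional velocity profile; its baseline is
`omega0 = 11`, appropriate for the blunt profiles of hyperemic coronary
flow, optionally scaled by a network-specific factor `f_omega`.

**Quasi-rigidity.** FFR reference computations treat the lumen as rigid, so
`beta` is deliberately set far above physiological stiffness: the package
calibrates the smallest `beta` on a factor-2 grid for which the area
deviation stays under 1% across the pressure range the simulation will
visit, then applies a further safety factor of 2 (`calibrate_beta`). For a
60–125 mmHg range with `P0 = 88 mmHg` this yields `beta = 5.1e7 dyn/cm^2`
before safety; measured deviations in the pulsatile tests are below 0.3%.
The price of stiffness is a large wave speed (`c = sqrt(beta/2 rho)
(A/A0)^{1/4}`, about 4000 cm/s), which controls the explicit time step.

**Boundary conditions.** The inlet prescribes the aortic pressure `P_ao`
(constant, or a periodic waveform; a raised-cosine systole between stated
diastolic and systolic pressures is provided for synthetic runs since
patient waveforms are case-specific). Outlets prescribe flows. Hyperemic
flows are constructed from cardiac output: resting coronary flow
`RCBF = 0.045 CO`, hyperemic flow `HCBF = CFR * RCBF` with `CFR = 2.6`,
apportioned per artery by circulation dominance (LAD/LCx/RCA/RI percentage
table) and split among outlets by Murray's law, `Q_k ∝ r_k^3`, with the
outlet radius taken as the mean over the distal 0.25 cm of the branch to be
robust to endpoint noise. Cardiac output is an input: regressing it from
demographics is outside this package's scope.

## Junction models

Junctions conserve mass, `sum_i sigma_i Q_i = 0`. The remaining relations
come in two flavors:

* **S (standard):** total pressure `P + rho U^2/2` is equal across all
  connected branches.
* **D (dissipative):** each non-supplier branch i loses
  `p_loss_i = K_i rho u_1^2/2` relative to the supplier (the branch
  delivering most of the inflow; ties broken by branch id), with

      K_i = (2 C_i + u_i^2/u_1^2 - 1) u_i^2/u_1^2
      C_i = 1 - cos(3/4 (pi - phi_i)) / (lambda_i psi_i)

  where `lambda_i = Q_i/Q_1`, `psi_i = A_1/A_i` and `phi_i` is the
  branching angle measured from the supplier. Two conventions are ours:
  the angle enters through a single 3/4 factor (the loss model's source
  literature composes the angle transformation ambiguously), and the loss
  is clamped at >= 0 — the model adds dissipation, never energy. Angles are
  measured from the geometry by least-squares tangent fits over a 0.25 cm
  window adjacent to the junction.

The coupling to the branch interiors uses the outgoing Riemann invariants
`W = U ± 4c` of the hyperbolic system, giving `2 N_j` algebraic equations
per junction, solved by a damped Newton iteration with an analytic Jacobian
(the D loss term is Picard-lagged; if that stalls far from equilibrium, a
finite-difference quasi-Newton fallback on the full residual is attempted
before reporting failure). Converged solves satisfy mass to 1e-10 relative
and the total-pressure relations to 1e-10 relative; forcing `K_i = 0`
reproduces the S model exactly, which the tests assert bitwise.

## Stenosis element

Detected lesions are excised from the 1D mesh (the span `[s_start, s_end]`)
and replaced by a lumped element enforcing

    dP = Kv mu/D U + Kt rho/2 (A/A_s - 1)^2 U |U| + Ku rho L_s dU/dt

between its end faces, with `U`, `A`, `D` of the unobstructed vessel
(evaluated at the reference area of the lesion), `A_s` the minimal lumen
area and `L_s` the lesion length. `Kt = 1.52`, `Ku = 1.0` are the
one-fits-all coefficients; the viscous coefficient is geometry-based,

    Kv0 = 32 (0.83 L_s + 3.28 sqrt(A_s)) / (2 sqrt(A)) [0.75 A/A_s + 0.25]^2

optionally scaled by a per-lesion factor `f_K`. In the transient solver the
element is a 0D coupler between the adjacent mesh faces (mass continuity,
`dU/dt` discretized backward-Euler); in the steady solver it is a pressure
jump. The embedding as an excised span is our choice — the element
literature specifies the drop, not the mesh surgery.

## Stenosis detection

Lesion extraction must be reproducible, so it is fully automatic:

1. **Reference lumen:** iteratively reweighted least-squares line fit of
   area vs arclength per branch; points with negative residual beyond
   `2.5 * MAD` are excluded and the line refit until the inlier set is
   stable (max 20 iterations). Only lumen *loss* is treated as outlying.
2. **Lesions:** the severity profile `sigma = 1 - A/A_ref` is thresholded:
   a lesion is a maximal connected region with `sigma > 0.25` containing at
   least one point with `sigma >= 0.4`; regions closer than 0.5 cm merge.
   Per lesion, `A_s` is the minimum area, `A` the reference area at that
   minimum (a single reference value per lesion, since the drop formula
   uses one), `L_s` the region extent.

All four thresholds are configuration-exposed; the defaults above are this
package's concrete instantiation of an automatic detector and were chosen
so that moderate (50% area) cosine lesions are detected while physiologic
taper is not.

## Scenarios

* **R (raw):** no elements; the narrowing stays in the mesh and only
  friction and Bernoulli effects act.
* **P (practical):** detected lesions become elements with `f_K = 1` —
  no tuning of any kind.
* **I (intermediate):** `f_K` estimated per lesion against target element
  pressure drops.
* **B (best-case):** as I, plus `f_omega` estimated against target outlet
  pressures.

Each combines with junction model S or D (eight scenarios `Y_X`). Targets
are typically lumped from a high-fidelity 3D reference solution; the
package reads them as plain per-lesion/per-outlet values and, in its test
conditions, generates them from its own solutions with known factors.

**Estimation** is deterministic bounded least squares
(`scipy.optimize.least_squares`, bounds [0.05, 20]) on the squared mismatch
— time-averaged over one cycle for waveform targets, plain for steady —
re-running the solver per iterate; `f_K` for all lesions of a network is
estimated jointly, then `f_omega`, optionally alternated (two sweeps
default). With flows prescribed, each element's drop depends only on its
own `f_K`, so the joint problem is well conditioned. A sequential
filter-based assimilation would estimate the same quantities; for this
low-dimensional steady/periodic setting a direct optimizer is simpler and
exactly reproducible.

## Numerics

**Steady solver.** With prescribed outlet flows the branch flows follow
exactly from tree mass balance and `A = A0`; the momentum balance
integrates in closed form (Bernoulli) plus trapezoidal quadrature of the
friction term along each branch at centerline resolution (0.05 cm),
inserting junction relations and element drops as algebraic jumps. This is
a differential-algebraic solve, exact up to quadrature.

**Transient solver.** Second-order finite volumes: minmod-limited MUSCL
reconstruction in `(eta, Q)` with `eta = A/A0`, an HLL flux, Heun (RK2)
time stepping under a global CFL restriction (default 0.9). Two choices
matter in the stiff quasi-rigid regime, where a relative area error of
1e-4 corresponds to ~2 mmHg:

* *Well-balanced geometry source.* The pressure-gradient flux is written in
  conservative form with the geometric source `eta^{3/2} beta dA0/(3 rho
  dx)`, algebraically identical to the continuum term but discretized so a
  state of uniform `eta` (uniform pressure, zero flow) is an exact discrete
  equilibrium for arbitrary `A0(x)`. Naive discretizations leave O(dx^2)
  imbalances that beta amplifies to mmHg-scale artifacts in steep tapers.
* *Constant-eta face extrapolation.* Boundary and coupler equations
  evaluate the interior state at the face as `A_face = eta_cell * A0_face`,
  not `A_cell`; in steep geometry the latter misstates the Riemann
  invariant by more than the entire velocity scale.

Runs with pulsatile boundaries integrate a fixed number of cycles
(landing exactly on cycle boundaries) and report final-cycle time averages
plus a cycle-to-cycle periodicity residual; constant-boundary runs stop
when the pressure field is stationary to 5e-3 mmHg (checked every 400
steps). Negative areas or non-convergent couplers abort with diagnostics.

**Verified properties** (the test suite computes all of these): steady
straight-tube drops match `2 omega pi mu L Q / A0^2` to 1e-10 (steady) and
0.5% (transient); transient and steady solutions agree within 0.5% in
pressure on tubes, stenotic tubes and 2-level trees; the pressure error
against a closed-form tapered solution decays at first order or better
under grid refinement (the element jumps limit global order); inviscid
runs conserve total pressure along branches to 1e-12.

## FFR and statistics

FFR at a point is the ratio of time-averaged pressure to time-averaged
aortic pressure over the final cycle (plain ratio in steady mode) —
ratio-of-means, matching how reference fields are normalized. Sampling
helpers provide the quarter-length locations `{l/4, l/2, 3l/4, l}` per
vessel and a clinical interrogation point at least 10 mm distal to the
target lesion (warning when the vessel is too short).

Field comparisons report Bland–Altman mean ± SD (n−1) of the differences,
the OLS fit `FFR_test = a FFR_ref + b`, Pearson r with a two-sided t-test
p-value, and — at the 0.8 cutoff with lower FFR as positive — prevalence,
accuracy, sensitivity, specificity, PPV, NPV and AUC (from the continuous
test values against reference labels; equals the Mann–Whitney rank
statistic, which the tests assert). Degenerate single-class references
yield NaN with a warning. A Wilcoxon signed-rank utility covers paired
pressure-drop comparisons.

## Synthetic data: what it shows and what it does not

The generator produces straight tubes, tubes with raised-cosine area dips
(peak fractional severity, fixed extent), and symmetric binary trees with
cube-law daughter areas, planar branching at a set half-angle, and optional
seeded multiplicative area noise. These exercise every code path —
detection, excision, junction coupling for both models, calibration,
pulsatile dynamics — against closed-form or brute-force oracles.

They do not emulate: irregular/eccentric lumen profiles and imaging noise
of real centerlines, diffuse disease (the reference-line fit assumes a
mostly healthy branch), serial overlapping lesions, non-planar tortuosity
(angles are exact by construction), patient pressure waveforms, or the
availability of an independent 3D reference solution — calibration tests
recover factors from self-generated targets, which validates the estimator,
not the physical fidelity of the element model on real lesions. Agreement
statistics on clinical cohorts therefore cannot be reproduced here; the
package verifies the machinery that would compute them.

## Problem sizes and defaults

Synthetic studies use 3–10 cm vessels at 0.05 cm resolution (60–200 cells),
2-level trees (7 branches, ~260 cells), two cardiac cycles of 0.8 s for
pulsatile runs and stationarity-terminated runs otherwise; these sizes make
every oracle comparison exact or tight while keeping the full verification
suite in the minutes range on one core. All defaults (`rho`, `mu`, `P0`,
`omega0`, `Kt`, `Ku`, `CFR`, thresholds, bounds) are single constants in
the module that owns them and are overridable per call.

## Known limitations

* The wall law is linear in `sqrt(A/A0)` with a single `beta`; viscoelastic
  or collapse behavior is out of scope (irrelevant in the quasi-rigid use).
* The D junction loss model derives from planar two-branch bifurcation
  data; its extrapolation to >3-way or strongly non-planar junctions is
  uncontrolled (losses are clamped non-negative as a safeguard).
* Outlet flows are prescribed; there is no downstream resistance/Windkessel
  closure, so flow redistribution by lesion severity must come from the
  upstream pipeline that produces the flows.
* The transient element treats `dU/dt` backward-Euler (first order), which
  caps the temporal order at element faces.
* Stenosis spans may not overlap on a branch, and a span must leave at
  least two mesh cells on each side.
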