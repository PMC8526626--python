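# Methods

## Model and assumptions

`slithersim` treats a snake as a prescribed-curvature planar curve propelled
by substrate friction.  The assumptions, in decreasing order of importance:

* **Kinematics are prescribed, dynamics are reduced.**  The lateral curvature
  wave κ(s, t) = ε cos(2πk(s + t)) is imposed exactly; the body never deviates
  from it.  Internal forces and torques are assumed to integrate to zero, so
  the only dynamical degrees of freedom are the centre of mass x̄(t) and the
  mean orientation ᾱ(t).  The internal force field itself is never
  represented.
* **Lift is weight redistribution, not geometry.**  Out-of-plane lifting
  enters purely through the non-negative modulation N̂(s, t) of the normal
  force, clipped at zero (a body section cannot push up on the ground) and
  renormalised at every instant so the total weight is conserved:
  N = N̂ / ∫N̂ ds.  The normalisation is recomputed numerically at each
  evaluation time, which keeps non-integer wavenumber ratios λ (where ∫N̂ ds
  varies with t) consistent.
* **Friction is kinetic, anisotropic Coulomb.**  The coefficient vector
  resolves the slip direction into transverse and fore/aft components with
  ratios μt/μf and μb/μf; static friction is omitted (it does not affect the
  steady-state behaviors this package measures).  The Heaviside split uses
  H(0) = 1/2.
* **Inertia is retained.**  The equations keep the Fr-scaled inertial terms
  (including the shape-change correction in the angular equation) rather than
  taking the quasi-static Fr → 0 limit; the working regime Fr = 0.1 is
  friction-dominated but not inertia-free.
* **Terrain heterogeneity is a scalar field.**  Substrate features scale the
  whole friction vector by a positive factor p evaluated at each node's
  instantaneous lab position; all three coefficients are scaled equally.
  Rigid obstacles are represented only as high-friction patches; there is no
  contact mechanics and no substrate memory or remodeling.

The angular equation was re-derived from the node-level momentum balance
(substituting the kinematic acceleration expansion, crossing with x − x̄, and
using the zero-integral assumptions on internal loads); the resulting
inertial correction ∫ I[n̂]·I[t̂ α_t²] − I[t̂]·I[t̂ I[κ_tt]] ds is validated
in the test suite against a finite-difference oracle that differentiates the
reconstructed motion directly (agreement < 1e-4 relative).

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| ε | lateral curvature amplitude | 7 | — |
| k | lateral wavenumber | 1 | waves / body length |
| A | lifting amplitude | 0 | — |
| Φ | lifting phase offset | 0 | turns (fraction of a period) |
| λ | lifting/lateral wavenumber ratio | 1 | — |
| μt/μf | transverse/forward friction ratio | 2 | — |
| μb/μf | backward/forward friction ratio | 1.5 | — |
| Fr | inertia/friction ratio | 0.1 | — |
| δ | Coulomb velocity regularisation | 1e-6 | body lengths / period |

ε = 7 and k = 1 match kinematic measurements of slithering snakes; μb/μf =
1.5 matches measured scale anisotropy and has little effect on outcomes;
μt/μf is the environmental parameter that selects between gait regimes
(≈ 2 on firm ground, → 1 on yielding sand/mud, ≫ 1 for wheeled robots).
`froude_number(L, tau, g, mu_f)` converts physical scales; the measured
values L = 0.35 m, τ = 2 s, μf = 0.089 give Fr ≈ 0.100.

λ = 1 lifts one side of the body only (the sidewinding template: with
Φ ≈ 1/4 the unweighted segments are those moving transversely); λ = 2 lifts
both sides symmetrically.  For the stock λ = 2 comparison strategy we use
Φ = 0.25, which places the weight minima at the curvature extremes —
lifting the bends, as observed in slithering colubrids — and yields forward
travel; Φ = 0 concentrates weight at the bends instead and reverses the
direction of travel.  The `exp_curvature` model (N̂ ∝ e^{−κ}) is provided
for comparison with earlier work; its proportionality constant is absorbed
by the normalisation.

## Numerics

* **Arclength grid.**  201 uniform nodes with trapezoidal quadrature;
  the mean-zero integral is a cumulative trapezoid minus its quadrature mean,
  making the mean-zero property exact by construction.  Quadrature accuracy
  is O(h²): ~3e-5 on positions and ~6e-6 on J at the default grid for the
  ε = 7 integrands; tests verify both the values and the O(h²) contraction
  under grid doubling.
* **Velocity regularisation.**  u = v/√(|v|² + δ²) removes the Coulomb
  singularity at rest; reported displacements change by < 1e-3 when δ is
  reduced tenfold (tested).  Node velocities are assembled analytically from
  the state derivatives (chain rule), not by numerical differencing.
* **Time integration.**  Adaptive RK45 (`scipy.solve_ivp`), rtol 1e-8 /
  atol 1e-10 by default; the regularised force is continuous in time so no
  event handling is needed.  Output is sampled uniformly at ≥ 100
  samples/period.  The snake starts from rest with the wave already imposed;
  the standard protocol integrates 10 periods and measures over the final
  one, by which point startup transients are dissipated (metrics from the
  two final windows agree, and this convergence is checked per run).
  A numba-compiled right-hand side is used on uniform substrates (verified
  against the readable numpy assembly to 1e-14 relative); heterogeneous maps
  take the numpy path.
* **Metrics.**  The polar-coordinate trajectory metrics are realised through
  the COM-velocity heading: θ is the unwrapped heading of the one-period
  trailing-averaged velocity (robust to within-period wobble), θ̇ its net
  rate over the window, and |v_eff| the magnitude of the window-averaged
  velocity in the frame co-rotating at θ̇.  For circular steady states this
  reproduces the polar-coordinate definitions exactly (validated on
  constructed circular and straight paths); for straight paths it avoids the
  origin-dependence a fixed-origin polar angle would have.  When net travel
  is below 10% of path length the heading is meaningless: θ̇ is set to 0 and
  the run flagged non-directional, which keeps closed COM loops (wiggling in
  place) from registering a spurious winding as steering.  Pose-angle
  integrands are unwrapped before averaging to avoid ±π branch artifacts.
* **Classifier.**  The published phase diagrams do not print their cutoffs;
  the defaults (|θ̇| < 0.05 rad/period → straight, |γ| < 0.35 rad →
  slithering, 0.35–2.6 → sidewinding, > 2.6 → backward, v_eff < 0.02 with
  |θ̇| ≥ 0.05 → spinning, unconverged → transition) reproduce the expected
  phase topology and are configurable and surfaced in all output metadata.
* **Sweeps.**  Cells are independent, deterministic simulations; per-cell
  failures are flagged and labeled transitional without aborting the sweep.
  The default desk-scale resolution is 41×41 (the published 501×501 map is a
  cluster-scale computation); separatrices are extracted with
  marching-squares zero contours (scikit-image) with linear interpolation.
* **Landscapes.**  Overlapping primitives resolve deterministically
  (last-listed wins).  Ensembles vary initial lateral offset
  deterministically — the dynamics have no noise, and deflection spread
  arises from where each snake meets the pattern.  Deflection α_p is the
  heading change between the period before first map contact and the period
  after last contact (contact = any body node sampling a scale ≠ 1); snakes
  still in contact at the end of the run, or barely moving afterwards, are
  reported as stuck and excluded from (but counted alongside) the pdf.

## Known behaviors and limitations

* **Isotropic residual slip.**  With μt/μf = 1 and no lifting, the model
  retains a small, fully converged backward drift of ≈ 0.006 body
  lengths/period (insensitive to grid, tolerance, and δ).  This is a real
  property of the prescribed-curvature friction model — idealised accounts
  round it to zero — and the metrics report it honestly rather than
  suppressing it.
* **Mirror-symmetry nulls.**  Instantaneous-torque cancellation on
  mirror-symmetric shapes holds only for fore-aft symmetric friction
  (μb = μf), because mirroring reverses the tangent field and swaps
  forward/backward slip; the period-averaged net loads of the A = 0 and
  λ = 2 gaits vanish regardless (< 1e-4, tested).
* **Qualitative landscapes.**  The landscape module targets symmetry and
  null-perturbation contracts (uniform map → no deflection, mirrored system
  → negated deflections, zero-width strip → null).  Quantitative deflection
  distributions of real snakes traversing rigid posts involve 3D bodies and
  contact mechanics and are out of scope for the planar model.
* **What passing tests show.**  All inputs are generated by the model itself
  under the stock study conditions; there is no observational data in the
  loop.  Agreement therefore demonstrates internal consistency of the
  implementation and reproduction of the model-level claims, not validation
  against animal kinematics.
* Performance-scale choices: the suite runs sweeps at reduced resolution
  (e.g. 5×5 vs 9×9 label agreement, 6-period cells, 61–101 nodes) and the
  acceptance protocol uses the full defaults (10 periods, 201 nodes,
  rtol 1e-8).
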