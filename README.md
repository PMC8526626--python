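# slithersim

A planar, effective-friction simulator of limbless (snake) locomotion.

Terrestrial snakes propel themselves by pressing an undulating body against
the ground: lateral body waves are rectified into motion by anisotropic
Coulomb friction, and out-of-plane body lifting redistributes weight along the
body, modulating the local friction force. `slithersim` implements this view
as a small, deterministic dynamical system and uses it to map out how gaits —
slithering, sidewinding, in-place spinning, backward travel — emerge from the
interplay of the lifting wave and the frictional environment, and how
*heterogeneous* friction landscapes (high-friction patches, frictionless
strips, gradient "lenses") passively steer a snake, in analogy with optics.

It is aimed at researchers in organismal biomechanics and snake-like robotics
who want a fast, scriptable desk-scale model rather than a full 3D
elastic-body simulation.

## Model

The snake is an inextensible planar curve of unit length (arclength
`s ∈ [0, 1]`, tail to head; time in undulation periods) with prescribed
lateral curvature and lifting waves

```
κ(s, t)  = ε cos(2π k (s + t))
N̂(s, t) = max{0, A cos(2π k_l (s + t + Φ)) + 1},   k_l = λ k
```

Weight is conserved through the normalisation `N = N̂ / ∫₀¹ N̂ ds`.  Local
orientation and position follow from the mean-zero integration operator
`I[f](s) = ∫₀ˢ f ds′ − ⟨∫₀ˢ f ds′⟩`:

```
α(s, t) = ᾱ(t) + I[κ],      x(s, t) = x̄(t) + I[t̂],    t̂ = (cos α, sin α)
```

The substrate acts through a regularised anisotropic Coulomb force density
`F = −N μ`, with

```
μ = (μt/μf)(u·n̂)n̂ + [H(u·t̂) + (μb/μf)(1 − H(u·t̂))](u·t̂)t̂
```

where `u` is the (regularised) slip direction and `H` the Heaviside step.
Balancing friction against inertia (internal forces integrate to zero) leaves
a 6-dimensional system for the centre of mass `x̄` and mean orientation `ᾱ`:

```
Fr x̄_tt = ∫₀¹ F ds
Fr ᾱ_tt = (1/J) ∫₀¹ (x − x̄) × F ds
          + (Fr/J) ∫₀¹ ( I[n̂]·I[t̂ α_t²] − I[t̂]·I[t̂ I[κ_tt]] ) ds
```

with moment of inertia `J = ∫ (x − x̄)² ds` and Froude number
`Fr = (L/τ²)/(g μf)` (friction-dominated at the working value 0.1).
Steady gaits are summarised by the pose angle γ (body orientation vs travel
direction), steering rate θ̇, and effective speed |v_eff|; heterogeneous
substrates enter as a multiplicative scale field `p(x)` on the friction
coefficients.

Stock parameters: ε = 7, k = 1, μb/μf = 1.5, Fr = 0.1, with μt/μf the key
environmental dial.

## Worked example

Sidewinding under isotropic friction — a one-sided (λ = 1) lifting wave a
quarter period out of phase with the lateral wave:

```sh
$ slithersim simulate --A 1.0 --phi 0.25 --mu-t-ratio 1.0 -o out/
label=turning_sidewinding gamma=1.4739 theta_dot=-0.0966 v_eff=0.5397
```

The snake travels at 0.54 body lengths per period while holding its body at
1.47 rad (≈ 84°) to its direction of travel — the signature of sidewinding —
with a slow residual turn of −0.097 rad/period.  Compare lifting strategies
across frictional environments:

```sh
$ slithersim profiles --ratios "1,2" -o out/
   strategy    ...  mu_t_ratio    v_eff     theta_dot       gamma                label
    no_lift    ...         1.0 0.005983 -5.305285e-07  3.7464e-08  straight_slithering
    no_lift    ...         2.0 0.159394 -1.525523e-09 -1.2589e-09  straight_slithering
 asymmetric    ...         1.0 0.539681 -9.658261e-02  1.4739e+00  turning_sidewinding
 asymmetric    ...         2.0 0.500838 -7.706510e-02  1.3179e+00  turning_sidewinding
  symmetric    ...         1.0 0.130833  8.941968e-08  1.1015e-07  straight_slithering
  symmetric    ...         2.0 0.252222  6.892782e-08  5.3839e-08  straight_slithering
```

On a near-isotropic substrate (μt/μf = 1) planar undulation barely moves
(0.006 BL/period) while sidewinding is fast (0.54); with anisotropy
(μt/μf = 2) ordinary slithering becomes effective (0.16) and keeps speeding
up as the ratio grows.  Other entry points:

```sh
slithersim sweep --resolution 41 -o out/        # (A, Φ) phase map + separatrices
slithersim ensemble --config diffraction.yml    # deflection pdf over a friction landscape
slithersim contours out/phase_map.csv -o out/   # re-extract zero contours
```

or from Python: `simulate()`, `compute_metrics()`, `sweep()`,
`friction_ratio_profiles()`, `run_ensemble()` — see the module docstrings.

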