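# Methods

## The constitutive model

`fungqlv` implements the causal form of Fung's quasi-linear viscoelasticity
(QLV) for isotropic, finitely deformed solids.  The instantaneous response
is hyperelastic: a strain energy function W(I1, I2, I3) of the principal
invariants of B = F·Fᵀ generates the effective elastic Cauchy stress

    Tᵉ = β0 I + β1 B + β−1 B⁻¹,
    β0 = (2/J)(I2 W2 + I3 W3),  β1 = (2/J) W1,  β−1 = −2 J W2,

with Wk = ∂W/∂Ik and J = det F.  Tᵉ is split into its deviatoric and
hydrostatic parts, and each part is pulled back to a second
Piola–Kirchhoff measure (Π_Dᵉ, Π_Hᵉ) so that the fading-memory
superposition stays objective.  The viscoelastic Cauchy stress is then

    T(t) = J⁻¹F(t)[Π_Dᵉ(t) + ∫₀ᵗ D′(t−s) Π_Dᵉ(s) ds]Fᵀ(t)
         + J⁻¹F(t)[Π_Hᵉ(t) + ∫₀ᵗ H′(t−s) Π_Hᵉ(s) ds]Fᵀ(t),

where D(t) and H(t) are scalar reduced relaxation functions (D(0) = H(0)
= 1) acting on the shear-origin and volumetric-origin parts respectively.
The integrated-by-parts form carries any jump at t = 0 through the
instantaneous term, so step inputs are represented by their t = 0⁺ value
at the first grid node.

Causality is built in: every catalog SEF satisfies the natural-state
identity W1 + 2W2 + W3 = 0 at (I1, I2, I3) = (3, 3, 1), so both effective
stress parts vanish in the undeformed state and the stress is identically
zero until a deformation is imposed.  This is the property that
distinguishes the formulation from variants in which the stress snaps to
zero the moment the stretch returns to 1; the Ciambella et al. comparator
(`ciambella_uniaxial`) reproduces that defect on purpose, and the
ABAQUS-style comparator (`abaqus_style_uniaxial`) convolves the full
instantaneous stress with a single relaxation function.

For incompressible materials (J ≡ 1) the hydrostatic branch collapses
into a Lagrange-multiplier pressure.  For the uniaxial bar with
traction-free lateral faces the pressure is eliminated between the axial
and lateral normal-stress equations, leaving a single shear function D(t)
and the closed forms implemented in `yeoh_uniaxial` and
`mooney_rivlin_uniaxial` (which agree with the generic split-based path
to 1e−10·μ, a permanent regression test).

## Material catalog

| model          | W | parameters | notes |
|----------------|---|------------|-------|
| `neo-hookean`  | μ/2 (I1−3) | μ | incompressible; = `yeoh2` at α = 0, = `mooney-rivlin` at γ = 1/2 |
| `yeoh2`        | μ/4 [2(I1−3) + α(I1−3)²] | μ, α ≥ 0 | incompressible; hardens with α |
| `mooney-rivlin`| μ/2 (1/2+γ)(I1−3) + μ/2 (1/2−γ)(I2−3) | μ, γ ∈ [−1/2, 1/2] | incompressible; softens as γ drops |
| `horgan-murphy`| μ/2 (1/2+γ)(I1−3I3^{1/3}) + μ/2 (1/2−γ)(I2−3I3^{2/3}) + κ/2 (I3^{1/2}−1)² | μ, γ, κ | slightly compressible; κ is the infinitesimal bulk modulus |
| `gent`         | −μ/2 Jm log(1−(I1−3I3^{1/3})/Jm) + κ/32 (I3−1−log I3)⁴ | μ, Jm, κ | limited chain extensibility; hard error at the locking limit |

Two remarks on the Gent entry.  First, the limited-extensibility term
uses the isochorically adjusted invariant I1 − 3I3^{1/3} (the same
adjustment the Horgan–Murphy SEF applies to both invariants); this is
required for the natural-state identity to hold — with a bare I1 − 3 the
residual would be μ/2 and the model would be non-causal — and it reduces
exactly to the classical incompressible Gent form at I3 = 1.  Second, the
volumetric well (I3−1−log I3)⁴ behaves like (J−1)⁸ near J = 1: its
linearized bulk stiffness is zero, so κ only sets the scale of the
volumetric wall and a Gent bar dilates noticeably under tension.  That is
a property of this SEF, reproduced deliberately; users wanting a stiff
volumetric response should use Horgan–Murphy.

Gent inputs with I1 − 3I3^{1/3} ≥ Jm raise `LockingError` (naming the
first offending node in history evaluations) rather than clamping —
silent clamping would corrupt creep solves.

Parameter validation happens at construction (`MaterialModel` is frozen):
μ > 0, γ ∈ [−1/2, 1/2], κ > 0, Jm > 0, and incompressibility is a fixed
attribute of the model name.

## Relaxation functions

`ReducedRelaxation` is an N-term Prony series
D(t) = g∞ + (1−g∞) Σ gᵢ e^{−t/τᵢ} with Σ gᵢ = 1, g∞ ∈ (0, 1], τᵢ > 0 (s).
The worked examples use the classical one-term series with g∞ = μ∞/μ =
0.5 and τ = 1 s.  Evaluation is written as 1 + (1−g∞) Σ gᵢ·expm1(−t/τᵢ),
which is exactly 1 at t = 0 in floating point.  The analytic derivative
is used everywhere (never a numerical one), and negative times are domain
errors.

The bulk function H(t) belongs to the same family with independent
parameters.  The underlying catalog never prescribes H; the CLI defaults
H to D's parameters when no `bulk_relaxation` block is given, and this is
a package choice, not a modelling claim.  In the incompressible limit
κ/μ → ∞ the dilatational relaxation time must also be taken to zero
(H → constant): with a *relaxing* H the bulk history term does not reduce
to a pure pressure and the compressible solution does **not** converge to
the incompressible one (the gap saturates; verified numerically).  The
incompressible-limit tests therefore use H ≡ 1, under which the
Horgan–Murphy bar converges to the incompressible Mooney–Rivlin bar with
a gap ∝ μ/κ.

## Discretization

Histories live on uniform grids t₀ = 0 < … < t_N with identity (or zero
load) pre-history.  All hereditary integrals use composite Simpson
weights: the 3/8 rule covers the first three intervals when the interval
count is odd, and the single-interval startup integral over [0, h] is
Simpson on [0, h] with the integrand midpoint reconstructed by quadratic
interpolation through the first three nodes (this keeps kernel arguments
nonnegative and is locally O(h⁴)).  The scheme is fourth-order for smooth
integrands (verified against analytic exponential convolutions).

The creep problem — imposed axial stress, unknown stretch — is the
nonlinear Volterra equation

    T(t) = g(λ(t)) + Σⱼ fⱼ(λ(t)) ∫₀ᵗ D′(t−s) hⱼ(λ(s)) ds,

with N = 2 history terms (axial and lateral parts of Π_Dᵉ, prefactors
λ²(t) and −λ⁻¹(t)); `to_separable` builds (g, fⱼ, hⱼ) from any
incompressible catalog model and g(1) = hⱼ(1) = 0 by construction.  The
solver marches node by node: the history integral splits into a lagged
sum over known nodes plus a current-step part, and a scalar Newton
iteration (numerical derivative, previous node as initial guess,
residual acceptance at `newton_tol`·max(μ, |T|), expanding-bracket
bisection fallback) finds the node value.  Because the composite rules
need three nodes, nodes 1 and 2 are solved as a coupled 2×2 collocation
system before scalar marching begins.  On manufactured smooth solutions
the observed convergence order is ≈ 4 (the advertised bar is ≥ 3); the
default convergence study uses grids of 32–128 intervals against a
4096-interval forward reference, where errors sit far above both the
Newton floor and the reference's own O(10⁻¹³) error.

The lateral problem of the compressible bar — imposed λ1(t), unknown
λ2(t) — uses the same machinery on the zero-lateral-traction residual
Π_D22ᵉ + Π_H22ᵉ + conv(D′, Π_D22ᵉ) + conv(H′, Π_H22ᵉ) = 0 (the positive
push-forward prefactor divides out), with both relaxation branches in
the residual.  After any solve, re-evaluating the forward law on the
returned stretches reproduces the imposed data to solver tolerance; this
discrete-residual certificate is asserted in the tests.

Root selection is by continuity: Newton starts from the previous node, so
when the instantaneous response is non-monotone the branch continuous
with the creep path is tracked.

## Fixture protocols

`generate_history` provides the canonical test programmes: `step`
(t = 0⁺ value at every node), `ramp_hold`, `ramp_hold_release` (linear
ramps), `smooth_pulse` (C¹ cosine ramps up and back), and
`random_smooth` (seeded low-frequency Fourier modes under a C¹ envelope,
bit-reproducible for equal seeds).  Defaults — amplitude 0.5 (stretch
1.5 or load T/μ = 1 after scaling), ramp and hold times of 1 s against a
relaxation time of 1 s — mirror the slow ramp-and-hold programmes used
on soft-tissue specimens, where inertia is negligible; that quasi-static
assumption is inherited here (no dynamics anywhere in the package).
These synthetic histories exercise every code path but are idealized:
real experiments add measurement noise, imperfect gripping, and
non-homogeneous deformation, none of which is modelled, so passing tests
validate the constitutive implementation, not an experimental pipeline.

## Numerical choices and edge cases

- Grids must be uniform to 1e−12 (relative) and start at t = 0; violations
  are rejected at container construction, file parse errors name the line.
- Stresses are reported in units of μ when μ = 1 (the default); time is in
  seconds.
- The incompressible `elastic_cauchy` fixes the indeterminate pressure by
  returning the trace-free (deviatoric) part; only normal-stress
  differences are meaningful there.
- Solver defaults: `newton_tol` 1e−10 (relative residual), 50 iterations,
  bracket growth ×1.8 with 40 expansions.
- Convolutions are O(N²) in the number of nodes; a 4096-node forward pass
  runs in about a second on one core.

## Known limitations

- Isotropic materials only; the anisotropic rank-4 relaxation tensor is
  out of scope, as are inhomogeneous deformations, shear/torsion
  histories, dynamics, and fitting to experimental data.
- The compressible bar supports imposed stretch only (imposed load for
  the compressible case is not implemented).
- Power-law/fractional kernels, WLF temperature shifts and continuous
  relaxation spectra are not supported — Prony series only.
- No adaptive time-stepping; accuracy is controlled by the (uniform) grid.
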