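# fungqlv

Quasi-linear viscoelasticity (QLV, Fung's model) for finite-strain
uniaxial extension of soft-tissue-like materials, in a causal formulation:
the stress at time t is the instantaneous hyperelastic stress decreased by
a fading-memory convolution over the deformation history,

    T(t) = J⁻¹F(t)[Π_Dᵉ(t) + ∫₀ᵗ D′(t−s) Π_Dᵉ(s) ds]Fᵀ(t)
         + J⁻¹F(t)[Π_Hᵉ(t) + ∫₀ᵗ H′(t−s) Π_Hᵉ(s) ds]Fᵀ(t),

where Π_Dᵉ and Π_Hᵉ are the second Piola–Kirchhoff images of the
deviatoric and hydrostatic parts of the effective elastic Cauchy stress
derived from a strain energy function, and D(t), H(t) are Prony-series
reduced relaxation functions with D(0) = H(0) = 1.  Because every strain
energy function in the catalog satisfies W1 + 2W2 + W3 = 0 at the
undeformed state, the effective stresses vanish at zero deformation and
the model is causal — it carries memory of past excursions instead of
snapping to zero stress whenever the stretch returns to 1.

The package is for mechanicians and biomechanics modellers who want to

- predict stress for an imposed stretch history (incompressible uniaxial
  closed forms for neo-Hookean / two-term Yeoh / Mooney–Rivlin, a generic
  diagonal tensorial path for the compressible Horgan–Murphy and Gent
  materials, plus two published comparator formulations);
- solve the inverse problems: **creep** (imposed axial load → stretch) and
  the implicit lateral stretch of a **compressible bar**, both nonlinear
  Volterra integral equations marched by a high-order time-stepper
  (observed convergence order ≈ 4 on manufactured solutions);
- check the infinitesimal limit against Boltzmann's linear viscoelasticity.

## Worked example

Stress relaxation of an incompressible Yeoh bar (α = 1) under a held step
stretch of 1.5, with the one-term Prony relaxation μ∞/μ = 0.5, τ = 1 s:

```python
import numpy as np
from fungqlv import ReducedRelaxation, UniaxialHistory, yeoh_uniaxial

D = ReducedRelaxation.one_term(0.5, 1.0)          # D(t) = 0.5 + 0.5 e^{-t}
t = np.linspace(0.0, 20.0, 801)
hist = UniaxialHistory(t, np.full_like(t, 1.5))   # step held at lambda = 1.5
T = yeoh_uniaxial(0.0, D, hist).T                 # alpha = 0: neo-Hookean
print(round(T[0], 6), round(T[-1] / T[0], 6))
```

prints

```
1.583333 0.5
```

T(0⁺)/μ = λ² − λ⁻¹ = 1.583333 is the instantaneous elastic stress, and the
stress then relaxes to exactly the long-time fraction μ∞/μ = 0.5 of it —
for a held step the entire QLV convolution factorizes to T(t) = D(t)·T(0⁺).

Creep under a held load, solved through the Volterra time-stepper:

```python
from fungqlv import (MaterialModel, ProtocolSpec, generate_history,
                     solve_creep_incompressible, to_separable)

load = generate_history(ProtocolSpec("ramp_hold", amplitude=1.0,
                                     hold_time=5.0, n_nodes=301, stress=True))
form = to_separable(MaterialModel("yeoh2", alpha=1.0))
lam = solve_creep_incompressible(form, D, load).lam
print(round(lam[50], 4), round(lam[-1], 4))       # end of ramp, end of hold
```

prints `1.3187 1.4309`: the bar reaches stretch 1.319 when the load ramp
ends and keeps creeping to 1.431 as the material relaxes toward its
long-time stiffness.

The `examples/` directory holds one narrative script per capability
(stress relaxation families, formulation comparison, creep, compressible
bar); each prints the numbers it computes and what they mean.  A thin CLI
wraps the same operations:

```sh
qlv make-history --kind ramp_hold_release --amplitude 0.5 --out hist.csv
qlv relax --config material.yaml --history hist.csv --compare ciambella,abaqus --out stress.csv
qlv creep --config material.yaml --load load.csv --out stretch.csv
qlv compressible --config material.yaml --history lam1.csv --out result.csv
```

See `docs/methods.md` for the model, the material catalog, the quadrature
and solver design, and known limitations.

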