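"""Simple extension of a compressible viscoelastic bar.

The axial stretch lambda1(t) is imposed (smooth pulse to 1.3) on
Horgan-Murphy and Gent bars with distinct shear (D) and bulk (H)
relaxation.  The traction-free lateral faces make the lateral stretch
lambda2(t) the solution of an implicit Volterra equation, solved here
node by node.  With a large bulk modulus and instantaneous bulk
relaxation the Horgan-Murphy response converges to the incompressible
Mooney-Rivlin bar.
"""

import numpy as np

from fungqlv import (MaterialModel, ProtocolSpec, ReducedRelaxation,
                     compressible_axial_stress, generate_history,
                     simple_extension_compressible, solve_lateral_compressible,
                     uniaxial_incompressible_stress)

hist = generate_history(ProtocolSpec("smooth_pulse", amplitude=0.3,
                                     ramp_time=1.0, hold_time=1.0, n_nodes=241))
D = ReducedRelaxation.one_term(0.5, 1.0)
H = ReducedRelaxation.one_term(0.7, 0.3, kind="H")

for m in (MaterialModel("horgan-murphy", gamma=0.5, kappa=10.0),
          MaterialModel("gent", kappa=10.0, Jm=20.0)):
    diag, stress = simple_extension_compressible(m, D, H, hist)
    i = np.argmin(np.abs(hist.times - 1.5))  # mid-hold, lambda1 = 1.3
    J = np.prod(diag.stretches[i])
    print(f"{m.name}: at t = 1.5 s (lambda1 = {hist.lam[i]:.3f})  "
          f"lambda2 = {diag.stretches[i, 1]:.4f}, J = {J:.4f}, "
          f"T/mu = {stress.T[i]:.4f}, lateral stress = {stress.diagonal[i, 1]:.1e}")

print("\nJ > 1 under tension: the bar dilates slightly; the lateral stress is")
print("zero to solver tolerance (the implicit equation is satisfied).")

# incompressible limit: kappa/mu -> infinity with instantaneous bulk relaxation
oneH = ReducedRelaxation.constant("H")
T_inc = uniaxial_incompressible_stress(MaterialModel("mooney-rivlin", gamma=0.5),
                                       D, hist).T
print("\nincompressible limit (gap to the Mooney-Rivlin bar, gamma = 1/2):")
for kappa in (1e2, 1e3, 1e4):
    m = MaterialModel("horgan-murphy", gamma=0.5, kappa=kappa)
    lam2 = solve_lateral_compressible(m, D, oneH, hist)
    T = compressible_axial_stress(m, D, oneH, hist.times, hist.lam, lam2).T
    print(f"  kappa/mu = {kappa:7.0f}: max |T - T_inc|/mu = "
          f"{np.max(np.abs(T - T_inc)):.2e}")
print("The gap shrinks like mu/kappa, recovering the incompressible theory.")
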