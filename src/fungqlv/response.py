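"""Forward QLV: stress histories for imposed deformation histories.

Given an imposed stretch history the QLV Cauchy stress is the
instantaneous effective elastic stress decreased by a fading-memory
convolution of the effective-stress history with the derivative of the
reduced relaxation function(s):

    T(t) = J^-1 F(t) [ Pi_D^e(t) + int_0^t D'(t-s) Pi_D^e(s) ds ] F^T(t)
         + J^-1 F(t) [ Pi_H^e(t) + int_0^t H'(t-s) Pi_H^e(s) ds ] F^T(t).

For an incompressible uniaxial bar the hydrostatic branch collapses into
the Lagrange-multiplier pressure, which is eliminated through the
traction-free lateral faces, leaving a single shear relaxation function
D(t) acting on the deviatoric-origin split.  Closed uniaxial forms for the
two-term Yeoh and Mooney-Rivlin materials are provided alongside the
generic path, plus two comparator formulations from the literature
(Ciambella et al. and the ABAQUS-style convolution of the full stress)
and the Boltzmann linear model used for infinitesimal-strain consistency
checks.
"""

from __future__ import annotations

import numpy as np

from ._quadrature import convolve
from .histories import DiagonalHistory, StressHistory, UniaxialHistory
from .materials import MaterialModel, _pk2_components
from .relaxation import ReducedRelaxation

__all__ = [
    "uniaxial_incompressible_stress",
    "yeoh_uniaxial",
    "mooney_rivlin_uniaxial",
    "ciambella_uniaxial",
    "abaqus_style_uniaxial",
    "qlv_cauchy_tensorial",
    "boltzmann_linear_stress",
]


def _uniaxial_pid(m: MaterialModel, lam: np.ndarray):
    """Axial/lateral deviatoric-split components for isochoric uniaxial stretch.

    Pi_D11 = 2 * (2/3)(W1 + W2/lam)(1 - lam^-3),
    Pi_D22 = 2 * (1/3)(W1 + W2/lam)(1 - lam^3).
    """
    lat = lam ** -0.5
    pi_d, _ = _pk2_components(m, lam, lat, lat)
    return pi_d[..., 0], pi_d[..., 1]


def uniaxial_incompressible_stress(m: MaterialModel, D: ReducedRelaxation,
                                   hist: UniaxialHistory) -> StressHistory:
    """Axial Cauchy stress of an incompressible uniaxial QLV bar.

    Generic path: the pressure is eliminated between the axial and lateral
    normal-stress equations, giving

        T(t) = lam^2(t) [P1(t) + conv(D', P1)] - lam^-1(t) [P2(t) + conv(D', P2)]

    with P1, P2 the axial/lateral components of Pi_D^e.  The lateral
    stress is identically zero by construction.
    """
    if not m.incompressible:
        raise ValueError("uniaxial_incompressible_stress requires an incompressible model")
    lam = hist.lam
    P1, P2 = _uniaxial_pid(m, lam)
    c1 = convolve(D.derivative, hist.times, P1)
    c2 = convolve(D.derivative, hist.times, P2)
    T = lam ** 2 * (P1 + c1) - (P2 + c2) / lam
    return StressHistory(hist.times, T)


def _yeoh_k(alpha: float, lam: np.ndarray) -> np.ndarray:
    return 2.0 * alpha + (1.0 - 3.0 * alpha) * lam + alpha * lam ** 3


def yeoh_uniaxial(alpha: float, D: ReducedRelaxation, hist: UniaxialHistory,
                  mu: float = 1.0) -> StressHistory:
    """Closed-form uniaxial QLV stress for the two-term Yeoh material.

    T/mu = k(t)(lam - lam^-2)
         + int_0^t D'(t-s) k(s) [ lam^2(t) (2/3)(lam^-1(s) - lam^-4(s))
                                  - lam^-1(t) (1/3)(lam^-1(s) - lam^2(s)) ] ds,
    k(t) = 2 alpha + (1 - 3 alpha) lam(t) + alpha lam^3(t).
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    lam = hist.lam
    k = _yeoh_k(alpha, lam)
    axial = k * (2.0 / 3.0) * (lam ** -1 - lam ** -4)
    lateral = k * (1.0 / 3.0) * (lam ** -1 - lam ** 2)
    ca = convolve(D.derivative, hist.times, axial)
    cl = convolve(D.derivative, hist.times, lateral)
    T = mu * (k * (lam - lam ** -2) + lam ** 2 * ca - cl / lam)
    return StressHistory(hist.times, T)


def mooney_rivlin_uniaxial(gamma: float, D: ReducedRelaxation, hist: UniaxialHistory,
                           mu: float = 1.0) -> StressHistory:
    """Closed-form uniaxial QLV stress for the Mooney-Rivlin material.

    T/mu = (1/2) l(t) (lam - lam^-2)
         + (1/6) int_0^t D'(t-s) l(s) [ 2 lam^2(t)(lam^-1(s) - lam^-4(s))
                                        + lam^-1(t)(lam^2(s) - lam^-1(s)) ] ds,
    l(t) = 1 - 2 gamma + lam(t)(1 + 2 gamma).

    The instantaneous term uses l at the current time (the printed source
    formula's l(s) there fails the elastic reduction and the gamma = 1/2
    neo-Hookean equivalence, both of which hold with l(t)).
    """
    if not -0.5 <= gamma <= 0.5:
        raise ValueError("gamma must lie in [-1/2, 1/2]")
    lam = hist.lam
    ell = 1.0 - 2.0 * gamma + lam * (1.0 + 2.0 * gamma)
    axial = ell * 2.0 * (lam ** -1 - lam ** -4)
    lateral = ell * (lam ** 2 - lam ** -1)
    ca = convolve(D.derivative, hist.times, axial)
    cl = convolve(D.derivative, hist.times, lateral)
    T = mu * (0.5 * ell * (lam - lam ** -2) + (lam ** 2 * ca + cl / lam) / 6.0)
    return StressHistory(hist.times, T)


def ciambella_uniaxial(alpha: float, D: ReducedRelaxation, hist: UniaxialHistory,
                       mu: float = 1.0) -> StressHistory:
    """Comparator: the Ciambella et al. QLV variant for the Yeoh material.

    T/mu = (lam(t) - lam^-2(t)) k(t)
         + (lam^2(t) - lam^-1(t)) int_0^t D'(t-s) lam^-1(s) k(s) ds.

    Reproduced exactly as published: the stress returns instantaneously to
    zero whenever lam returns to 1 (the memory defect this package's main
    formulation avoids).  Do not "fix".
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    lam = hist.lam
    k = _yeoh_k(alpha, lam)
    conv = convolve(D.derivative, hist.times, k / lam)
    T = mu * ((lam - lam ** -2) * k + (lam ** 2 - lam ** -1) * conv)
    return StressHistory(hist.times, T)


def abaqus_style_uniaxial(alpha: float, D: ReducedRelaxation, hist: UniaxialHistory,
                          mu: float = 1.0) -> StressHistory:
    """Comparator: convolution of the full instantaneous uniaxial stress.

    T/mu = (lam(t) - lam^-2(t)) k(t)
         + int_0^t D'(t-s) (lam(s) - lam^-2(s)) k(s) ds,

    the heuristic used by the ABAQUS finite-element package.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    lam = hist.lam
    g = (lam - lam ** -2) * _yeoh_k(alpha, lam)
    T = mu * (g + convolve(D.derivative, hist.times, g))
    return StressHistory(hist.times, T)


def qlv_cauchy_tensorial(m: MaterialModel, D: ReducedRelaxation, H: ReducedRelaxation,
                         hist: DiagonalHistory) -> StressHistory:
    """Full diagonal QLV Cauchy stress for a compressible material.

    Both relaxation branches act on their own effective-stress split:
    D'(t-s) convolves Pi_D^e and H'(t-s) convolves Pi_H^e, and the result
    is pushed forward with the current deformation.
    """
    if m.incompressible:
        raise ValueError("the tensorial path requires a compressible model; use "
                         "uniaxial_incompressible_stress for incompressible bars")
    s = hist.stretches
    pi_d, pi_h = _pk2_components(m, s[:, 0], s[:, 1], s[:, 2])
    conv_d = convolve(D.derivative, hist.times, pi_d)
    conv_h = convolve(H.derivative, hist.times, pi_h)
    J = np.prod(s, axis=1)
    diag = s ** 2 / J[:, None] * (pi_d + conv_d + pi_h + conv_h)
    return StressHistory(hist.times, diag[:, 0], diagonal=diag)


def boltzmann_linear_stress(times: np.ndarray, strain: np.ndarray,
                            mu0: float, kappa0: float,
                            mu_relax: ReducedRelaxation,
                            kappa_relax: ReducedRelaxation) -> np.ndarray:
    """Boltzmann linear viscoelastic stress for a small-strain history.

    sigma(t) = 2 mu(0) dev eps(t) + 2 int_0^t mu'(t-s) dev eps(s) ds
             + kappa(0) tr eps(t) I + int_0^t kappa'(t-s) tr eps(s) I ds,

    with mu(t) = mu0 * mu_relax(t) and kappa(t) = kappa0 * kappa_relax(t).
    ``strain`` has shape (N, 3, 3) (or (N, 3), taken as diagonal); the
    stress is returned in the same shape.
    """
    times = np.asarray(times, dtype=float)
    eps = np.asarray(strain, dtype=float)
    diag_in = eps.ndim == 2
    if diag_in:
        full = np.zeros((eps.shape[0], 3, 3))
        full[:, np.arange(3), np.arange(3)] = eps
        eps = full
    if eps.shape != (times.size, 3, 3):
        raise ValueError("strain must have shape (n_nodes, 3, 3) or (n_nodes, 3)")
    tr = np.trace(eps, axis1=1, axis2=2)
    dev = eps - tr[:, None, None] / 3.0 * np.eye(3)
    conv_dev = convolve(mu_relax.derivative, times, dev.reshape(len(times), 9))
    conv_tr = convolve(kappa_relax.derivative, times, tr)
    sigma = (2.0 * mu0 * (dev + conv_dev.reshape(dev.shape))
             + kappa0 * (tr + conv_tr)[:, None, None] * np.eye(3))
    if diag_in:
        return sigma[:, np.arange(3), np.arange(3)]
    return sigma
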