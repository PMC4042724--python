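"""Kinematics and the hyperelastic layer of the QLV model.

This module houses the principal-stretch kinematics (diagonal deformation
gradients, Cauchy-Green invariants), a small catalog of isotropic strain
energy functions (SEFs), and the stress measures built from them: the
elastic Cauchy stress via the response functions, and the split of the
effective elastic stress into the second Piola-Kirchhoff images of its
deviatoric and hydrostatic Cauchy parts.  That split is the quantity the
viscoelastic convolution acts on, so every QLV computation in the package
starts here.

Conventions
-----------
* ``F = diag(l1, l2, l3)`` with all principal stretches positive;
  ``J = l1*l2*l3`` is the volume ratio and ``I3 = J**2``.
* ``W = W(I1, I2, I3)`` with partial derivatives ``Wk = dW/dIk``.
* Every admissible SEF satisfies the natural-state identity
  ``W1(3,3,1) + 2*W2(3,3,1) + W3(3,3,1) = 0`` so that the effective
  stresses vanish in the undeformed state (the causality requirement).
* Stresses carry the units of the shear modulus ``mu``; with the default
  ``mu = 1`` everything is reported in units of mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Stretches",
    "InvariantTriple",
    "MaterialModel",
    "EffectiveStressSplit",
    "LockingError",
    "invariants_from_stretches",
    "incompressible_lateral",
    "sef_partials",
    "response_functions",
    "elastic_cauchy",
    "pk2_split",
    "pk2_split_principal",
    "natural_state_residual",
]

_INCOMPRESSIBLE_MODELS = ("neo-hookean", "yeoh2", "mooney-rivlin")
_COMPRESSIBLE_MODELS = ("horgan-murphy", "gent")
MODEL_NAMES = _INCOMPRESSIBLE_MODELS + _COMPRESSIBLE_MODELS


class LockingError(ValueError):
    """Raised when a Gent material is driven to its extensibility limit."""


@dataclass(frozen=True)
class Stretches:
    """Principal stretches of a diagonal deformation gradient."""

    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        if not (self.l1 > 0 and self.l2 > 0 and self.l3 > 0):
            raise ValueError(f"principal stretches must be positive, got {self}")

    @property
    def J(self) -> float:
        """Volume ratio det F."""
        return self.l1 * self.l2 * self.l3

    def as_array(self) -> np.ndarray:
        return np.array([self.l1, self.l2, self.l3])


@dataclass(frozen=True)
class InvariantTriple:
    """Principal invariants of B = F F^T."""

    I1: float
    I2: float
    I3: float


@dataclass(frozen=True)
class EffectiveStressSplit:
    """Diagonal components of Pi_D^e and Pi_H^e.

    ``pi_d``/``pi_h`` are the second Piola-Kirchhoff images of the
    deviatoric and hydrostatic parts of the effective elastic Cauchy
    stress.  For incompressible materials the hydrostatic part is absorbed
    into the Lagrange-multiplier pressure and ``pi_h`` is ``None``.
    """

    pi_d: np.ndarray
    pi_h: Optional[np.ndarray]


def invariants_from_stretches(s: Stretches) -> InvariantTriple:
    """Principal invariants of B from the principal stretches.

    I1 = sum li^2, I2 = sum of pairwise products li^2 lj^2, I3 = (l1 l2 l3)^2.
    """
    a, b, c = s.l1 ** 2, s.l2 ** 2, s.l3 ** 2
    return InvariantTriple(a + b + c, a * b + b * c + a * c, a * b * c)


def incompressible_lateral(l1: float) -> float:
    """Lateral stretch of an isochoric uniaxial deformation: l2 = l1^(-1/2)."""
    if not l1 > 0:
        raise ValueError(f"axial stretch must be positive, got {l1}")
    return float(l1) ** -0.5


@dataclass(frozen=True)
class MaterialModel:
    """A strain energy function from the catalog, with its parameters.

    Parameters
    ----------
    name:
        One of ``neo-hookean``, ``yeoh2``, ``mooney-rivlin`` (incompressible)
        or ``horgan-murphy``, ``gent`` (compressible).
    mu:
        Infinitesimal shear modulus (stress units, > 0).
    alpha:
        Two-term Yeoh coefficient (dimensionless, >= 0).
    gamma:
        Mooney-Rivlin / Horgan-Murphy coefficient, -1/2 <= gamma <= 1/2.
        ``gamma = 1/2`` recovers the neo-Hookean shear response.
    kappa:
        Bulk stiffness (stress units, > 0; compressible only).  For
        Horgan-Murphy this is the infinitesimal bulk modulus; the Gent
        volumetric well is quartic in (I3 - 1 - log I3) and therefore flat
        to high order at J = 1, so kappa sets only the scale of its wall.
    Jm:
        Gent limiting value of I1 - 3 (dimensionless, > 0).
    """

    name: str
    mu: float = 1.0
    alpha: float = 0.0
    gamma: float = 0.5
    kappa: Optional[float] = None
    Jm: Optional[float] = None
    incompressible: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        object.__setattr__(self, "incompressible", self.name in _INCOMPRESSIBLE_MODELS)
        if self.name == "yeoh2" and self.alpha < 0:
            raise ValueError("yeoh2 requires alpha >= 0")
        if self.name in ("mooney-rivlin", "horgan-murphy") and not -0.5 <= self.gamma <= 0.5:
            raise ValueError("gamma must lie in [-1/2, 1/2]")
        if self.name in _COMPRESSIBLE_MODELS:
            if self.kappa is None or not self.kappa > 0:
                raise ValueError(f"{self.name} requires a positive bulk modulus kappa")
        if self.name == "gent":
            if self.Jm is None or not self.Jm > 0:
                raise ValueError("gent requires Jm > 0")
            # natural-state identity, checked once at construction
            res = natural_state_residual(self)
            if abs(res) > 1e-12 * self.mu:
                raise AssertionError(f"natural-state residual {res} for {self.name}")


def _as_arrays(I1, I2, I3):
    return (np.asarray(I1, dtype=float), np.asarray(I2, dtype=float),
            np.asarray(I3, dtype=float))


def sef_partials(m: MaterialModel, inv: InvariantTriple | tuple):
    """Value and partial derivatives (W, W1, W2, W3) of the SEF.

    Accepts scalar or array invariants.  For incompressible models W3 is
    reported as 0 and never used.  Raises :class:`LockingError` when a Gent
    material reaches its extensibility limit and ``ValueError`` for I3 <= 0.
    """
    if isinstance(inv, InvariantTriple):
        I1, I2, I3 = inv.I1, inv.I2, inv.I3
    else:
        I1, I2, I3 = inv
    I1, I2, I3 = _as_arrays(I1, I2, I3)
    mu = m.mu
    zero = np.zeros(np.broadcast(I1, I2, I3).shape)

    if m.name in ("neo-hookean", "yeoh2"):
        a = 0.0 if m.name == "neo-hookean" else m.alpha
        W = mu / 4.0 * (2.0 * (I1 - 3.0) + a * (I1 - 3.0) ** 2)
        W1 = mu / 2.0 * (1.0 - 3.0 * a + a * I1)
        return W, W1, zero, zero

    if m.name == "mooney-rivlin":
        c1 = mu / 2.0 * (0.5 + m.gamma)
        c2 = mu / 2.0 * (0.5 - m.gamma)
        W = c1 * (I1 - 3.0) + c2 * (I2 - 3.0)
        return W, c1 + zero, c2 + zero, zero

    if np.any(I3 <= 0):
        raise ValueError("I3 must be positive for a compressible model")

    if m.name == "horgan-murphy":
        c1 = mu / 2.0 * (0.5 + m.gamma)
        c2 = mu / 2.0 * (0.5 - m.gamma)
        k = float(m.kappa)
        W = (c1 * (I1 - 3.0 * I3 ** (1.0 / 3.0))
             + c2 * (I2 - 3.0 * I3 ** (2.0 / 3.0))
             + k / 2.0 * (I3 ** 0.5 - 1.0) ** 2)
        W1 = c1 + zero
        W2 = c2 + zero
        W3 = (-c1 * I3 ** (-2.0 / 3.0) - 2.0 * c2 * I3 ** (-1.0 / 3.0)
              + k / 2.0 * (1.0 - I3 ** -0.5))
        return W, W1, W2, W3

    # gent: isochoric-modified limited-extensibility term plus a smooth
    # volumetric well; reduces to the classical Gent form at I3 = 1.
    Jm = float(m.Jm)
    k = float(m.kappa)
    x = (I1 - 3.0 * I3 ** (1.0 / 3.0)) / Jm
    if np.any(x >= 1.0):
        idx = int(np.argmax(np.atleast_1d(x) >= 1.0))
        raise LockingError(
            f"Gent locking limit reached: I1 - 3*I3^(1/3) >= Jm (first at index {idx})")
    v = I3 - 1.0 - np.log(I3)
    W = -mu / 2.0 * Jm * np.log(1.0 - x) + k / 32.0 * v ** 4
    W1 = mu / 2.0 / (1.0 - x)
    W3 = -mu / 2.0 / (1.0 - x) * I3 ** (-2.0 / 3.0) + k / 8.0 * (1.0 - 1.0 / I3) * v ** 3
    return W, W1, zero, W3


def response_functions(m: MaterialModel, inv: InvariantTriple | tuple):
    """Elastic response functions (beta0, beta1, beta_m1) of T^e = b0 I + b1 B + b-1 B^-1.

    beta0 = (2/J)(I2 W2 + I3 W3), beta1 = (2/J) W1, beta_m1 = -2 J W2,
    with J = sqrt(I3).  Compressible models only.
    """
    if m.incompressible:
        raise ValueError("response functions require a compressible model; "
                         "the incompressible stress is determined only up to a pressure")
    if isinstance(inv, InvariantTriple):
        I1, I2, I3 = inv.I1, inv.I2, inv.I3
    else:
        I1, I2, I3 = inv
    I1, I2, I3 = _as_arrays(I1, I2, I3)
    if np.any(I3 <= 0):
        raise ValueError("I3 must be positive")
    _, W1, W2, W3 = sef_partials(m, (I1, I2, I3))
    J = np.sqrt(I3)
    beta0 = 2.0 / J * (I2 * W2 + I3 * W3)
    beta1 = 2.0 / J * W1
    beta_m1 = -2.0 * J * W2
    return beta0, beta1, beta_m1


def elastic_cauchy(m: MaterialModel, s: Stretches) -> np.ndarray:
    """Diagonal elastic Cauchy stress T^e = beta0 I + beta1 B + beta_m1 B^-1.

    For incompressible models the stress is determined only up to the
    Lagrange-multiplier pressure; the deviatoric part of 2 W1 B - 2 W2 B^-1
    is returned (the trace is absorbed into p) and only normal-stress
    differences are meaningful.
    """
    inv = invariants_from_stretches(s)
    B = s.as_array() ** 2
    if m.incompressible:
        if abs(s.J - 1.0) > 1e-8:
            raise ValueError(f"incompressible model requires J = 1, got J = {s.J}")
        _, W1, W2, _ = sef_partials(m, inv)
        T = 2.0 * W1 * B - 2.0 * W2 / B
        return T - np.mean(T)
    beta0, beta1, beta_m1 = response_functions(m, inv)
    return beta0 + beta1 * B + beta_m1 / B


def pk2_split(m: MaterialModel, s: Stretches) -> EffectiveStressSplit:
    """Deviatoric/hydrostatic effective-stress split, in PK2 measure.

    Pi_D^e = 2[ (I2 W2 - I1 W1)/3 C^-1 + W1 I - I3 W2 C^-2 ]
    Pi_H^e = 2( 2 I2 W2/3 + I1 W1/3 + I3 W3 ) C^-1

    evaluated on the diagonal (C = diag(li^2)).  Both parts vanish at the
    identity; for incompressible models ``pi_h`` is ``None`` (absorbed into
    the pressure) and ``pi_d`` takes its isochoric form with I3 = 1.
    """
    pi_d, pi_h = _pk2_components(m, *s.as_array())
    if m.incompressible:
        if abs(s.J - 1.0) > 1e-8:
            raise ValueError(f"incompressible model requires J = 1, got J = {s.J}")
        return EffectiveStressSplit(pi_d, None)
    return EffectiveStressSplit(pi_d, pi_h)


def _pk2_components(m: MaterialModel, l1, l2, l3):
    """Vectorized diagonal Pi_D^e, Pi_H^e for stacked principal stretches.

    Shapes broadcast; returns arrays with a trailing axis of length 3.
    For incompressible models the hydrostatic part is returned as computed
    with W3 = 0 (it is discarded by the public API).
    """
    l = np.stack(np.broadcast_arrays(np.asarray(l1, float),
                                     np.asarray(l2, float),
                                     np.asarray(l3, float)), axis=-1)
    if np.any(l <= 0):
        raise ValueError("principal stretches must be positive")
    C = l ** 2
    a, b, c = C[..., 0], C[..., 1], C[..., 2]
    I1 = a + b + c
    I2 = a * b + b * c + a * c
    I3 = a * b * c
    _, W1, W2, W3 = sef_partials(m, (I1, I2, I3))
    W1, W2, W3 = (x[..., None] for x in (W1, W2, W3))
    I1_, I2_, I3_ = (x[..., None] for x in (I1, I2, I3))
    pi_d = 2.0 * ((I2_ * W2 - I1_ * W1) / 3.0 / C + W1 - I3_ * W2 / C ** 2)
    pi_h = 2.0 * (2.0 * I2_ * W2 / 3.0 + I1_ * W1 / 3.0 + I3_ * W3) / C
    return pi_d, pi_h


def pk2_split_principal(m: MaterialModel, s: Stretches) -> EffectiveStressSplit:
    """The same split via the principal-stretch form of the SEF.

    Pi_Di^e = Wt_i/l_i - (1/(3 l_i^2)) sum_j l_j Wt_j,
    Pi_Hi^e = (1/(3 l_i^2)) sum_j l_j Wt_j,

    with Wt_i = dW~/dl_i obtained by the chain rule from the invariant
    partials.  An independent algebraic route used to cross-check
    :func:`pk2_split`.
    """
    l = s.as_array()
    inv = invariants_from_stretches(s)
    _, W1, W2, W3 = sef_partials(m, inv)
    # dI1/dli = 2 li, dI2/dli = 2 li (I1 - li^2), dI3/dli = 2 I3 / li
    Wt = 2.0 * l * W1 + 2.0 * l * (inv.I1 - l ** 2) * W2 + 2.0 * inv.I3 / l * W3
    sigma = np.sum(l * Wt) / 3.0
    pi_d = Wt / l - sigma / l ** 2
    pi_h = sigma / l ** 2
    if m.incompressible:
        return EffectiveStressSplit(pi_d, None)
    return EffectiveStressSplit(pi_d, pi_h)


def natural_state_residual(m: MaterialModel) -> float:
    """Residual of the natural-state identity W1 + 2 W2 + W3 at (3, 3, 1).

    Zero (to rounding) for every admissible SEF; the hydrostatic effective
    stress vanishes in the undeformed state exactly when this holds.
    """
    if m.incompressible:
        raise ValueError("the natural-state identity involves W3; for "
                         "incompressible models I3 = 1 and only W1, W2 are used")
    _, W1, W2, W3 = sef_partials(m, (3.0, 3.0, 1.0))
    return float(W1 + 2.0 * W2 + W3)
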