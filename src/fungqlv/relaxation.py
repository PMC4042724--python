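"""Reduced relaxation functions as Prony series.

The QLV convolution acts through two scalar reduced relaxation functions:
D(t) for the (deviatoric-origin) shear response and H(t) for the
(hydrostatic-origin) volumetric response, both normalized so that the
value at t = 0 is exactly 1.  An N-term Prony series

    D(t) = g_inf + (1 - g_inf) * sum_i g_i exp(-t / tau_i),   sum_i g_i = 1,

covers the classical one-term case g_inf = mu_inf/mu used throughout the
uniaxial examples, where mu_inf is the long-time infinitesimal shear
modulus and tau the relaxation time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["ReducedRelaxation"]


@dataclass(frozen=True)
class ReducedRelaxation:
    """Normalized Prony-series relaxation function.

    Parameters
    ----------
    long_time_ratio:
        Limit of the function as t -> infinity, in (0, 1].  For the shear
        function D this is mu_inf / mu.
    terms:
        Sequence of ``(g_i, tau_i)`` pairs with weights g_i >= 0 summing to
        1 and relaxation times tau_i > 0 (seconds).  May be empty only when
        ``long_time_ratio == 1`` (the purely elastic, constant function).
    kind:
        Label, conventionally ``"D"`` (shear) or ``"H"`` (bulk).
    """

    long_time_ratio: float
    terms: Tuple[Tuple[float, float], ...] = ()
    kind: str = "D"

    def __post_init__(self) -> None:
        if not 0.0 < self.long_time_ratio <= 1.0:
            raise ValueError("long_time_ratio must lie in (0, 1]")
        terms = tuple((float(g), float(tau)) for g, tau in self.terms)
        object.__setattr__(self, "terms", terms)
        if self.long_time_ratio == 1.0 and not terms:
            return
        if not terms:
            raise ValueError("a relaxing function (long_time_ratio < 1) needs Prony terms")
        if any(g < 0 for g, _ in terms):
            raise ValueError("Prony weights must be nonnegative")
        if any(tau <= 0 for _, tau in terms):
            raise ValueError("relaxation times must be positive")
        total = sum(g for g, _ in terms)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"Prony weights must sum to 1, got {total}")

    @classmethod
    def one_term(cls, long_time_ratio: float, tau: float, kind: str = "D") -> "ReducedRelaxation":
        """Classical one-term series g_inf + (1 - g_inf) exp(-t/tau)."""
        if long_time_ratio == 1.0:
            return cls(1.0, (), kind)
        return cls(long_time_ratio, ((1.0, tau),), kind)

    @classmethod
    def constant(cls, kind: str = "D") -> "ReducedRelaxation":
        """The purely elastic limit, identically 1 (no relaxation)."""
        return cls(1.0, (), kind)

    @property
    def is_constant(self) -> bool:
        return self.long_time_ratio == 1.0

    def __call__(self, t):
        """Evaluate the function; t >= 0 (scalar or array), dimensionless result.

        Evaluated as 1 + (1 - g_inf) sum_i g_i (exp(-t/tau_i) - 1), which is
        algebraically identical (weights sum to 1) and exactly 1 at t = 0.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("relaxation functions are defined for t >= 0")
        out = np.ones(t.shape)
        for g, tau in self.terms:
            out = out + (1.0 - self.long_time_ratio) * g * np.expm1(-t / tau)
        return out if out.shape else float(out)

    def derivative(self, t):
        """Analytic derivative (per second); <= 0 everywhere on t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("relaxation functions are defined for t >= 0")
        out = np.zeros(t.shape)
        for g, tau in self.terms:
            out = out - (1.0 - self.long_time_ratio) * g / tau * np.exp(-t / tau)
        return out if out.shape else float(out)
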