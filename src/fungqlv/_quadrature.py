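"""High-order convolution quadrature on uniform grids.

The hereditary integrals have the form

    c(t_i) = int_0^{t_i} K'(t_i - s) v(s) ds,

with a smooth Prony-series kernel derivative K' and nodal samples of v.
Composite Simpson weights are used (the 3/8 rule covers the first three
intervals when the interval count is odd), which is fourth-order for
smooth integrands.  The single-interval startup integral over [0, h] is
handled by Simpson on [0, h] with the integrand midpoint reconstructed by
quadratic interpolation of v through the first three nodes; this keeps
every kernel argument nonnegative and preserves O(h^4) local accuracy.

These startup choices are what let the Volterra time-steppers built on
top of this module retain their high order from the first step onward.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simpson_weights", "convolve"]

# v(h/2) ~ (3 v0 + 6 v1 - v2) / 8 : quadratic through nodes 0, 1, 2
MIDPOINT_COEFFS = np.array([3.0, 6.0, -1.0]) / 8.0


def simpson_weights(n: int, h: float) -> np.ndarray:
    """Weights over nodes 0..n for int_0^{n h} f ds, composite Simpson.

    n even: plain composite Simpson.  n odd >= 3: Simpson 3/8 on the first
    three intervals, composite Simpson on the rest.  n == 1 falls back to
    the trapezoid (callers wanting full order at the first node use the
    midpoint startup in :func:`convolve` instead).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    w = np.zeros(n + 1)
    if n == 0:
        return w
    if n == 1:
        w[:] = h / 2.0
        return w
    start = 0
    if n % 2 == 1:
        w[0:4] += 3.0 * h / 8.0 * np.array([1.0, 3.0, 3.0, 1.0])
        start = 3
    if n > start:
        m = n - start  # even
        pattern = np.ones(m + 1)
        pattern[1:-1:2] = 4.0
        pattern[2:-1:2] = 2.0
        w[start:] += h / 3.0 * pattern
    return w


def convolve(dkernel, times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Evaluate c(t_i) = int_0^{t_i} K'(t_i - s) v(s) ds at every node.

    Parameters
    ----------
    dkernel:
        Callable evaluating K' on a nonnegative array argument.
    times:
        Uniform grid (N,) starting at 0.
    values:
        Nodal samples of v, shape (N,) or (N, m) (each column convolved).

    Returns an array of the same shape as ``values``.
    """
    times = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    n_nodes = times.size
    squeeze = v.ndim == 1
    if squeeze:
        v = v[:, None]
    if v.shape[0] != n_nodes:
        raise ValueError("values must be sampled on the time grid")
    out = np.zeros_like(v)
    if n_nodes < 2:
        return out[:, 0] if squeeze else out
    h = times[1] - times[0]

    # kernel values K'(j h) for all lags once
    K = np.asarray(dkernel(times - times[0]), dtype=float)

    for i in range(1, n_nodes):
        if i == 1 and n_nodes >= 3:
            vmid = MIDPOINT_COEFFS @ v[:3]
            fmid = dkernel(h / 2.0) * vmid
            out[1] = h / 6.0 * (K[1] * v[0] + 4.0 * fmid + K[0] * v[1])
        else:
            w = simpson_weights(i, h)
            out[i] = (w * K[i::-1]) @ v[: i + 1]
    return out[:, 0] if squeeze else out
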