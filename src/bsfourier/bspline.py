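"""Uniform cubic B-spline basis functions and temporal Fourier design rows.

The motion model blends control-lattice coefficients with the four uniform
cubic B-spline basis polynomials per axis (tensor product, 64 nodes per
query) and a truncated Fourier series in time.  Everything here is pure
numpy and vectorised over query arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cubic_bspline_basis",
    "cubic_bspline_dbasis",
    "basis_weights",
    "dbasis_weights",
    "fourier_design_row",
    "fourier_design_matrix",
]


def basis_weights(u):
    """The four cubic B-spline weights ``(B0, B1, B2, B3)`` at fraction ``u``.

    Vectorised: ``u`` may be any array with values in ``[0, 1]``; the result
    has shape ``(4,) + u.shape``.  The weights are a partition of unity.
    """
    u = np.asarray(u, dtype=float)
    v = 1.0 - u
    return np.stack(
        [
            v * v * v / 6.0,
            (3.0 * u**3 - 6.0 * u**2 + 4.0) / 6.0,
            (-3.0 * u**3 + 3.0 * u**2 + 3.0 * u + 1.0) / 6.0,
            u**3 / 6.0,
        ]
    )


def dbasis_weights(u):
    """First derivatives ``(B0', B1', B2', B3')`` at fraction ``u`` (sum to 0)."""
    u = np.asarray(u, dtype=float)
    v = 1.0 - u
    return np.stack(
        [
            -v * v / 2.0,
            (3.0 * u**2 - 4.0 * u) / 2.0,
            (-3.0 * u**2 + 2.0 * u + 1.0) / 2.0,
            u * u / 2.0,
        ]
    )


def cubic_bspline_basis(u: float) -> np.ndarray:
    """Scalar entry point with the input-domain check ``0 <= u < 1``."""
    u = float(u)
    if not (0.0 <= u < 1.0):
        raise ValueError(f"B-spline fraction must lie in [0, 1), got {u}")
    return basis_weights(u)


def cubic_bspline_dbasis(u: float) -> np.ndarray:
    u = float(u)
    if not (0.0 <= u < 1.0):
        raise ValueError(f"B-spline fraction must lie in [0, 1), got {u}")
    return dbasis_weights(u)


def fourier_design_row(t, n_modes: int, period: float) -> np.ndarray:
    """Temporal basis values ``[cos(2*pi*f*t/P) for f=0..N, sin(...) for f=1..N]``.

    ``t`` may be scalar or an array; the trailing axis of the result has
    length ``2N + 1``.  The ``sin(0)`` column is omitted (identically zero).
    """
    t = np.asarray(t, dtype=float)
    f = np.arange(n_modes + 1, dtype=float)
    ang = 2.0 * np.pi * t[..., None] * f / float(period)
    return np.concatenate([np.cos(ang), np.sin(ang[..., 1:])], axis=-1)


def fourier_design_matrix(frames, n_modes: int, period: float) -> np.ndarray:
    """Design matrix (len(frames) x (2N+1)) for the least-squares Fourier fit."""
    return fourier_design_row(np.asarray(frames, dtype=float), n_modes, period)
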