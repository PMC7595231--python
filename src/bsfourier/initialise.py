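"""First BSF estimate (C^init) from forward-marched trajectories.

Three steps compose: a per-point least-squares Fourier fit of the
trajectories (Moore-Penrose pseudoinverse of the trigonometric design
matrix), recentring of every sample to its temporal mean position (the
0th-order Fourier term), which defines the motion-centred reference frame,
and a per-channel multilevel B-spline approximation of the scattered
Fourier coefficients onto a regular control lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnderdeterminedError
from .bspline import fourier_design_matrix
from .fields import TrajectorySet
from .mlb import mlb_approximate, mlb_grid_size
from .model import BSFModel

__all__ = ["FourierSamples", "fit_fourier", "recenter", "initialise"]

_SVD_CUTOFF = 1e-10


@dataclass
class FourierSamples:
    """Scattered per-point Fourier coefficients with their coordinates.

    ``coords`` (n, 3) are physical mm; before recentring they are the
    frame-0 positions, after recentring each point's temporal mean
    position.  ``coeffs`` has shape (n, 2N+1, 3); ``residual_rms`` is the
    per-point root-mean-square fit residual over frames (mm).
    """

    coords: np.ndarray
    coeffs: np.ndarray
    n_modes: int
    period: float
    residual_rms: np.ndarray
    recentred: bool = False

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("sample coordinates must be finite")
        if self.coeffs.shape[1] != 2 * self.n_modes + 1:
            raise ValueError("one coefficient block of 2N+1 triples per sample")


def fit_fourier(traj: TrajectorySet, n_modes: int, period=None) -> FourierSamples:
    """Least-squares Fourier fit of every trajectory (pseudoinverse solve).

    The design system has one row per frame and ``2N + 1`` trigonometric
    columns; all points and Cartesian axes share the design matrix, so a
    single pseudoinverse (SVD, relative cutoff 1e-10) solves everything.
    Requires ``P >= 2N + 1`` frames.
    """
    if period is None:
        period = traj.period
    P = traj.positions.shape[1]
    if P < 2 * n_modes + 1:
        raise UnderdeterminedError(
            f"{P} frames cannot determine {2 * n_modes + 1} Fourier coefficients"
        )
    if not np.all(np.isfinite(traj.positions)):
        raise ValueError("trajectories must be finite")
    D = fourier_design_matrix(np.arange(P), n_modes, period)
    u, s, vt = np.linalg.svd(D, full_matrices=False)
    if np.any(s < _SVD_CUTOFF * s[0]):
        bad = int(np.argmax(np.abs(vt[np.argmin(s)])))
        f = bad if bad <= n_modes else bad - n_modes
        raise ValueError(f"degenerate frequency mode {f} in the Fourier design")
    pinv = vt.T @ np.diag(1.0 / s) @ u.T
    # positions: (n, P, 3) -> coefficients (n, 2N+1, 3)
    coeffs = np.einsum("cp,npa->nca", pinv, traj.positions)
    fit = np.einsum("pc,nca->npa", D, coeffs)
    resid = fit - traj.positions
    residual_rms = np.sqrt(np.mean(np.sum(resid**2, axis=2), axis=1))
    return FourierSamples(
        coords=traj.positions[:, 0].copy(),
        coeffs=coeffs,
        n_modes=n_modes,
        period=float(period),
        residual_rms=residual_rms,
    )


def recenter(samples: FourierSamples) -> FourierSamples:
    """Re-anchor every sample at its temporal mean position (F_0).

    Coefficients are unchanged; only the coordinate labels move, defining
    the motion-centred BSF reference frame.
    """
    return FourierSamples(
        coords=samples.coeffs[:, 0, :].copy(),
        coeffs=samples.coeffs,
        n_modes=samples.n_modes,
        period=samples.period,
        residual_rms=samples.residual_rms,
        recentred=True,
    )


def _direct_solve(samples: FourierSamples, levels: int, bbox):
    """Direct pseudoinverse solve of the lattice (less stable than MLB;
    kept behind a flag for testing)."""
    from .bspline import basis_weights

    g = mlb_grid_size(levels)
    m = g - 3
    lo, hi = bbox
    extent = np.where(hi - lo > 0, hi - lo, 1.0)
    t = np.clip((samples.coords - lo) / extent, 0, 1) * m
    i = np.minimum(np.floor(t).astype(int), m - 1)
    frac = t - i
    n = len(t)
    W = np.zeros((n, g * g * g))
    w = [basis_weights(frac[:, a]) for a in range(3)]
    rows = np.arange(n)
    for l in range(4):
        for m_ in range(4):
            for k in range(4):
                cols = ((i[:, 0] + l) * g + i[:, 1] + m_) * g + i[:, 2] + k
                W[rows, cols] += w[0][l] * w[1][m_] * w[2][k]
    rhs = samples.coeffs.reshape(n, -1)
    sol, *_ = np.linalg.lstsq(W, rhs, rcond=_SVD_CUTOFF)
    return sol.reshape(g, g, g, samples.coeffs.shape[1], 3), (lo, hi)


def initialise(traj: TrajectorySet, n_modes: int, levels: int,
               method: str = "mlb") -> BSFModel:
    """Compose fit -> recentre -> per-channel MLB into a BSF model (C^init).

    All ``(2N+1) x 3`` coefficient channels are approximated independently
    on a shared lattice whose cells span the recentred samples' bounding
    box plus a one-cell margin.
    """
    samples = recenter(fit_fourier(traj, n_modes))
    return samples_to_model(samples, levels, method=method)


def samples_to_model(samples: FourierSamples, levels: int,
                     method: str = "mlb", bbox=None) -> BSFModel:
    """Approximate scattered Fourier samples onto a regular control lattice."""
    nchan = samples.coeffs.shape[1] * 3
    values = samples.coeffs.reshape(len(samples.coords), nchan)
    if bbox is None:
        # cells span the sample bounding box exactly; the lattice's outer
        # node ring (outside the support region) is the one-cell margin
        lo = samples.coords.min(axis=0)
        hi = samples.coords.max(axis=0)
        hi = np.where(hi - lo > 0, hi, lo + 1.0)
        bbox = (lo, hi)
    if method == "mlb":
        lattice, (lo, hi) = mlb_approximate(samples.coords, values, levels, bbox=bbox)
        lattice = lattice.reshape(lattice.shape[:3] + (samples.coeffs.shape[1], 3))
    elif method == "direct":
        lattice, (lo, hi) = _direct_solve(samples, levels, bbox)
    else:
        raise ValueError(f"unknown initialisation method {method!r}")
    m = lattice.shape[0] - 3
    extent = np.where(hi - lo > 0, hi - lo, 1.0)
    spacing = extent / m
    origin = lo - spacing  # reference coordinate 1 maps to `lo`
    return BSFModel(lattice, spacing, origin, samples.period, samples.n_modes)
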