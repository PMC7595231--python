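"""Multilevel B-spline (MLB) scattered-data approximation.

Fits a tensor-product uniform cubic B-spline surface to scattered samples
by a coarse-to-fine hierarchy of control grids.  Each level applies the
B-spline approximation (BA) step -- every control node receives the
weighted least-norm value explained by nearby samples -- to the residuals
left by the previous levels, and the accumulated surface is carried to the
next level by exact cubic-B-spline subdivision (one coarse surface is
representable on the doubled grid, so the hierarchy sums losslessly).

Grid-size rule: level ``h`` has ``2**h`` cells and ``2**h + 3`` control
nodes per axis (a single-cell seed grid at level 0; node count doubles per
level with 3 extra nodes at the final level).
"""

from __future__ import annotations

import numpy as np

from .bspline import basis_weights

__all__ = ["mlb_grid_size", "mlb_approximate", "mlb_evaluate", "refine_lattice"]


def mlb_grid_size(levels: int) -> int:
    """Control points per axis after ``levels`` refinements: ``2**levels + 3``."""
    levels = int(levels)
    if levels < 0:
        raise ValueError(f"levels must be nonnegative, got {levels}")
    return 2**levels + 3


def _cell_coords(coords01: np.ndarray, m: int):
    """Map unit-cube coordinates to (base node index, fraction) on an m-cell grid."""
    t = np.clip(coords01, 0.0, 1.0) * m
    i = np.minimum(np.floor(t).astype(int), m - 1)
    return i, t - i


def _tensor_weights(frac: np.ndarray):
    """(n, 64) tensor-product weights and per-axis node offsets."""
    w = [basis_weights(frac[:, a]) for a in range(3)]  # each (4, n)
    n = frac.shape[0]
    out = np.empty((n, 64))
    offs = np.empty((64, 3), dtype=int)
    c = 0
    for l in range(4):
        for m_ in range(4):
            for k in range(4):
                out[:, c] = w[0][l] * w[1][m_] * w[2][k]
                offs[c] = (l, m_, k)
                c += 1
    return out, offs


def _ba_level(coords01, values, m):
    """One BA step: least-norm control coefficients on an m-cell grid."""
    g = m + 3
    i, frac = _cell_coords(coords01, m)
    w, offs = _tensor_weights(frac)  # (n, 64), (64, 3)
    sw2 = np.sum(w * w, axis=1)  # (n,)
    # per-sample least-norm node values phi_b = w_b v / sum(w^2)
    nchan = values.shape[1]
    num = np.zeros((g * g * g, nchan))
    den = np.zeros(g * g * g)
    node = (i[:, None, :] + offs[None, :, :])  # (n, 64, 3)
    flat = (node[..., 0] * g + node[..., 1]) * g + node[..., 2]
    contrib = w[..., None] ** 2 * (w[..., None] * values[:, None, :] / sw2[:, None, None])
    np.add.at(num, flat.ravel(), contrib.reshape(-1, nchan))
    np.add.at(den, flat.ravel(), (w * w).ravel())
    lat = np.zeros((g * g * g, nchan))
    nz = den > 0
    lat[nz] = num[nz] / den[nz, None]
    return lat.reshape(g, g, g, nchan)


def mlb_evaluate(lattice, coords01):
    """Evaluate a (g, g, g, c) lattice at unit-cube coordinates (n, 3)."""
    g = lattice.shape[0]
    m = g - 3
    i, frac = _cell_coords(np.asarray(coords01, dtype=float), m)
    w, offs = _tensor_weights(frac)
    out = np.zeros((coords01.shape[0], lattice.shape[3]))
    for c in range(64):
        l, m_, k = offs[c]
        out += w[:, c, None] * lattice[i[:, 0] + l, i[:, 1] + m_, i[:, 2] + k]
    return out


def _refine_axis(lat, axis):
    """Exact cubic-B-spline subdivision along one axis: m cells -> 2m cells."""
    lat = np.moveaxis(lat, axis, 0)
    n = lat.shape[0]  # m + 3
    m = n - 3
    out = np.empty((2 * m + 3,) + lat.shape[1:])
    # fine node 2j-1 sits on coarse node j; fine node 2j sits on the midpoint
    j = np.arange(1, m + 2)
    out[2 * j - 1] = (lat[j - 1] + 6.0 * lat[j] + lat[j + 1]) / 8.0
    j = np.arange(0, m + 2)
    out[2 * j] = (lat[j] + lat[j + 1]) / 2.0
    return np.moveaxis(out, 0, axis)


def refine_lattice(lat):
    """Represent a coarse 3D lattice exactly on the doubled grid."""
    for axis in range(3):
        lat = _refine_axis(lat, axis)
    return lat


def mlb_approximate(coords, values, levels: int, bbox=None):
    """Fit scattered ``values`` at physical ``coords`` with the MLB hierarchy.

    Parameters
    ----------
    coords : (n, 3) sample positions.
    values : (n,) or (n, c) sample values; channels are fitted jointly
        (identical weights, independent right-hand sides).
    levels : final refinement level; the returned lattice has
        ``2**levels + 3`` nodes per axis.
    bbox : optional (lo, hi) pair of 3-vectors.  Defaults to the sample
        bounding box padded by one final-level cell per side.

    Returns
    -------
    lattice : (g, g, g, c) control coefficients.
    (lo, hi) : the physical box mapped onto the lattice's cell span.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if coords.shape[0] == 0:
        raise ValueError("mlb_approximate requires at least one sample")
    levels = int(levels)
    if levels < 0:
        raise ValueError("levels must be nonnegative")
    m_final = 2**levels
    if bbox is None:
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        extent = np.where(hi - lo > 0, hi - lo, 1.0)
        pad = extent / m_final
        lo, hi = lo - pad, hi + pad
    else:
        lo = np.asarray(bbox[0], dtype=float)
        hi = np.asarray(bbox[1], dtype=float)
    extent = hi - lo
    extent = np.where(extent > 0, extent, 1.0)
    coords01 = (coords - lo) / extent

    # Affine baseline, exactly representable on any lattice (B-splines
    # reproduce linear functions); makes constant/linear data exact even at
    # nodes with no nearby samples.
    design = np.column_stack([np.ones(len(coords01)), coords01])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    detrended = values - design @ beta

    residual = detrended.copy()
    lattice = None
    for h in range(levels + 1):
        m = 2**h
        phi = _ba_level(coords01, residual, m)
        lattice = phi if lattice is None else refine_lattice(lattice) + phi
        residual = detrended - mlb_evaluate(lattice, coords01)

    g = m_final + 3
    node01 = (np.arange(g, dtype=float) - 1.0) / m_final
    nx, ny, nz = np.meshgrid(node01, node01, node01, indexing="ij")
    node_design = np.column_stack(
        [np.ones(g**3), nx.ravel(), ny.ravel(), nz.ravel()]
    )
    lattice = lattice + (node_design @ beta).reshape(g, g, g, -1)
    return lattice, (lo, hi)
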