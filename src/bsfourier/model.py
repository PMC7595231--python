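"""The B-splines-of-Fourier (BSF) motion model.

A BSF model describes a cyclic motion field: the position of a material
point over one cardiac cycle is a truncated Fourier series in time,

    X(t) = sum_f F_f cos(2 pi f t / P) + F_{N+f} sin(2 pi f t / P),

whose coefficient triples ``F_f`` vary over space as a tensor-product
uniform cubic B-spline of a regular control lattice ``C[i, j, k, f]``.
Space is parameterised in the *reference domain*: lattice units in which
control nodes sit at integer coordinates, linked to physical millimetres by
a diagonal affine (per-axis spacing + origin).  The reference frame is
anchored at each point's temporal mean position (the 0th-order Fourier
term), i.e. the model's output at any time is an absolute physical
position, not a displacement.

Frequency-slot layout: ``2N + 1`` slots per node -- cosines for f = 0..N
followed by sines for f = 1..N.  The identically-zero sin(0) slot is not
stored, which keeps every least-squares design matrix full rank.

The valid query region is ``[1, G - 2]`` per axis (G = nodes per axis),
where a full 4x4x4 control-node support exists.  Queries within half a
cell beyond that are clamped (padded-lattice convention); anything farther
raises :class:`~bsfourier.errors.BoundaryError`.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .bspline import basis_weights, dbasis_weights, fourier_design_row
from .errors import BoundaryError

__all__ = ["BSFModel", "fourier_coeffs_at", "evaluate_model", "jacobian_det"]

_CLAMP_MARGIN = 0.5  # half a cell, in lattice units


@dataclass
class BSFModel:
    """Control lattice plus geometry of the BSF motion model.

    Parameters
    ----------
    lattice : ndarray, shape (Gx, Gy, Gz, 2N+1, 3)
        Fourier coefficient triples (mm) at every control node.
    spacing : ndarray, shape (3,)
        Physical extent (mm) of one lattice cell per axis.
    origin : ndarray, shape (3,)
        Physical position (mm) of reference coordinate 0.
    period : float
        Cycle period P, in frames (frame P coincides with frame 0).
    n_modes : int
        Number of Fourier frequency modes N.
    """

    lattice: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    period: float
    n_modes: int

    def __post_init__(self):
        self.lattice = np.ascontiguousarray(self.lattice, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.period = float(self.period)
        self.n_modes = int(self.n_modes)
        if self.lattice.ndim != 5:
            raise ValueError("lattice must have shape (Gx, Gy, Gz, 2N+1, 3)")
        if self.lattice.shape[3] != 2 * self.n_modes + 1:
            raise ValueError(
                f"lattice has {self.lattice.shape[3]} frequency slots, "
                f"expected 2N+1 = {2 * self.n_modes + 1}"
            )
        if self.lattice.shape[4] != 3:
            raise ValueError("lattice must carry coefficient triples")
        if min(self.lattice.shape[:3]) < 4:
            raise ValueError("cubic B-spline support needs >= 4 nodes per axis")
        if self.period <= 0:
            raise ValueError("period must be positive")

    # ------------------------------------------------------------------
    # geometry helpers
    # ------------------------------------------------------------------
    @property
    def grid_shape(self) -> tuple:
        return self.lattice.shape[:3]

    @property
    def support_bounds(self) -> np.ndarray:
        """(2, 3) array of [lo, hi] valid reference coordinates per axis."""
        hi = np.asarray(self.grid_shape, dtype=float) - 2.0
        return np.stack([np.ones(3), hi])

    def ref_to_physical(self, refs) -> np.ndarray:
        refs = np.asarray(refs, dtype=float)
        return self.origin + refs * self.spacing

    def physical_to_ref(self, pos) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        return (pos - self.origin) / self.spacing

    def node_ref_coords(self, interior: bool = True) -> np.ndarray:
        """Reference coordinates of control nodes, flattened to (n, 3).

        With ``interior=True`` only nodes inside the support region are
        returned (lattice coordinates 1 .. G-2 per axis).
        """
        gx, gy, gz = self.grid_shape
        if interior:
            ax = [np.arange(1, g - 1, dtype=float) for g in (gx, gy, gz)]
        else:
            ax = [np.arange(g, dtype=float) for g in (gx, gy, gz)]
        grid = np.meshgrid(*ax, indexing="ij")
        return np.stack([g.ravel() for g in grid], axis=-1)

    def _prepare(self, refs):
        """Validate/clamp reference queries; return (base indices, fractions)."""
        refs = np.atleast_2d(np.asarray(refs, dtype=float))
        lo, hi = self.support_bounds
        bad = (refs < lo - _CLAMP_MARGIN) | (refs > hi + _CLAMP_MARGIN)
        if np.any(bad):
            idx = np.argwhere(bad)[0, 0]
            raise BoundaryError(refs[idx].tolist(), self.support_bounds.tolist())
        refs = np.clip(refs, lo, hi)
        t = refs - 1.0
        m = np.asarray(self.grid_shape) - 3  # cells per axis
        i = np.minimum(np.floor(t), m - 1).astype(int)
        frac = t - i
        return i, frac

    # ------------------------------------------------------------------
    # evaluation
    # ------------------------------------------------------------------
    def fourier_coeffs(self, refs, deriv: bool = False):
        """Blend the control lattice at reference points.

        Returns ``F`` of shape (n, 2N+1, 3); with ``deriv=True`` also the
        spatial derivative ``dF`` of shape (n, 3, 2N+1, 3) (axis 1 = the
        reference axis of differentiation, in lattice units).
        """
        i, frac = self._prepare(refs)
        w = [basis_weights(frac[:, a]) for a in range(3)]  # each (4, n)
        n = frac.shape[0]
        nf = self.lattice.shape[3]
        F = np.zeros((n, nf, 3))
        dF = np.zeros((n, 3, nf, 3)) if deriv else None
        dw = [dbasis_weights(frac[:, a]) for a in range(3)] if deriv else None
        lat = self.lattice
        ix, iy, iz = i[:, 0], i[:, 1], i[:, 2]
        for l in range(4):
            for m_ in range(4):
                wxy = w[0][l] * w[1][m_]
                for k in range(4):
                    node = lat[ix + l, iy + m_, iz + k]  # (n, 2N+1, 3)
                    wt = wxy * w[2][k]
                    F += wt[:, None, None] * node
                    if deriv:
                        dF[:, 0] += (dw[0][l] * w[1][m_] * w[2][k])[:, None, None] * node
                        dF[:, 1] += (w[0][l] * dw[1][m_] * w[2][k])[:, None, None] * node
                        dF[:, 2] += (wxy * dw[2][k])[:, None, None] * node
        return (F, dF) if deriv else F

    def evaluate(self, refs, t, deriv: bool = False):
        """Physical positions (mm) of reference points at time ``t``.

        ``refs`` is (n, 3) (a single triple is promoted); ``t`` is a scalar
        frame value or an (n,) array, wrapped modulo the period.  With
        ``deriv=True`` the spatial Jacobian d X / d X_ref (n, 3, 3) is also
        returned (derivatives w.r.t. lattice-unit reference coordinates).
        """
        squeeze = np.asarray(refs, dtype=float).ndim == 1
        out = self.fourier_coeffs(refs, deriv=deriv)
        F, dF = out if deriv else (out, None)
        tau = fourier_design_row(np.asarray(t, dtype=float), self.n_modes, self.period)
        if tau.ndim == 1:
            pos = np.einsum("p,npa->na", tau, F)
            jac = np.einsum("p,nbpa->nab", tau, dF) if deriv else None
        else:
            pos = np.einsum("np,npa->na", tau, F)
            jac = np.einsum("np,nbpa->nab", tau, dF) if deriv else None
        if squeeze:
            pos = pos[0]
            jac = jac[0] if deriv else None
        return (pos, jac) if deriv else pos

    def jacobian(self, refs, t) -> np.ndarray:
        return self.evaluate(refs, t, deriv=True)[1]

    def jacobian_det(self, refs, t) -> np.ndarray:
        """det(d X / d X_ref) at reference points and time ``t``."""
        return np.linalg.det(self.jacobian(refs, t))

    # ------------------------------------------------------------------
    # misc
    # ------------------------------------------------------------------
    def copy(self) -> "BSFModel":
        return BSFModel(
            self.lattice.copy(),
            self.spacing.copy(),
            self.origin.copy(),
            self.period,
            self.n_modes,
        )

    def save(self, path) -> None:
        """Write the model as a single archive (lattice + JSON header)."""
        header = {
            "format": "bsf-model",
            "version": 1,
            "grid_shape": [int(g) for g in self.grid_shape],
            "n_modes": self.n_modes,
            "period": self.period,
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            zf.writestr("header.json", json.dumps(header, indent=1))
            for name, arr in (
                ("lattice", self.lattice),
                ("spacing", self.spacing),
                ("origin", self.origin),
            ):
                buf = io.BytesIO()
                np.save(buf, arr)
                zf.writestr(name + ".npy", buf.getvalue())

    @classmethod
    def load(cls, path) -> "BSFModel":
        with zipfile.ZipFile(path, "r") as zf:
            header = json.loads(zf.read("header.json"))
            if header.get("format") != "bsf-model":
                raise ValueError(f"{path} is not a BSF model archive")
            arrays = {
                name: np.load(io.BytesIO(zf.read(name + ".npy")))
                for name in ("lattice", "spacing", "origin")
            }
        return cls(
            arrays["lattice"],
            arrays["spacing"],
            arrays["origin"],
            header["period"],
            header["n_modes"],
        )


# ----------------------------------------------------------------------
# functional wrappers (spec-level operation names)
# ----------------------------------------------------------------------
def fourier_coeffs_at(model: BSFModel, x) -> np.ndarray:
    """(2N+1, 3) Fourier coefficient triples at one reference point."""
    return model.fourier_coeffs(np.asarray(x, dtype=float)[None, :])[0]


def evaluate_model(model: BSFModel, x, t):
    """Physical position (mm) of reference point ``x`` at time ``t``."""
    return model.evaluate(x, t)


def jacobian_det(model: BSFModel, x, t) -> float:
    """det of the spatial Jacobian at one reference point and time."""
    return float(model.jacobian_det(np.asarray(x, dtype=float)[None, :], t)[0])
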