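"""Consistency correction: optimising the model against all pairwise fields.

The initialised model is fitted to the marched trajectories only; at the
positions the model itself predicts, the registration fields prescribe
displacements the model may disagree with.  The correction minimises, at
every sample point (control-node reference positions by default),

    sum_fields || w * ((X_BSF(t+dt) - X_BSF(t)) - dX(X_BSF(t))) ||^2 / 2

over that sample's Fourier coefficient block with Levenberg-Marquardt
(the blocks are independent, so the optimisation is node-by-node), then
rebuilds the control lattice from the optimised blocks by a pseudoinverse
solve of the B-spline blending system.  Each field is sampled at the
model-predicted position of its source frame.  By default only the
neighbour-chain fields with uniform weight participate; arbitrary extra
weighted fields (e.g. an end-diastole to end-systole boundary constraint)
are included simply by appending them to the registration set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._lm import LMParams, LMResult, lm_minimise
from .bspline import basis_weights, fourier_design_row
from .errors import ConfigurationError
from .fields import DisplacementField, RegistrationSet
from .model import BSFModel

__all__ = [
    "consistency_cost",
    "optimise_node",
    "consistency_correct",
    "build_boundary_constraint",
    "CorrectionReport",
]

_SVD_CUTOFF = 1e-10


def neighbour_fields(reg) -> list:
    """The neighbour-chain subset of a registration set (the default input
    to the correction, per the uniform-weight neighbouring-pairs default)."""
    return [f for f in reg
            if f.role == "neighbour"
            or (f.role is None and f.t_to == f.t_from + 1)]


def _select_fields(reg, fields):
    if fields == "neighbours":
        out = neighbour_fields(reg)
    elif fields == "all":
        out = list(reg)
    else:
        out = list(fields)
    if not out:
        raise ConfigurationError("no displacement fields selected")
    return out


def _shared_family(fields):
    """A common exact-sampler backend shared by every field, if any.

    Synthetic exactly-consistent fields expose the generator through a
    ``family`` attribute; sampling all fields in one batched call is then
    much cheaper than looping per field.
    """
    fams = {id(getattr(f, "family", None)) for f in fields}
    fam = getattr(fields[0], "family", None)
    return fam if len(fams) == 1 and fam is not None else None


class _NodeProblem:
    """Residuals/Jacobian of the consistency cost for one free coefficient
    block; all other quantities (the fields) are fixed."""

    def __init__(self, fields, period: float, n_modes: int,
                 anchor: float = 0.0, barrier: float = 10.0):
        self.fields = list(fields)
        self.n_modes = n_modes
        self.nc = 2 * n_modes + 1
        self.anchor = float(anchor)
        self.F_anchor = None  # flat reference block, set per node
        self.barrier = float(barrier)
        self.dom_lo = np.stack([f.physical_bounds[0] for f in self.fields])
        self.dom_hi = np.stack([f.physical_bounds[1] for f in self.fields])
        t_from = np.array([f.t_from for f in self.fields], dtype=float)
        t_to = np.array([f.t_to for f in self.fields], dtype=float)
        self.t_from = t_from
        self.t_to = t_to
        self.w = np.array([f.weight for f in self.fields], dtype=float)
        self.tau_from = fourier_design_row(t_from, n_modes, period)
        self.tau_to = fourier_design_row(t_to, n_modes, period)
        self.family = _shared_family(self.fields)
        self._warm = None  # last inverse-map solution (batched warm start)
        self._stack = None
        if self.family is None and all(f.exact_fn is None for f in self.fields):
            self._stack = np.stack([f.vectors for f in self.fields])
            f0 = self.fields[0]
            self._spacing = f0.spacing
            self._origin = f0.origin

    def reset_warm_start(self):
        self._warm = None

    def _stack_sample(self, x):
        """Trilinear sample of field i at x[i] for all fields at once."""
        shape = np.asarray(self._stack.shape[1:4])
        idx = np.clip((x - self._origin) / self._spacing, 0.0, shape - 1.0)
        i0 = np.minimum(np.floor(idx).astype(int), shape - 2)
        f = idx - i0
        rows = np.arange(len(self.fields))
        out = np.zeros((len(self.fields), 3))
        for dx in (0, 1):
            wx = f[:, 0] if dx else 1.0 - f[:, 0]
            for dy in (0, 1):
                wxy = wx * (f[:, 1] if dy else 1.0 - f[:, 1])
                for dz in (0, 1):
                    w = wxy * (f[:, 2] if dz else 1.0 - f[:, 2])
                    out += w[:, None] * self._stack[
                        rows, i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        return out

    def _positions(self, F):
        Fm = F.reshape(self.nc, 3)
        return self.tau_from @ Fm, self.tau_to @ Fm

    def _sample(self, x_from):
        if self.family is not None:
            d, ref = self.family.displacement(
                x_from, self.t_from, self.t_to, ref0=self._warm,
                return_ref=True)
            self._warm = ref
            return d
        if self._stack is not None:
            return self._stack_sample(x_from)
        return np.stack([f.sample(x) for f, x in zip(self.fields, x_from)])

    def _sample_jac(self, x_from):
        if self.family is not None:
            return self.family.displacement_jacobian(
                x_from, self.t_from, self.t_to, ref0=self._warm)
        if self._stack is not None:
            jac = np.empty((len(self.fields), 3, 3))
            for a in range(3):
                e = np.zeros(3)
                e[a] = 0.5 * self._spacing[a]
                jac[:, :, a] = (self._stack_sample(x_from + e)
                                - self._stack_sample(x_from - e)) / (2 * e[a])
            return jac
        return np.stack(
            [f.sample_jacobian(x[None, :])[0]
             for f, x in zip(self.fields, x_from)]
        )

    @property
    def _anchor_scale(self) -> float:
        # scaling with ||w||_2 keeps the anchored argmin invariant under a
        # uniform rescaling of all field weights
        return self.anchor * float(np.linalg.norm(self.w))

    def _excess(self, x):
        """Per-axis distance by which positions leave their field's domain."""
        return (np.maximum(self.dom_lo - x, 0.0)
                - np.maximum(x - self.dom_hi, 0.0))

    def residual(self, F):
        x_from, x_to = self._positions(F)
        d = self._sample(x_from)
        rows = (self.w[:, None] * ((x_to - x_from) - d)).ravel()
        if self.barrier > 0.0:
            wb = (self.barrier * self.w)[:, None]
            rows = np.concatenate([
                rows,
                (wb * self._excess(x_from)).ravel(),
                (wb * self._excess(x_to)).ravel(),
            ])
        if self.anchor > 0.0 and self.F_anchor is not None:
            rows = np.concatenate(
                [rows, self._anchor_scale * (F - self.F_anchor)])
        return rows

    def jac(self, F):
        x_from, _ = self._positions(F)
        G = self._sample_jac(x_from)  # (nf, 3, 3)
        nf = len(self.fields)
        J = np.zeros((nf, 3, self.nc, 3))
        dtau = self.tau_to - self.tau_from  # (nf, nc)
        eye = np.eye(3)
        J += self.w[:, None, None, None] * (
            dtau[:, None, :, None] * eye[None, :, None, :]
            - G[:, :, None, :] * self.tau_from[:, None, :, None]
        )
        J = J.reshape(nf * 3, self.nc * 3)
        if self.barrier > 0.0:
            x_from, x_to = self._positions(F)
            wb = self.barrier * self.w
            blocks = []
            for x, tau in ((x_from, self.tau_from), (x_to, self.tau_to)):
                # d excess / d x = -1 below the domain, +1 above, 0 inside
                sgn = -(x < self.dom_lo).astype(float) \
                    - (x > self.dom_hi).astype(float)
                Jb = (wb[:, None, None, None] * sgn[:, :, None, None]
                      * tau[:, None, :, None] * eye[None, :, None, :])
                blocks.append(Jb.reshape(nf * 3, self.nc * 3))
            J = np.vstack([J] + blocks)
        if self.anchor > 0.0 and self.F_anchor is not None:
            J = np.vstack([J, self._anchor_scale * np.eye(self.nc * 3)])
        return J

    def jac_fd(self, F, h: float = 1e-6):
        """Finite-difference Jacobian (cross-check path)."""
        r0 = self.residual(F)
        J = np.empty((len(r0), len(F)))
        for p in range(len(F)):
            e = np.zeros(len(F))
            e[p] = h
            J[:, p] = (self.residual(F + e) - self.residual(F - e)) / (2 * h)
        return J


def consistency_cost(model: BSFModel, reg, samples=None,
                     fields: str = "neighbours") -> float:
    """Total weighted half-sum-of-squares disparity between the model's
    frame-to-frame motion and the registration fields, over all samples.

    ``fields`` selects which members of ``reg`` participate:
    ``"neighbours"`` (default, the uniform-weight neighbour chain),
    ``"all"``, or an explicit list of fields.
    """
    if samples is None:
        samples = model.node_ref_coords(interior=True)
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 0:
        raise ValueError("consistency cost needs at least one sample point")
    cost = 0.0
    for f in _select_fields(reg, fields):
        x_from = model.evaluate(samples, float(f.t_from))
        x_to = model.evaluate(samples, float(f.t_to))
        d = f.sample(x_from)
        r = f.weight * ((x_to - x_from) - d)
        cost += 0.5 * float(np.sum(r * r))
    return cost


def optimise_node(F, reg, period, n_modes=None, lm_params: LMParams | None = None,
                  jac: str = "analytic", fields="all",
                  anchor: float = 0.0, barrier: float = 10.0) -> LMResult:
    """Optimise one sample's coefficient block against the field set.

    ``F`` is the (2N+1, 3) block (or its flattening); the block is the only
    free variable -- its Fourier series predicts the sample's trajectory,
    at which every field is sampled.  Returns the LM result with the
    optimised block in ``.x`` (same shape as the input), final cost
    ``.cost`` (sum of squares; half of it is the consistency cost), iteration
    count and a convergence flag (False means max-iterations reached).
    """
    F = np.asarray(F, dtype=float)
    shape = F.shape
    if n_modes is None:
        n = (F.size // 3 - 1) // 2
    else:
        n = n_modes
    selected = _select_fields(reg, fields)
    prob = _NodeProblem(selected, float(period), n, anchor=anchor,
                        barrier=barrier)
    prob.F_anchor = F.ravel().copy()
    jac_fn = prob.jac if jac == "analytic" else prob.jac_fd
    res = lm_minimise(prob.residual, jac_fn, F.ravel(),
                      lm_params or LMParams())
    res.x = res.x.reshape(shape)
    return res


def _barrier_cost(model, fields, samples, barrier: float) -> float:
    """Half-sum-of-squares of the domain-excess barrier rows (0 when all
    model-predicted sample positions stay inside the field domains)."""
    if barrier <= 0.0:
        return 0.0
    total = 0.0
    for f in fields:
        lo, hi = f.physical_bounds
        for t in (float(f.t_from), float(f.t_to)):
            x = model.evaluate(samples, t)
            excess = np.maximum(lo - x, 0.0) + np.maximum(x - hi, 0.0)
            total += 0.5 * float(np.sum((barrier * f.weight * excess) ** 2))
    return total


@dataclass
class CorrectionReport:
    cost_before: float
    cost_after: float
    n_nodes: int
    n_not_converged: int
    sweeps: int


def _blend_matrix(model: BSFModel, samples: np.ndarray) -> np.ndarray:
    """Dense (n_samples x n_nodes) cubic B-spline blending matrix."""
    gx, gy, gz = model.grid_shape
    m = np.asarray(model.grid_shape) - 3
    t = samples - 1.0
    i = np.minimum(np.floor(t), m - 1).astype(int)
    frac = t - i
    w = [basis_weights(frac[:, a]) for a in range(3)]
    n = samples.shape[0]
    W = np.zeros((n, gx * gy * gz))
    rows = np.arange(n)
    for l in range(4):
        for m_ in range(4):
            for k in range(4):
                cols = ((i[:, 0] + l) * gy + i[:, 1] + m_) * gz + i[:, 2] + k
                W[rows, cols] += w[0][l] * w[1][m_] * w[2][k]
    return W


def consistency_correct(model: BSFModel, reg,
                        lm_params: LMParams | None = None, sweeps: int = 1,
                        samples=None, jac: str = "analytic",
                        fields: str = "neighbours", anchor: float = 0.0,
                        barrier: float = 10.0):
    """Node-by-node correction of the whole model.

    Optimises the coefficient block at every sample point (default: all
    interior control-node reference positions, matching the node-by-node
    formulation), then solves the blending system for the control lattice
    by a minimum-norm *update* relative to the current lattice (SVD cutoff
    1e-10), keeping weakly-constrained boundary nodes at their initialised
    values.  The consistency cost at the samples never increases.

    Returns ``(corrected_model, CorrectionReport)``.
    """
    if samples is None:
        samples = model.node_ref_coords(interior=True)
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    selected = _select_fields(reg, fields)
    current = model.copy()
    cost_before = consistency_cost(current, selected, samples, fields="all")
    barrier_before = _barrier_cost(current, selected, samples, barrier)
    n_bad = 0
    prob = _NodeProblem(selected, current.period, current.n_modes,
                        anchor=anchor, barrier=barrier)
    jac_fn = prob.jac if jac == "analytic" else prob.jac_fd
    for _ in range(int(sweeps)):
        F_all = current.fourier_coeffs(samples)  # (n, 2N+1, 3)
        F_star = np.empty_like(F_all)
        for idx in range(samples.shape[0]):  # raster order over nodes
            prob.reset_warm_start()
            prob.F_anchor = F_all[idx].ravel().copy()
            res = lm_minimise(prob.residual, jac_fn, F_all[idx].ravel(),
                              lm_params or LMParams())
            if not res.converged:
                n_bad += 1
            F_star[idx] = res.x.reshape(F_all[idx].shape)
        W = _blend_matrix(current, samples)
        nchan = F_all.shape[1] * 3
        c_flat = current.lattice.reshape(-1, nchan)
        rhs = F_star.reshape(-1, nchan) - W @ c_flat
        delta, *_ = np.linalg.lstsq(W, rhs, rcond=_SVD_CUTOFF)
        c_flat = c_flat + delta
        current = BSFModel(
            c_flat.reshape(current.lattice.shape),
            current.spacing, current.origin, current.period, current.n_modes,
        )
    cost_after = consistency_cost(current, selected, samples, fields="all")
    if barrier_before > 0.0:
        # the initial model already leaves the data domain somewhere: only
        # the barrier-augmented objective is guaranteed non-increasing
        cost_after_full = cost_after + _barrier_cost(current, selected,
                                                     samples, barrier)
        cost_before_full = cost_before + barrier_before
    else:
        cost_after_full, cost_before_full = cost_after, cost_before
    if cost_after_full > cost_before_full * (1 + 1e-9) + 1e-12:
        raise RuntimeError(
            f"consistency cost increased: {cost_before:.6e} -> {cost_after:.6e}"
        )
    report = CorrectionReport(
        cost_before=cost_before, cost_after=cost_after,
        n_nodes=samples.shape[0] * int(sweeps), n_not_converged=n_bad,
        sweeps=int(sweeps),
    )
    return current, report


def build_boundary_constraint(mask_ed, mask_es, register, t_ed: int, t_es: int,
                              weight: float = 10.0, spacing=(1.0, 1.0, 1.0),
                              origin=(0.0, 0.0, 0.0)) -> DisplacementField:
    """Extra displacement field between end-diastole and end-systole masks.

    Both masks are binarised, smoothed with a 9x9x9 Gaussian kernel of
    standard deviation 2 voxels per axis (soft edges), and handed to the
    supplied pairwise-registration callback ``register(moving, fixed)``
    which must return an (nx, ny, nz, 3) displacement array (mm).  The
    returned field is labelled (t_ed -> t_es) with the given weight --
    default 10x the uniform neighbour-field weight -- so that the
    correction emphasises the stroke-volume extremes.
    """
    a = (np.asarray(mask_ed) > 0).astype(float)
    b = (np.asarray(mask_es) > 0).astype(float)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("boundary masks must be non-empty")
    # sd 2 with truncate 2.0 gives the 9x9x9 (radius-4) kernel
    soft_a = ndimage.gaussian_filter(a, sigma=2.0, truncate=2.0)
    soft_b = ndimage.gaussian_filter(b, sigma=2.0, truncate=2.0)
    vectors = np.asarray(register(soft_a, soft_b), dtype=float)
    if vectors.shape != a.shape + (3,):
        raise ValueError("registration callback must return an (nx,ny,nz,3) field")
    return DisplacementField(vectors, t_from=t_ed, t_to=t_es, weight=weight,
                             spacing=spacing, origin=origin)
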