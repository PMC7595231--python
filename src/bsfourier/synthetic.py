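"""Synthetic ground truth: cyclic motion, registration sets, landmarks,
phantom images.

The generator emulates what the real pipeline consumes: a smooth, cyclic,
fold-free ground-truth motion with known Fourier content; pairwise
displacement fields sampled from it (neighbour chain plus reference-frame
fields) with optional spatially-correlated noise; ground-truth landmark
trajectories; and a deformed ellipsoidal-shell intensity phantom with
end-diastole/end-systole masks.  All randomness flows through one seeded
generator passed explicitly -- no global state.

Noise-free registration sets carry an exact analytic sampler backed by the
generating model (displacements obtained by inverse-mapping the query
point and re-evaluating), so they are exactly consistent with the model at
*any* position; spatially-correlated Gaussian noise (emulating the smooth
errors of real registration) is defined on the voxel grid, so noisy sets
sample their gridded values trilinearly.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .evaluation import LandmarkTracks
from .fields import DisplacementField, RegistrationSet
from .model import BSFModel

__all__ = [
    "make_ground_truth",
    "make_registration_set",
    "make_truth_tracks",
    "make_phantom",
    "ExactFieldFamily",
]


def make_ground_truth(grid: int = 64, period: int = 28, n_modes: int = 4,
                      amplitude: float = 2.0, smoothness: float = 16.0,
                      seed: int = 0) -> BSFModel:
    """Random smooth cyclic motion model on a ``grid``^3 voxel domain (1 mm
    isotropic voxels).

    The static channel is the identity map; dynamic channels are low-pass
    random lattices with amplitudes decaying as 1/(1+f), scaled so the
    peak dynamic displacement is ``amplitude`` mm.  ``smoothness`` is the
    approximate spatial scale (voxels) of motion variation and sets the
    lattice density.  The model is audited for folds (sampled det(J) > 0);
    amplitudes producing folds are damped with a warning.  Deterministic
    per seed.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if period < 2 * n_modes + 1:
        raise ValueError("period must be at least 2 * n_modes + 1 frames")
    rng = np.random.default_rng(seed)
    levels = 0
    while (grid - 1) / 2**levels > smoothness and levels < 6:
        levels += 1
    m = 2**levels
    g = m + 3
    spacing = np.full(3, (grid - 1) / m)
    origin = -spacing  # reference coordinate 1 -> physical 0

    nc = 2 * n_modes + 1
    lattice = np.zeros((g, g, g, nc, 3))
    node_phys = origin[0] + np.arange(g) * spacing[0]
    nx, ny, nz = np.meshgrid(node_phys, node_phys, node_phys, indexing="ij")
    lattice[..., 0, 0] = nx
    lattice[..., 0, 1] = ny
    lattice[..., 0, 2] = nz

    dyn = rng.normal(size=(g, g, g, nc - 1, 3))
    dyn = ndimage.gaussian_filter(dyn, sigma=(1.0, 1.0, 1.0, 0, 0))
    for s in range(1, nc):
        f = s if s <= n_modes else s - n_modes
        dyn[..., s - 1, :] /= f
    peak = np.abs(dyn).sum(axis=3).max()
    dyn *= amplitude / peak

    amp = 1.0
    for attempt in range(8):
        lattice[..., 1:, :] = amp * dyn
        model = BSFModel(lattice.copy(), spacing, origin, period, n_modes)
        pts = rng.uniform(1.0, g - 2.0, size=(200, 3))
        ok = all(
            np.all(model.jacobian_det(pts, float(t)) > 0)
            for t in range(period)
        )
        if ok:
            if attempt:
                warnings.warn(
                    f"ground-truth amplitude damped by {amp:.3g} to avoid folds"
                )
            return model
        amp *= 0.5
    raise RuntimeError("could not generate a fold-free ground-truth model")


class ExactFieldFamily:
    """Batched exact sampler of model-consistent displacement fields.

    ``displacement(x, t_from, t_to)`` inverse-maps each physical query to
    its reference coordinate at ``t_from`` (damped Newton on the model's
    analytic Jacobian, iterated far below the fields' use tolerance) and
    returns ``X(t_to) - x``; the analytic spatial Jacobian of the
    displacement follows from the chain rule.
    """

    def __init__(self, model: BSFModel, tol: float = 1e-12, max_iter: int = 80):
        self.model = model
        self.tol = tol
        self.max_iter = max_iter

    def invmap(self, x, t, ref0=None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        t = np.broadcast_to(np.asarray(t, dtype=float), x.shape[:1]).copy()
        lo, hi = self.model.support_bounds
        ref = (self.model.physical_to_ref(x) if ref0 is None
               else np.array(ref0, dtype=float))
        ref = np.clip(ref, lo, hi)
        prev = np.inf
        stalled = 0
        for _ in range(self.max_iter):
            pos, jac = self.model.evaluate(ref, t, deriv=True)
            r = x - pos
            m = float(np.max(np.abs(r)))
            if m < self.tol:
                break
            # queries outside the deformed domain clamp at the support and
            # stop improving; give up on them rather than burn iterations
            if m > 0.5 * prev:
                stalled += 1
                if stalled >= 3:
                    break
            else:
                stalled = 0
            prev = m
            step = np.linalg.solve(jac, r[..., None])[..., 0]
            norm = np.linalg.norm(step, axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(norm > 2.0, step * (2.0 / norm), step)
            ref = np.clip(ref + step, lo, hi)
        return ref

    def displacement(self, x, t_from, t_to, ref0=None, return_ref=False):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        t_from = np.broadcast_to(np.asarray(t_from, dtype=float), (n,))
        t_to = np.broadcast_to(np.asarray(t_to, dtype=float), (n,))
        ref = self.invmap(x, t_from, ref0=ref0)
        # displacement of the matched material point: for queries inside the
        # deformed domain this equals X(t_to) - x; clamped queries get the
        # nearest domain point's displacement (clamp-to-edge convention)
        d = self.model.evaluate(ref, t_to) - self.model.evaluate(ref, t_from)
        return (d, ref) if return_ref else d

    def displacement_jacobian(self, x, t_from, t_to, ref0=None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        t_from = np.broadcast_to(np.asarray(t_from, dtype=float), (n,))
        t_to = np.broadcast_to(np.asarray(t_to, dtype=float), (n,))
        ref = self.invmap(x, t_from, ref0=ref0)
        j_from = self.model.evaluate(ref, t_from, deriv=True)[1]
        j_to = self.model.evaluate(ref, t_to, deriv=True)[1]
        return j_to @ np.linalg.inv(j_from) - np.eye(3)

    def field(self, t_from: int, t_to: int, grid_shape,
              weight: float = 1.0, role=None, domain=None) -> DisplacementField:
        vectors = np.zeros(tuple(grid_shape) + (3,))

        def exact_fn(x, _tf=float(t_from), _tt=float(t_to)):
            return self.displacement(x, _tf, _tt)

        def exact_jac_fn(x, _tf=float(t_from), _tt=float(t_to)):
            return self.displacement_jacobian(x, _tf, _tt)

        return DisplacementField(
            vectors, t_from=t_from, t_to=t_to, weight=weight, role=role,
            exact_fn=exact_fn, exact_jac_fn=exact_jac_fn, family=self,
            domain=domain,
        )


def _grid_points(grid_shape):
    axes = [np.arange(n, dtype=float) for n in grid_shape]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=-1)


def _required_pairs(period: int, include_reference: bool):
    pairs = [(t, t + 1, "neighbour") for t in range(period)]
    if include_reference:
        pairs += [(0, t, "reference") for t in range(1, period)]
    return pairs


def make_registration_set(model: BSFModel, grid: int = 64, noise: float = 0.0,
                          seed: int = 0, corr_length: float = 6.0,
                          include_reference: bool = True,
                          materialise: bool | None = None) -> RegistrationSet:
    """Pairwise fields sampled from a ground-truth model.

    Generates the neighbour chain ``t -> t+1`` (t = 0..P-1, closing the
    cycle) and, optionally, the reference-frame fields ``0 -> t``.  With
    ``noise == 0`` the fields sample the model exactly (see module notes);
    with ``noise > 0``, Gaussian white noise filtered to a correlation
    length of ``corr_length`` voxels and scaled to a pointwise standard
    deviation of ``noise`` voxels is added to the gridded values, and the
    noise magnitude scales linearly with ``noise`` at fixed seed.
    """
    period = int(round(model.period))
    shape = (grid, grid, grid)
    family = ExactFieldFamily(model)
    if materialise is None:
        materialise = noise > 0
    if noise > 0:
        materialise = True  # noise is defined on the voxel grid
    domain = (np.zeros(3), np.full(3, grid - 1.0))
    pairs = _required_pairs(period, include_reference)
    if not materialise:
        fields = [family.field(a, b, (2, 2, 2), role=role, domain=domain)
                  for a, b, role in pairs]
        return RegistrationSet(fields, period)

    rng = np.random.default_rng(seed)
    pts = _grid_points(shape)
    fields = []
    # group by t_from so the inverse map is computed once per source frame
    by_from = {}
    for a, b, role in pairs:
        by_from.setdefault(a, []).append((b, role))
    ref_cache = {}
    for a in sorted(by_from):
        ref_cache[a] = family.invmap(pts, float(a),
                                     ref0=ref_cache.get(a - 1))
    for a, b, role in pairs:
        t_to = np.full(pts.shape[0], float(b))
        disp = (model.evaluate(ref_cache[a], t_to) - pts).reshape(shape + (3,))
        if noise > 0:
            white = rng.normal(size=shape + (3,))
            corr = ndimage.gaussian_filter(white, sigma=(corr_length,) * 3 + (0,))
            corr *= noise / corr.std()
            disp = disp + corr
            fields.append(DisplacementField(disp, a, b, role=role))
        else:
            f = family.field(a, b, (2, 2, 2), role=role, domain=domain)
            f.vectors = disp
            fields.append(f)
    return RegistrationSet(fields, period)


def make_truth_tracks(model: BSFModel, n: int, seed: int = 0,
                      margin: float = 1.0) -> LandmarkTracks:
    """Ground-truth landmark trajectories: random interior reference points
    evaluated at every frame (positions double as the truth)."""
    rng = np.random.default_rng(seed)
    period = int(round(model.period))
    if n == 0:
        empty = np.empty((0, period, 3))
        return LandmarkTracks(empty, empty.copy())
    lo, hi = model.support_bounds
    refs = rng.uniform(lo + margin, hi - margin, size=(n, 3))
    frames = np.arange(period, dtype=float)
    pos = np.stack([model.evaluate(refs, t) for t in frames], axis=1)
    return LandmarkTracks(pos, pos.copy())


def make_phantom(model: BSFModel, grid: int = 32, centre=None, radii=None,
                 thickness: float = 4.0, intensity: float = 100.0,
                 speckle: float = 0.0, seed: int = 0):
    """Deformed ellipsoidal-shell intensity phantom with ED/ES masks.

    The shell (a crude ventricular wall) lives in the reference frame;
    each frame's image is rendered by inverse-mapping every voxel and
    evaluating the shell profile there, with optional multiplicative
    speckle.  Masks of the enclosed cavity are returned at the frames of
    maximal (ED) and minimal (ES) cavity volume.

    Returns ``(images (P, n, n, n), mask_ed, mask_es, t_ed, t_es)``.
    """
    rng = np.random.default_rng(seed)
    period = int(round(model.period))
    if centre is None:
        centre = np.full(3, (grid - 1) / 2.0)
    if radii is None:
        radii = np.full(3, grid / 4.0)
    centre = np.asarray(centre, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= thickness / 2) or np.any(centre + radii > grid) \
            or np.any(centre - radii < 0):
        raise ValueError("shell geometry does not fit inside the grid")
    family = ExactFieldFamily(model)
    pts = _grid_points((grid, grid, grid))
    shape = (grid, grid, grid)
    images = np.empty((period,) + shape)
    cavity = np.empty((period,) + shape, dtype=bool)
    ref_prev = None
    for t in range(period):
        ref_prev = family.invmap(pts, float(t), ref0=ref_prev)
        p = model.ref_to_physical(ref_prev)
        rho = np.linalg.norm((p - centre) / radii, axis=1)
        wall = np.exp(-((rho - 1.0) * radii.mean() / (thickness / 2.0)) ** 2)
        img = intensity * wall
        if speckle > 0:
            img = img * (1.0 + speckle * rng.normal(size=img.shape))
        images[t] = img.reshape(shape)
        cavity[t] = (rho < 1.0).reshape(shape)
    volumes = cavity.reshape(period, -1).sum(axis=1)
    t_ed = int(np.argmax(volumes))
    t_es = int(np.argmin(volumes))
    return images, cavity[t_ed], cavity[t_es], t_ed, t_es
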