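"""Forward marching: accumulating pairwise displacements into trajectories.

The marching recursion blends an Eulerian estimate (current position plus
the neighbour-frame displacement sampled there) with a Lagrangian estimate
(the seed position plus the 0 -> t+1 displacement sampled at the seed):

    X^{t+1} = w(t) (X^t + dX_{t->t+1}(X^t)) + (1 - w(t)) (X^0 + dX_{0->t+1}(X^0))

The weight families model decaying confidence in the Lagrangian
registration away from the reference frame: ``w == 1`` is pure Eulerian,
``w == 0`` pure Lagrangian, the quadratic weight is
``w(t) = (P - t) t / (P/2)^2``, and a Gaussian-shaped alternative
``w(t) = (1 - exp(-t(P-t)/(2 sigma^2)))`` normalised to 1 at mid-cycle is
provided (no canonical form exists for it; post-correction results are
insensitive to the choice).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .fields import RegistrationSet, TrajectorySet

__all__ = ["quadratic_weight", "gaussian_weight", "sample_field", "march", "make_seeds"]


def quadratic_weight(t, P):
    """Quadratic Eulerian/Lagrangian blending weight ``(P - t) t / (P/2)^2``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > P):
        raise ValueError(f"marching time must lie in [0, {P}], got {t}")
    w = (P - t) * t / (P / 2.0) ** 2
    return float(w) if w.ndim == 0 else w


def gaussian_weight(t, P, sigma=None):
    """Gaussian-shaped blending weight, normalised so that w(P/2) = 1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > P):
        raise ValueError(f"marching time must lie in [0, {P}], got {t}")
    if sigma is None:
        sigma = P / 4.0
    w = 1.0 - np.exp(-t * (P - t) / (2.0 * sigma**2))
    w = w / (1.0 - np.exp(-(P / 2.0) ** 2 / (2.0 * sigma**2)))
    return float(w) if w.ndim == 0 else w


def sample_field(field, x):
    """Trilinear (clamp-to-edge) sample of a displacement field at ``x`` mm."""
    return field.sample(x)


def _weight_fn(scheme: str, P: int, sigma=None):
    if scheme == "eulerian":
        return lambda t: 1.0
    if scheme == "lagrangian":
        return lambda t: 0.0
    if scheme == "quadratic":
        return lambda t: quadratic_weight(t, P)
    if scheme == "gaussian":
        return lambda t: gaussian_weight(t, P, sigma)
    raise ConfigurationError(f"unknown marching scheme {scheme!r}")


def march(reg: RegistrationSet, seeds, scheme: str = "quadratic",
          sigma=None) -> TrajectorySet:
    """March ``seeds`` (n, 3) through frames 0..P-1 of the cycle.

    The Eulerian term samples each neighbour field at the current marched
    position; the Lagrangian term samples each reference field at the seed.
    Missing fields raise :class:`ConfigurationError` naming the pair.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    P = reg.period
    wfn = _weight_fn(scheme, P, sigma)
    positions = np.empty((seeds.shape[0], P, 3))
    positions[:, 0] = seeds
    x = seeds.copy()
    for t in range(P - 1):
        w = wfn(t)
        if w != 0.0:
            eul = x + reg.neighbour(t).sample(x)
        else:
            eul = 0.0
        if w != 1.0:
            lag = seeds + reg.reference(t + 1).sample(seeds)
        else:
            lag = 0.0
        x = w * eul + (1.0 - w) * lag
        positions[:, t + 1] = x
    return TrajectorySet(positions, P)


def make_seeds(grid_shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
               stride: int = 4, margin: int = 0) -> np.ndarray:
    """Regular sub-grid of voxel centres at a configurable stride (mm)."""
    axes = [
        np.arange(margin, n - margin, stride, dtype=float)
        for n in grid_shape
    ]
    if any(len(a) == 0 for a in axes):
        raise ConfigurationError("seed margin/stride leaves no seeds on the grid")
    g = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([a.ravel() for a in g], axis=-1)
    return np.asarray(origin) + idx * np.asarray(spacing)
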