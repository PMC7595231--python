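"""Displacement vector fields and registration-field collections.

A :class:`DisplacementField` holds one pairwise-registration output: a 3D
grid of displacement triples labelled with its source frame ``t_from``,
target frame ``t_to`` and a nonnegative weight.  Sampling at arbitrary
physical positions uses trilinear interpolation with clamp-to-edge
boundary handling (the cardiac region of interest is interior to the
image, so clamping never extrapolates wildly).

A field may additionally carry an exact analytic sampler (``exact_fn``),
used by the synthetic-data generator to produce registration sets that are
exactly consistent with a generating motion model; when present it
overrides the gridded interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np

from .errors import ConfigurationError

__all__ = ["DisplacementField", "RegistrationSet", "TrajectorySet"]


def _trilinear(grid: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Clamp-to-edge trilinear sampling of a (nx, ny, nz, 3) grid at
    fractional voxel indices (n, 3)."""
    shape = np.asarray(grid.shape[:3])
    idx = np.clip(idx, 0.0, shape - 1.0)
    i0 = np.minimum(np.floor(idx).astype(int), shape - 2)
    f = idx - i0
    out = np.zeros((idx.shape[0], grid.shape[3]))
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        for dy in (0, 1):
            wxy = wx * (f[:, 1] if dy else 1.0 - f[:, 1])
            for dz in (0, 1):
                w = wxy * (f[:, 2] if dz else 1.0 - f[:, 2])
                out += w[:, None] * grid[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


@dataclass
class DisplacementField:
    """One pairwise-registration displacement field on a regular voxel grid."""

    vectors: np.ndarray  # (nx, ny, nz, 3), mm
    t_from: int
    t_to: int
    weight: float = 1.0
    spacing: np.ndarray = dc_field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    role: Optional[str] = None  # None | "neighbour" | "reference"
    exact_fn: Optional[Callable] = None  # x (n,3) -> displacement (n,3)
    exact_jac_fn: Optional[Callable] = None  # x (n,3) -> (n,3,3)
    family: object = None  # shared exact-sampler backend (synthetic fields)
    domain: object = None  # optional (lo, hi) physical validity bounds

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise ValueError("vectors must have shape (nx, ny, nz, 3)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.weight < 0:
            raise ValueError("field weight must be nonnegative")

    @property
    def grid_shape(self):
        return self.vectors.shape[:3]

    @property
    def physical_bounds(self):
        """(lo, hi) corners of the region where the field carries data."""
        if self.domain is not None:
            return (np.asarray(self.domain[0], dtype=float),
                    np.asarray(self.domain[1], dtype=float))
        hi = self.origin + (np.asarray(self.grid_shape) - 1) * self.spacing
        return self.origin, hi

    def sample(self, x) -> np.ndarray:
        """Displacement (mm) at physical positions ``x`` (n, 3) or (3,)."""
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        x = np.atleast_2d(x)
        if self.exact_fn is not None:
            d = self.exact_fn(x)
        else:
            idx = (x - self.origin) / self.spacing
            d = _trilinear(self.vectors, idx)
        if not np.all(np.isfinite(d)):
            raise ValueError(
                f"non-finite displacement sampled from field {self.t_from}->{self.t_to}"
            )
        return d[0] if squeeze else d

    def sample_jacobian(self, x, step: float = 0.5) -> np.ndarray:
        """Spatial gradient d(displacement)/dx at ``x`` (n, 3, 3).

        Central finite differences with a physical step of ``step`` voxels;
        exact fields use their analytic Jacobian when available.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.exact_jac_fn is not None:
            return self.exact_jac_fn(x)
        h = step * self.spacing
        jac = np.empty((x.shape[0], 3, 3))
        for a in range(3):
            e = np.zeros(3)
            e[a] = h[a]
            jac[:, :, a] = (self.sample(x + e) - self.sample(x - e)) / (2.0 * h[a])
        return jac


class RegistrationSet:
    """The collection ``Reg`` of weighted pairwise displacement fields.

    Marching needs at minimum the neighbour chain ``{t -> t+1}``; blended
    schemes additionally need the reference-frame fields ``{0 -> t}``.  A
    field labelled (0, 1) serves both roles unless fields carry explicit
    ``role`` tags.  Arbitrary extra weighted pairs (e.g. an end-diastole to
    end-systole boundary constraint) may be appended for consistency
    correction.
    """

    def __init__(self, fields, period: int):
        self.fields = list(fields)
        self.period = int(period)
        self._validate()

    def _validate(self):
        if not self.fields:
            return
        ref = self.fields[0]
        for f in self.fields[1:]:
            if f.grid_shape != ref.grid_shape or not (
                np.allclose(f.spacing, ref.spacing) and np.allclose(f.origin, ref.origin)
            ):
                raise ConfigurationError(
                    f"field {f.t_from}->{f.t_to} grid geometry differs from "
                    f"{ref.t_from}->{ref.t_to}"
                )

    def __iter__(self):
        return iter(self.fields)

    def __len__(self):
        return len(self.fields)

    def add(self, field: DisplacementField):
        self.fields.append(field)
        self._validate()

    def _lookup(self, t_from: int, t_to: int, role: str) -> DisplacementField:
        tagged = [
            f for f in self.fields
            if f.t_from == t_from and f.t_to == t_to and f.role == role
        ]
        if tagged:
            return tagged[0]
        untagged = [
            f for f in self.fields
            if f.t_from == t_from and f.t_to == t_to and f.role is None
        ]
        if untagged:
            return untagged[0]
        raise ConfigurationError(
            f"registration set is missing the {role} field {t_from}->{t_to}"
        )

    def neighbour(self, t: int) -> DisplacementField:
        """Field t -> t+1 (Eulerian term)."""
        return self._lookup(t, t + 1, "neighbour")

    def reference(self, t: int) -> DisplacementField:
        """Field 0 -> t (Lagrangian term)."""
        return self._lookup(0, t, "reference")


@dataclass
class TrajectorySet:
    """Forward-marched sample-point paths over one cycle.

    ``positions`` has shape (n_points, P, 3); frame 0 equals the seeds.
    """

    positions: np.ndarray
    period: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n, P, 3)")
        if self.positions.shape[1] != self.period:
            raise ValueError("one position per frame of the cycle is required")

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def seeds(self) -> np.ndarray:
        return self.positions[:, 0, :]
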