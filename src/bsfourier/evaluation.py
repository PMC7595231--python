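"""Tracking-quality metrics, model-selection guidelines, audits.

Covers the landmark Euclidean-distance error (temporally averaged over the
closed cycle), the stationary-landmark exclusion rule used for manually
tracked ground truth, Dice overlap, mesh volume curves with spectral
temporal gradients, the cumulative-power rule for choosing the number of
Fourier modes, the feature-length/grid-spacing guideline, and the
det(Jacobian) diffeomorphism audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import BSFModel

__all__ = [
    "LandmarkTracks",
    "euclidean_error",
    "apply_exclusions",
    "dice",
    "volume_curve",
    "choose_modes",
    "suggest_grid",
    "jacobian_audit",
]


@dataclass
class LandmarkTracks:
    """Tracked (and optionally ground-truth) landmark positions per frame.

    ``positions``/``truth``: (n_landmarks, n_frames, 3) physical mm, frames
    aligned across landmarks.  Excluded landmarks carry a reason string.
    ``observer`` optionally labels the human observer who produced each
    truth track (used by the block-exclusion rule).
    """

    positions: np.ndarray
    truth: Optional[np.ndarray] = None
    excluded: np.ndarray = None
    reasons: list = field(default_factory=list)
    observer: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n, frames, 3)")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=float)
            if self.truth.shape != self.positions.shape:
                raise ValueError("truth must be frame-aligned with positions")
        if self.excluded is None:
            self.excluded = np.zeros(self.positions.shape[0], dtype=bool)
        if not self.reasons:
            self.reasons = [""] * self.positions.shape[0]

    @property
    def n_landmarks(self):
        return self.positions.shape[0]

    @property
    def n_frames(self):
        return self.positions.shape[1]


def euclidean_error(tracks: LandmarkTracks, convention: str = "closed"):
    """Temporally averaged Euclidean landmark error.

    The printed normalisation sums frames t = 0..P (the cyclic endpoint
    duplicates frame 0) and divides by P; ``convention="open"`` instead
    averages the P distinct frames.  Returns ``(per_landmark, mean)`` over
    included landmarks.
    """
    if tracks.truth is None:
        raise ValueError("ground-truth tracks are required")
    keep = ~tracks.excluded
    if not np.any(keep):
        raise ValueError("no included landmarks to evaluate")
    d = np.linalg.norm(tracks.positions[keep] - tracks.truth[keep], axis=2)
    P = tracks.n_frames
    if convention == "closed":
        per = (d.sum(axis=1) + d[:, 0]) / P
    elif convention == "open":
        per = d.sum(axis=1) / P
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return per, float(per.mean())


def _max_stationary_run(track: np.ndarray) -> int:
    """Longest run of consecutive frames with an unchanged position."""
    same = np.all(track[1:] == track[:-1], axis=1)
    best = run = 1
    for s in same:
        run = run + 1 if s else 1
        best = max(best, run)
    return best


def apply_exclusions(tracks: LandmarkTracks,
                     max_stationary: int = 3) -> LandmarkTracks:
    """Flag landmarks whose ground truth is stationary too long.

    A truth track that does not move for more than ``max_stationary``
    consecutive frames is excluded (a stationary stretch of exactly
    ``max_stationary`` frames is retained).  If observer labels are
    present and more than half of one observer's landmarks are flagged,
    that observer's entire block is excluded.
    """
    if tracks.truth is None:
        raise ValueError("exclusion rule operates on ground-truth tracks")
    n = tracks.n_landmarks
    excluded = tracks.excluded.copy()
    reasons = list(tracks.reasons)
    for i in range(n):
        if _max_stationary_run(tracks.truth[i]) > max_stationary:
            excluded[i] = True
            reasons[i] = f"stationary for more than {max_stationary} frames"
    if tracks.observer is not None:
        obs = np.asarray(tracks.observer)
        for o in np.unique(obs):
            sel = obs == o
            if excluded[sel].sum() * 2 > sel.sum():
                for i in np.where(sel & ~excluded)[0]:
                    reasons[i] = f"observer {o} block excluded"
                excluded |= sel
    return LandmarkTracks(tracks.positions, tracks.truth, excluded, reasons,
                          tracks.observer)


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two binary masks."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def _mesh_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def volume_curve(model: BSFModel, vertices, faces):
    """Enclosed volume per frame of a closed reference-frame surface mesh.

    Vertices (reference-frame physical mm) are deformed through the model
    at every frame; the signed volume follows from the divergence theorem
    and the temporal gradient from spectral differentiation of the
    periodic volume series.  Returns ``(volumes, dV/dt)`` over frames
    0..P-1.
    """
    import trimesh

    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if not mesh.is_watertight:
        raise ValueError("volume_curve requires a closed (watertight) mesh")
    refs = model.physical_to_ref(vertices)
    P = int(round(model.period))
    volumes = np.empty(P)
    for t in range(P):
        deformed = model.evaluate(refs, float(t))
        volumes[t] = abs(_mesh_volume(deformed, faces))
    k = np.fft.fftfreq(P, d=1.0) * P  # integer mode numbers
    dvdt = np.real(np.fft.ifft(np.fft.fft(volumes) * 2j * np.pi * k / P))
    return volumes, dvdt


def choose_modes(waveform, threshold: float = 0.95) -> int:
    """Smallest N whose Fourier modes 1..N hold >= ``threshold`` of the
    waveform's dynamic spectral power (the DC term carries no motion and is
    excluded from the ratio; a constant signal yields N = 0)."""
    w = np.asarray(waveform, dtype=float)
    spec = np.fft.rfft(w)
    power = np.abs(spec) ** 2
    dc = power[0]
    power[0] = 0.0
    total = power.sum()
    if total <= 1e-20 * (dc + 1.0):  # constant signal up to rounding
        return 0
    cum = np.cumsum(power) / total
    return int(np.argmax(cum >= threshold - 1e-12))


def suggest_grid(feature_length: float, domain_extent: float,
                 target_ratio: float = 0.5, band=(0.4, 0.6)):
    """Grid spacing and MLB level for a given feature size.

    The feature-length / grid-spacing ratio should sit near 0.4-0.6 (the
    Gaussian-kernel approximation of a cubic B-spline has standard
    deviation ~0.577 cells, so this keeps one feature within one standard
    deviation); the midpoint 0.5 is targeted.  The returned level is the
    smallest whose ``2**levels + 2`` cells cover the extent at no more
    than the suggested spacing.
    """
    if feature_length <= 0 or domain_extent <= 0:
        raise ValueError("feature length and domain extent must be positive")
    spacing = feature_length / target_ratio
    ratio = feature_length / spacing
    assert band[0] <= ratio <= band[1]
    levels = 0
    while domain_extent / (2**levels + 2) > spacing:
        levels += 1
        if levels > 30:
            raise ValueError("extent infeasibly large for the suggested spacing")
    return spacing, levels


def jacobian_audit(model: BSFModel, points, frames=None):
    """Evaluate det(Jacobian) over points x frames; a diffeomorphic motion
    has det > 0 everywhere (det = 1 would be incompressible).

    Returns a dict with ``min``, ``mean`` and a ``violations`` list of
    (point_index, frame, det) entries with det <= 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if frames is None:
        frames = np.arange(int(round(model.period)))
    dets = np.empty((len(frames), points.shape[0]))
    violations = []
    for fi, t in enumerate(frames):
        dets[fi] = model.jacobian_det(points, float(t))
        for pi in np.where(dets[fi] <= 0)[0]:
            violations.append((int(pi), float(t), float(dets[fi, pi])))
    return {
        "min": float(dets.min()),
        "mean": float(dets.mean()),
        "violations": violations,
    }
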