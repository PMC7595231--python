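"""Phase synchronisation of asynchronously acquired 2D cine slices.

Adjacent slices of a slice-by-slice cine acquisition each cover one full
cardiac cycle but start at an unknown phase.  The estimator builds the
P x P zero-mean normalised cross-correlation map between two slices,
takes each frame's best-matching frame in the other slice, circularly
unwraps the match indices and fits the intercept of a slope-1 line
(frame-rate-matched acquisitions fix the slope at 1 in frame units; the
intercept is the phase shift).  Cumulative pairwise shifts then let the
slices be resampled onto a common phase and stacked into a 4D image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["estimate_phase_shift", "synchronise_stack", "PhaseShift"]


@dataclass
class PhaseShift:
    shift: float  # fractional frames, modulo P
    residual: float  # RMS regression residual (frames)
    low_confidence: bool


def _ncc_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Zero-mean NCC of every frame of ``a`` against every frame of ``b``."""
    a = a.reshape(a.shape[0], -1).astype(float)
    b = b.reshape(b.shape[0], -1).astype(float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(a, axis=1)
    sb = np.linalg.norm(b, axis=1)
    if np.any(sa == 0) or np.any(sb == 0):
        raise ValueError("flat (zero-variance) frame: NCC undefined")
    return (a @ b.T) / np.outer(sa, sb)


def estimate_phase_shift(slice_a, slice_b, period=None,
                         residual_threshold: float = 1.0) -> PhaseShift:
    """Fractional frame shift of ``slice_b`` relative to ``slice_a``.

    Both inputs are (P, ny, nx) frame sequences covering one period.  The
    slope of the match line is fixed at 1 (equal frame rates); the
    intercept -- the circular mean of the unwrapped per-frame offsets --
    is the shift.  A large regression residual flags low confidence.
    """
    a = np.asarray(slice_a, dtype=float)
    b = np.asarray(slice_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("slices must have equal frame counts")
    P = a.shape[0] if period is None else int(period)
    ncc = _ncc_map(a, b)
    best = np.argmax(ncc, axis=1).astype(float)  # per frame of a
    # circular unwrap of the offsets (phase is periodic; raw argmax wraps)
    offsets = (best - np.arange(P)) % P
    ang = 2.0 * np.pi * offsets / P
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    shift = (mean_ang * P / (2.0 * np.pi)) % P
    dev = (offsets - shift + P / 2.0) % P - P / 2.0
    residual = float(np.sqrt(np.mean(dev**2)))
    return PhaseShift(shift=float(shift), residual=residual,
                      low_confidence=residual > residual_threshold)


def _circular_resample(frames: np.ndarray, shift: float) -> np.ndarray:
    """Resample a periodic frame sequence at ``t + shift`` (linear blend of
    the two bracketing frames, wrapped)."""
    P = frames.shape[0]
    t = (np.arange(P) + shift) % P
    i0 = np.floor(t).astype(int) % P
    i1 = (i0 + 1) % P
    f = (t - np.floor(t))[:, None, None]
    return (1.0 - f) * frames[i0] + f * frames[i1]


def synchronise_stack(slices) -> np.ndarray:
    """Align >= 2 cine slices to the phase of the first and stack them.

    Cumulative pairwise shifts are applied by circular temporal
    resampling; the result has shape (P, n_slices, ny, nx).
    """
    slices = [np.asarray(s, dtype=float) for s in slices]
    if len(slices) < 2:
        raise ValueError("need at least two slices to synchronise")
    P = slices[0].shape[0]
    if any(s.shape[0] != P for s in slices):
        raise ValueError("all slices must share the period")
    out = [slices[0]]
    cumulative = 0.0
    for prev, cur in zip(slices[:-1], slices[1:]):
        cumulative = (cumulative + estimate_phase_shift(prev, cur).shift) % P
        out.append(_circular_resample(cur, cumulative))
    return np.stack(out, axis=1)
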