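"""Evaluation utilities: landmark error, exclusions, Dice, volumes, audits."""

import numpy as np
import pytest
import trimesh

from bsfourier import (LandmarkTracks, apply_exclusions, choose_modes, dice,
                       euclidean_error, jacobian_audit, suggest_grid,
                       volume_curve)
from bsfourier.model import BSFModel


# ------------------------------------------------------------ euclidean error
def test_perfect_tracks_have_zero_error():
    pos = np.random.default_rng(0).normal(size=(3, 8, 3))
    _, mean = euclidean_error(LandmarkTracks(pos, pos.copy()))
    assert mean == 0.0


def test_constant_offset_error_closed_convention():
    """1 mm offset everywhere: the cyclic sum t=0..P over divisor P gives
    (P+1)/P mm; the open convention gives exactly 1 mm."""
    P = 8
    pos = np.zeros((2, P, 3))
    truth = pos.copy()
    pos[..., 0] += 1.0
    lt = LandmarkTracks(pos, truth)
    _, closed = euclidean_error(lt, convention="closed")
    _, open_ = euclidean_error(lt, convention="open")
    assert abs(closed - (P + 1) / P) < 1e-12
    assert abs(open_ - 1.0) < 1e-12


def test_error_matches_hand_computation():
    # two landmarks, 3 frames, hand-listed coordinates
    pos = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                    [[2, 0, 0], [2, 0, 0], [2, 0, 0]]], dtype=float)
    truth = np.array([[[0, 0, 0], [0, 0, 0], [0, 0, 0]],
                      [[0, 0, 0], [2, 0, 0], [2, 2, 0]]], dtype=float)
    per, mean = euclidean_error(LandmarkTracks(pos, truth), convention="open")
    np.testing.assert_allclose(per, [(0 + 1 + 1) / 3, (2 + 0 + 2) / 3])
    assert abs(mean - (2 / 3 + 4 / 3) / 2) < 1e-12


def test_error_requires_included_landmarks():
    pos = np.zeros((1, 4, 3))
    lt = LandmarkTracks(pos, pos.copy(), excluded=np.array([True]))
    with pytest.raises(ValueError):
        euclidean_error(lt)


# ---------------------------------------------------------------- exclusions
def _stationary_tracks(run_lengths, P=10):
    n = len(run_lengths)
    rng = np.random.default_rng(1)
    truth = rng.normal(size=(n, P, 3))
    for i, run in enumerate(run_lengths):
        truth[i, 2:2 + run] = truth[i, 2]  # `run` identical frames
    return LandmarkTracks(truth.copy(), truth)


def test_four_stationary_frames_excluded_three_retained():
    lt = apply_exclusions(_stationary_tracks([4, 3]))
    assert lt.excluded.tolist() == [True, False]
    assert "stationary" in lt.reasons[0]


def test_observer_block_excluded_when_majority_flagged():
    # observer A: 7 of 12 stationary -> whole block out; observer B clean
    runs = [4] * 7 + [1] * 5 + [1] * 3
    lt = _stationary_tracks(runs, P=12)
    lt = LandmarkTracks(lt.positions, lt.truth,
                        observer=np.array(["A"] * 12 + ["B"] * 3))
    out = apply_exclusions(lt)
    assert out.excluded[:12].all()
    assert not out.excluded[12:].any()


# ---------------------------------------------------------------------- dice
def test_dice_identical_disjoint_and_partial():
    a = np.zeros((10, 10, 10), dtype=bool)
    a[:5] = True
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
    b = np.zeros_like(a)
    b[:4] = True  # |A|=500, |B|=400, overlap 400
    assert abs(dice(a, b) - 2 * 400 / 900) < 1e-12


def test_dice_symmetry_and_empty_error(rng):
    a = rng.random((8, 8, 8)) > 0.5
    b = rng.random((8, 8, 8)) > 0.5
    assert dice(a, b) == dice(b, a)
    with pytest.raises(ValueError):
        dice(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))


# -------------------------------------------------------------- volume curve
def _scaling_model(P=12, scale_amp=0.1):
    """Model that scales space isotropically by 1 + amp*cos(2 pi t / P)."""
    g, n_modes = 7, 1
    lattice = np.zeros((g, g, g, 3, 3))
    coords = -4.0 + np.arange(g) * 4.0  # spacing 4, centred on 8
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    for a, A in enumerate((X, Y, Z)):
        lattice[..., 0, a] = A
        lattice[..., 1, a] = scale_amp * A  # cosine mode scales about 0
    return BSFModel(lattice, np.full(3, 4.0), np.full(3, -8.0), P, n_modes)


def test_static_model_constant_volume(identity_model):
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=1.5)
    centre = np.array([4.0, 4.0, 4.0])
    vols, dvdt = volume_curve(identity_model, sphere.vertices + centre,
                              sphere.faces)
    np.testing.assert_allclose(vols, vols[0], rtol=1e-12)
    np.testing.assert_allclose(dvdt, 0.0, atol=1e-9)


def test_isotropic_scaling_matches_analytic_sphere():
    model = _scaling_model()
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
    vols, dvdt = volume_curve(model, sphere.vertices, sphere.faces)
    P = 12
    t = np.arange(P)
    s = 1 + 0.1 * np.cos(2 * np.pi * t / P)
    # scaling is exactly linear, so the deformed mesh volume is s^3 times
    # the discrete mesh volume, which itself is within mesh discretisation
    # error of the analytic sphere volume
    np.testing.assert_allclose(vols, sphere.volume * s**3, rtol=1e-9)
    np.testing.assert_allclose(sphere.volume, 4 / 3 * np.pi * 2.0**3,
                               rtol=2e-2)
    assert abs(dvdt.sum()) < 1e-8  # cyclic conservation


def test_open_mesh_rejected(identity_model):
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]]) + 3.0
    with pytest.raises(ValueError):
        volume_curve(identity_model, verts, np.array([[0, 1, 2]]))


# -------------------------------------------------------------- choose_modes
def test_single_sinusoid_needs_one_mode():
    t = np.arange(16)
    assert choose_modes(np.sin(2 * np.pi * t / 16)) == 1


def test_constructed_spectrum_with_96_percent_in_four_modes():
    t = np.arange(64)
    w = sum(np.cos(2 * np.pi * f * t / 64) for f in range(1, 5))
    w = w + np.sqrt(1 / 6) * np.cos(2 * np.pi * 5 * t / 64)  # 4% of power
    assert choose_modes(w, threshold=0.95) == 4


def test_full_threshold_returns_exact_bandwidth():
    t = np.arange(32)
    w = np.cos(2 * np.pi * 3 * t / 32) + 0.2 * np.sin(2 * np.pi * 6 * t / 32)
    assert choose_modes(w, threshold=1.0) == 6


def test_constant_signal_needs_no_modes():
    assert choose_modes(np.full(20, 7.3)) == 0


def test_choose_modes_monotone_in_threshold(rng):
    w = rng.normal(size=32)
    ns = [choose_modes(w, th) for th in (0.5, 0.7, 0.9, 0.99)]
    assert all(a <= b for a, b in zip(ns, ns[1:]))


# -------------------------------------------------------------- suggest_grid
def test_suggest_grid_targets_midpoint_ratio():
    spacing, levels = suggest_grid(1.0, 40.0)
    assert spacing == 2.0
    assert 0.4 <= 1.0 / spacing <= 0.6
    # chosen level covers the extent at <= the suggested spacing
    assert 40.0 / (2**levels + 2) <= spacing


def test_suggest_grid_ratio_always_in_band(rng):
    for _ in range(20):
        feat = rng.uniform(0.1, 5.0)
        ext = rng.uniform(10, 200)
        spacing, levels = suggest_grid(feat, ext)
        assert 0.4 <= feat / spacing <= 0.6


def test_suggest_grid_rejects_nonpositive():
    with pytest.raises(ValueError):
        suggest_grid(0.0, 10.0)


# ------------------------------------------------------------ jacobian audit
def test_identity_audit_no_violations(identity_model, rng):
    lo, hi = identity_model.support_bounds
    pts = rng.uniform(lo, hi, size=(50, 3))
    report = jacobian_audit(identity_model, pts)
    assert report["violations"] == []
    np.testing.assert_allclose(report["min"], 8.0, atol=1e-9)


def test_injected_fold_reported(identity_model, rng):
    folded = identity_model.copy()
    folded.lattice[3, 3, 3, 0, :] -= 12.0  # strong local fold
    lo, hi = folded.support_bounds
    pts = rng.uniform(lo + 1, hi - 1, size=(300, 3))
    report = jacobian_audit(folded, pts, frames=[0.0])
    assert report["min"] <= 0
    assert len(report["violations"]) > 0


def test_volume_preserving_twist_mean_near_one():
    """Small solid-body-like rotation: mean det stays within 1e-2 of 1."""
    g, n_modes, P = 7, 1, 12
    lattice = np.zeros((g, g, g, 3, 3))
    coords = -4.0 + np.arange(g) * 4.0
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    lattice[..., 0, 0], lattice[..., 0, 1], lattice[..., 0, 2] = X, Y, Z
    theta = 0.05
    lattice[..., 1, 0] = -theta * Y  # linearised rotation about z
    lattice[..., 1, 1] = theta * X
    model = BSFModel(lattice, np.full(3, 4.0), np.full(3, -8.0), P, n_modes)
    pts = np.random.default_rng(2).uniform(1.5, 4.5, size=(200, 3))
    report = jacobian_audit(model, pts)
    assert abs(report["mean"] / 64.0 - 1.0) < 1e-2  # affine det is 4^3
    assert report["min"] > 0
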