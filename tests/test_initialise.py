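"""Initialisation: Fourier least squares, recentring, MLB hierarchy."""

import numpy as np
import pytest

from bsfourier import (TrajectorySet, fit_fourier, initialise, mlb_approximate,
                       mlb_grid_size, recenter)
from bsfourier.bspline import fourier_design_matrix
from bsfourier.errors import UnderdeterminedError
from bsfourier.initialise import samples_to_model
from bsfourier.mlb import mlb_evaluate


def _traj_from_model(model, refs, P=None):
    P = int(round(model.period)) if P is None else P
    frames = np.arange(P, dtype=float)
    pos = np.stack([model.evaluate(refs, t) for t in frames], axis=1)
    return TrajectorySet(pos, P)


# ----------------------------------------------------------------- Fourier fit
def test_constant_trajectory_gives_pure_dc():
    pos = np.broadcast_to(np.array([1.0, 2.0, 3.0]), (4, 10, 3)).copy()
    s = fit_fourier(TrajectorySet(pos, 10), n_modes=3)
    np.testing.assert_allclose(s.coeffs[:, 0, :],
                               np.tile([1.0, 2.0, 3.0], (4, 1)), atol=1e-10)
    np.testing.assert_allclose(s.coeffs[:, 1:, :], 0.0, atol=1e-10)
    np.testing.assert_allclose(s.residual_rms, 0.0, atol=1e-10)


def test_generate_and_refit_round_trip(random_model, rng):
    lo, hi = random_model.support_bounds
    refs = rng.uniform(lo, hi, size=(20, 3))
    traj = _traj_from_model(random_model, refs)
    s = fit_fourier(traj, random_model.n_modes)
    expected = random_model.fourier_coeffs(refs)
    np.testing.assert_allclose(s.coeffs, expected, atol=1e-8)


def test_undersampled_fit_is_rejected():
    pos = np.zeros((1, 5, 3))
    with pytest.raises(UnderdeterminedError):
        fit_fourier(TrajectorySet(pos, 5), n_modes=3)  # needs 7 frames


def test_out_of_band_mode_fits_pseudoinverse_projection(rng):
    """A pure mode-(N+1) trajectory fitted with N modes equals the explicit
    normal-equations solution and leaves a residual."""
    P, N = 12, 2
    t = np.arange(P)
    sig = np.cos(2 * np.pi * (N + 1) * t / P)
    pos = np.zeros((1, P, 3))
    pos[0, :, 0] = sig
    s = fit_fourier(TrajectorySet(pos, P), N)
    D = fourier_design_matrix(t, N, P)
    beta = np.linalg.solve(D.T @ D, D.T @ sig)
    np.testing.assert_allclose(s.coeffs[0, :, 0], beta, atol=1e-10)
    assert s.residual_rms[0] > 0.1


def test_fit_residual_non_increasing_in_modes(rng):
    P = 16
    pos = rng.normal(size=(5, P, 3))
    traj = TrajectorySet(pos, P)
    res = [fit_fourier(traj, N).residual_rms.mean() for N in range(0, 6)]
    assert all(a >= b - 1e-12 for a, b in zip(res, res[1:]))


# ------------------------------------------------------------------ recentring
def test_recenter_static_is_identity():
    pos = np.broadcast_to(np.array([1.0, 2.0, 3.0]), (1, 10, 3)).copy()
    s = recenter(fit_fourier(TrajectorySet(pos, 10), 2))
    np.testing.assert_allclose(s.coords, [[1.0, 2.0, 3.0]], atol=1e-10)


def test_recenter_maps_symmetric_oscillation_to_centre():
    P = 12
    t = np.arange(P)
    pos = np.zeros((1, P, 3))
    pos[0, :, 0] = 5.0 + 2.0 * np.sin(2 * np.pi * t / P)
    s = recenter(fit_fourier(TrajectorySet(pos, P), 2))
    np.testing.assert_allclose(s.coords, [[5.0, 0.0, 0.0]], atol=1e-10)


def test_recenter_equals_temporal_mean(random_model, rng):
    """The new coordinate equals dense temporal quadrature of the path."""
    lo, hi = random_model.support_bounds
    refs = rng.uniform(lo, hi, size=(5, 3))
    traj = _traj_from_model(random_model, refs)
    s = recenter(fit_fourier(traj, random_model.n_modes))
    P = random_model.period
    ts = np.linspace(0, P, 3000, endpoint=False)
    for i in range(5):
        path = random_model.evaluate(
            np.broadcast_to(refs[i], (len(ts), 3)), ts)
        np.testing.assert_allclose(s.coords[i], path.mean(axis=0), atol=1e-8)


# ------------------------------------------------------------------------- MLB
@pytest.mark.parametrize("levels,expected", [(2, 7), (3, 11), (4, 19)])
def test_mlb_grid_size_hierarchy(levels, expected):
    assert mlb_grid_size(levels) == expected


def test_mlb_grid_size_rejects_negative():
    with pytest.raises(ValueError):
        mlb_grid_size(-1)


def test_mlb_constant_reproduction(rng):
    pts = rng.uniform(0, 10, size=(40, 3))
    lat, _ = mlb_approximate(pts, np.full(40, 2.5), levels=3)
    np.testing.assert_allclose(lat, 2.5, atol=1e-9)


def test_mlb_single_sample_interpolated(rng):
    pt = np.array([[2.0, 3.0, 4.0]])
    lat, (lo, hi) = mlb_approximate(pt, np.array([5.0]), levels=3)
    u = (pt - lo) / (hi - lo)
    assert abs(mlb_evaluate(lat, u)[0, 0] - 5.0) < 1e-6


def test_mlb_residual_decreases_with_levels(rng):
    pts = rng.uniform(0, 1, size=(1000, 3))
    vals = np.sin(2 * np.pi * pts[:, 0]) * np.cos(np.pi * pts[:, 1]) + pts[:, 2]
    bbox = (np.zeros(3), np.ones(3))
    rms = {}
    for levels in (2, 4):
        lat, _ = mlb_approximate(pts, vals, levels, bbox=bbox)
        r = vals - mlb_evaluate(lat, pts)[:, 0]
        rms[levels] = np.sqrt(np.mean(r**2))
    assert rms[4] < rms[2]


def test_mlb_linear_reproduction(rng):
    pts = rng.uniform(0, 8, size=(60, 3))
    vals = 1.0 + 2 * pts[:, 0] - 0.5 * pts[:, 1] + 3 * pts[:, 2]
    lat, (lo, hi) = mlb_approximate(pts, vals, levels=3)
    q = rng.uniform(0.2, 0.8, size=(50, 3))
    phys = lo + q * (hi - lo)
    expected = 1.0 + 2 * phys[:, 0] - 0.5 * phys[:, 1] + 3 * phys[:, 2]
    np.testing.assert_allclose(mlb_evaluate(lat, q)[:, 0], expected, atol=1e-6)


def test_mlb_empty_samples_rejected():
    with pytest.raises(ValueError):
        mlb_approximate(np.empty((0, 3)), np.empty(0), 2)


# ------------------------------------------------------------------ initialise
def test_zero_motion_initialises_static_model():
    P = 10
    rng = np.random.default_rng(0)
    refs = rng.uniform(2, 8, size=(200, 3))
    pos = np.repeat(refs[:, None, :], P, axis=1)
    model = initialise(TrajectorySet(pos, P), n_modes=2, levels=2)
    assert np.abs(model.lattice[..., 1:, :]).max() < 1e-6


def test_initialise_round_trip_recovers_model(truth_model, rng):
    lo, hi = truth_model.support_bounds
    g = np.linspace(lo[0] + 0.1, hi[0] - 0.1, 10)
    refs = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    traj = _traj_from_model(truth_model, refs)
    model = initialise(traj, truth_model.n_modes, levels=2)
    # evaluate both models along fresh landmark paths
    q = rng.uniform(lo + 1, hi - 1, size=(30, 3))
    frames = np.arange(int(truth_model.period), dtype=float)
    errs = []
    for x in q:
        true_path = truth_model.evaluate(
            np.broadcast_to(x, (len(frames), 3)), frames)
        from bsfourier import map_to_reference
        res = map_to_reference(model, true_path[0], 0.0)
        fit_path = model.evaluate(
            np.broadcast_to(res.ref, (len(frames), 3)), frames)
        errs.append(np.sqrt(np.mean(np.sum((fit_path - true_path) ** 2, 1))))
    assert np.sqrt(np.mean(np.square(errs))) < 0.05  # voxels (1 mm spacing)


def test_initialise_lattice_size_matches_levels():
    P = 10
    rng = np.random.default_rng(1)
    refs = rng.uniform(0, 20, size=(100, 3))
    pos = np.repeat(refs[:, None, :], P, axis=1)
    model = initialise(TrajectorySet(pos, P), n_modes=4, levels=3)
    assert model.grid_shape == (11, 11, 11)
    assert model.lattice.shape[3] == 9  # 2N+1 slots


def test_direct_solve_agrees_with_mlb_on_smooth_data(truth_model):
    lo, hi = truth_model.support_bounds
    g = np.linspace(lo[0], hi[0], 8)
    refs = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    traj = _traj_from_model(truth_model, refs)
    from bsfourier.initialise import fit_fourier as ff, recenter as rc
    samples = rc(ff(traj, truth_model.n_modes))
    m1 = samples_to_model(samples, levels=2, method="mlb")
    m2 = samples_to_model(samples, levels=2, method="direct")
    x = np.array([3.0, 3.2, 2.8])
    np.testing.assert_allclose(m1.evaluate(x, 2.0), m2.evaluate(x, 2.0),
                               atol=0.1)
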