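"""scikit-learn-style estimator facade over the regularisation chain.

``BSFMotionModel`` is the one-object view of the pipeline: ``fit`` takes a
registration set (the displacement fields any pairwise registration
produced), runs forward marching, initialisation and consistency
correction, and exposes the fitted cyclic motion model; ``predict``
tracks points through the cycle and ``transform`` maps them between two
frames.  Hyper-parameters follow the sklearn convention (``get_params`` /
``set_params``, clonable), so the estimator composes with sklearn's
model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .consistency import consistency_correct, consistency_cost
from .fields import RegistrationSet
from .initialise import initialise
from .mapping import map_to_reference
from .marching import march, make_seeds
from .pipeline import track_landmarks

__all__ = ["BSFMotionModel", "regularise"]


class BSFMotionModel(BaseEstimator):
    """Cyclic spatio-temporal motion model fitted to registration fields.

    Parameters
    ----------
    n_modes : int, default 4
        Fourier frequency modes N; 2N+1 temporal basis functions.
    levels : int, default 3
        Multilevel B-spline refinement level; the control lattice has
        ``2**levels + 3`` nodes per axis (levels=3 -> 11^3).
    scheme : {"quadratic", "eulerian", "lagrangian", "gaussian"}
        Forward-marching weight family.
    stride, margin : int
        Marching seed sub-grid stride and border margin (voxels).
    sweeps : int, default 1
        Consistency-correction sweeps over the control nodes.
    fields : {"neighbours", "all"}, default "neighbours"
        Which pairwise fields drive the correction (the neighbour chain
        alone, or every field in the set).
    anchor : float, default 0.0
        Strength of the per-node Tikhonov anchor toward the initialised
        coefficients; use ~0.2 on noisy registration fields to keep the
        correction a local refinement.
    correct : bool, default True
        Whether to run the consistency correction after initialisation.
    seed : int, default 0
        Seed for the stochastic part of the inverse mapping.

    Attributes
    ----------
    model_ : BSFModel
        The fitted (corrected) motion model.
    init_model_ : BSFModel
        The model after initialisation, before correction.
    trajectories_ : TrajectorySet
        Forward-marched seed trajectories.
    cost_before_, cost_after_ : float
        Consistency cost at the sample nodes before/after correction.
    """

    def __init__(self, n_modes: int = 4, levels: int = 3,
                 scheme: str = "quadratic", stride: int = 4, margin: int = 0,
                 sweeps: int = 1, correct: bool = True, fields: str = "neighbours",
                 anchor: float = 0.0, seed: int = 0):
        self.n_modes = n_modes
        self.levels = levels
        self.scheme = scheme
        self.stride = stride
        self.margin = margin
        self.sweeps = sweeps
        self.correct = correct
        self.fields = fields
        self.anchor = anchor
        self.seed = seed

    def fit(self, X: RegistrationSet, y=None, seeds=None):
        """Fit the motion model to a :class:`RegistrationSet`."""
        if not isinstance(X, RegistrationSet):
            raise TypeError("X must be a RegistrationSet")
        if seeds is None:
            f0 = X.fields[0]
            lo, hi = f0.physical_bounds
            axes = [np.arange(lo[a] + self.margin, hi[a] - self.margin + 1e-9,
                              self.stride * f0.spacing[a]) for a in range(3)]
            if any(len(a) == 0 for a in axes):
                raise ValueError("stride/margin leave no marching seeds")
            g = np.meshgrid(*axes, indexing="ij")
            seeds = np.stack([a.ravel() for a in g], axis=-1)
        self.trajectories_ = march(X, seeds, scheme=self.scheme)
        self.init_model_ = initialise(self.trajectories_, self.n_modes,
                                      self.levels)
        if self.correct:
            self.model_, report = consistency_correct(
                self.init_model_, X, sweeps=self.sweeps, fields=self.fields,
                anchor=self.anchor)
            self.cost_before_ = report.cost_before
            self.cost_after_ = report.cost_after
        else:
            self.model_ = self.init_model_
            self.cost_before_ = self.cost_after_ = consistency_cost(
                self.model_, X)
        return self

    def predict(self, X, t: int = 0) -> np.ndarray:
        """Track points (n, 3) observed at frame ``t``; returns (n, P, 3)."""
        self._check_fitted()
        return track_landmarks(self.model_, X, t=t, seed=self.seed)

    def transform(self, X, t_from: int = 0, t_to: int = 0) -> np.ndarray:
        """Map points (n, 3) from frame ``t_from`` to frame ``t_to``."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(X)
        for i, x in enumerate(X):
            res = map_to_reference(self.model_, x, float(t_from),
                                   seed=self.seed)
            out[i] = self.model_.evaluate(res.ref, float(t_to))
        return out

    def score(self, X: RegistrationSet, y=None) -> float:
        """Negative consistency cost of the fitted model on ``X``."""
        self._check_fitted()
        return -consistency_cost(self.model_, X)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")


def regularise(reg: RegistrationSet, **params):
    """One-call regularisation: fit a :class:`BSFMotionModel` and return
    the corrected :class:`~bsfourier.model.BSFModel`."""
    return BSFMotionModel(**params).fit(reg).model_
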