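# bsfourier

Cyclic spatio-temporal regularisation of cardiac motion estimates, applied
as an add-on layer *after* pairwise image registration.

## The problem

Cardiac motion is usually estimated by registering each frame of a 3D+t
scan (echocardiography, embryonic ultrasound, light microscopy) to its
neighbours, giving a set of pairwise displacement fields
`dX[t -> t+dt]`.  Accumulating those fields to track tissue points
suffers from drift, frame-to-frame inconsistency, and a tracked cycle
that does not close — the myocardium must return to its starting state
after one beat.  `bsfourier` fits a global **B-splines-of-Fourier (BSF)**
motion model to the registration output, enforcing spatial and temporal
smoothness, exact cyclicity, and mutual consistency of all the pairwise
fields, without touching the registration algorithm itself.

## The model

The position of a material point over the cycle is a truncated Fourier
series in time,

    X(t) = sum_{f=0..N} F_f cos(2 pi f t / P) + F_{f+N+1} sin(2 pi f t / P),

whose coefficient triples `F_f` vary over space as a tensor-product cubic
B-spline of a regular control lattice `C[i, j, k, f]` defined on a
*reference frame* anchored at each point's temporal mean position (the
0th-order Fourier term).  Fitting proceeds in three stages:

1. **Forward marching** — pairwise displacements are accumulated into
   sample-point trajectories, blending an Eulerian estimate (neighbour
   fields, sampled at the moving point) with a Lagrangian estimate
   (frame-0 fields, sampled at the seed) via the quadratic weight
   `w(t) = (P - t) t / (P/2)^2` (Eulerian, Lagrangian, and Gaussian
   weight families are also provided).
2. **Initialisation** — each trajectory is least-squares fitted with the
   Fourier basis (Moore-Penrose pseudoinverse), re-anchored at its
   temporal mean, and the scattered coefficients are approximated onto
   the lattice by multilevel B-splines (a 1-node seed grid that doubles
   per level with 3 extra nodes at the final level: 7/11/19 nodes per
   axis at levels 2/3/4).
3. **Consistency correction** — at every control node the coefficient
   block is refined by Levenberg-Marquardt so that the model-implied
   frame-to-frame motion agrees with every (weighted) displacement field
   sampled at the model-predicted positions; the lattice is then rebuilt
   by a pseudoinverse solve.  Extra highly-weighted fields — e.g. a
   registration between end-diastolic and end-systolic segmentations —
   can be appended to constrain stroke volume.

Tracking any physical point first maps it into the reference frame
(Levenberg-Marquardt descent of the squared Euclidean distance, converged
below 1e-6) and then evaluates the model at every frame.

## Worked example

Everything is testable without data downloads: the synthetic module draws
a smooth fold-free cyclic ground-truth motion, samples pairwise fields
from it (optionally with spatially-correlated registration noise), and
produces ground-truth landmark tracks.

```python
import numpy as np
from bsfourier import (BSFMotionModel, make_ground_truth,
                       make_registration_set, make_truth_tracks)

truth = make_ground_truth(grid=24, period=12, n_modes=2, amplitude=2.0, seed=0)
reg = make_registration_set(truth, grid=24, noise=0.5, corr_length=5.0, seed=1)

est = BSFMotionModel(n_modes=2, levels=2, stride=2, margin=3,
                     fields="all", anchor=0.2).fit(reg)
print(f"consistency cost: {est.cost_before_:.1f} -> {est.cost_after_:.1f}")
print(f"control lattice:  {est.model_.grid_shape}, "
      f"{est.model_.lattice.shape[3]} Fourier slots per node")

tracks = make_truth_tracks(truth, 20, seed=2, margin=1.0)
pred = est.predict(tracks.truth[:, 0, :], t=0)
rmse = np.sqrt(np.mean(np.sum((pred - tracks.truth) ** 2, axis=2)))
print(f"landmark RMSE vs ground truth: {rmse:.3f} voxels")
```

prints

```
consistency cost: 1420.5 -> 664.1
control lattice:  (7, 7, 7), 5 Fourier slots per node
landmark RMSE vs ground truth: 0.227 voxels
```

The cost is the weighted disparity between the model's frame-to-frame
motion and the noisy registration fields; it halves after correction.
The tracking error of 0.23 voxels is well below both the injected
registration noise (0.5 voxels per field) and the error of raw forward
marching (~0.8 voxels under the same conditions) — the regulariser pools
information across the whole cycle.  `bsfourier.replicate_study` repeats
this comparison over seeded replicates; the median error ordering
*corrected < initialised < marched* is part of the test suite.

The same chain is available from the shell:

```
bsf simulate --grid 24 --frames 12 --noise 0.5 --out sim/
bsf march --manifest sim/manifest.json --stride 2 --margin 3 --out traj.csv
bsf init --traj traj.csv --modes 2 --levels 2 --out model.bsf
bsf correct --model model.bsf --manifest sim/manifest.json --out model_cc.bsf
bsf track --model model_cc.bsf --landmarks sim/truth.csv --out tracks.csv
bsf evaluate --tracks tracks.csv --truth sim/truth.csv
```

plus `bsf boundary` (stroke-volume constraint from ED/ES masks),
`bsf sync` (phase synchronisation of 2D cine slices into 4D stacks),
`bsf map`, and `bsf run` (whole pipeline from a JSON config).

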