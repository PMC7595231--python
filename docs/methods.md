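# Methods

This note documents the model, the numerical choices, and the synthetic
study design behind `bsfourier`, in the spirit of a methods appendix: what
the code computes, which knobs matter, and what the tests do and do not
demonstrate about real data.

## The B-splines-of-Fourier motion model

A material point's position over one cardiac cycle of period `P` frames is

    X(t) = sum_{f=0}^{N} F_f(X_ref) cos(2 pi f t / P)
         + sum_{f=1}^{N} F_{f+N}(X_ref) sin(2 pi f t / P),

with each coefficient triple a tensor-product uniform cubic B-spline of a
regular control lattice.  We store `2N + 1` frequency slots per node
(cosines f = 0..N, sines f = 1..N); the identically-zero sin(0) slot is
omitted so every least-squares design matrix stays full rank.  The output
of the model is an absolute position, not a displacement: the 0th-order
(DC) coefficient field *is* the reference-frame anatomy, anchored at each
point's temporal mean position.  Periodicity is exact by construction —
evaluations at `t` and `t + P` agree to machine precision — and the model
is linear in the lattice.

**Coordinates.**  The reference domain uses lattice units (control nodes
at integer coordinates), linked to physical mm by a per-axis spacing and
origin.  With `G` nodes per axis the valid query region is `[1, G-2]`
(full 4x4x4 support); queries within half a cell beyond are clamped, and
anything farther is an error carrying the offending coordinate.  Time is
counted in frames with `P` = frames per cycle (frame `P` coincides with
frame 0); a seconds-based convention only rescales the frequencies.

**Derivatives.**  The spatial Jacobian uses the analytic B-spline
derivative basis; `det(J) > 0` everywhere indicates a locally invertible
(diffeomorphic) deformation and `det(J) = 1` incompressibility.
`jacobian_audit` samples points x frames and reports minimum, mean, and
violations.

## Forward marching

The recursion

    X[t+1] = w(t) (X[t] + dX[t->t+1](X[t])) + (1 - w(t)) (X[0] + dX[0->t+1](X[0]))

blends an Eulerian estimate (neighbour-frame field sampled at the moving
point) with a Lagrangian one (frame-0 field sampled at the seed).
`w == 1` and `w == 0` recover the pure schemes; the default quadratic
weight `w(t) = (P-t) t / (P/2)^2` trusts the Lagrangian registration near
both ends of the cycle (where the frame-0 image is most similar) and the
Eulerian chain mid-cycle.  A Gaussian-shaped family
`w(t) = (1 - exp(-t (P-t) / (2 sigma^2)))`, normalised to 1 at mid-cycle
(`sigma` defaults to `P/4`), is provided for completeness; no canonical
form for it exists, and after consistency correction the choice of
weighting family has a sub-0.1 % effect, so none is recommended over
another.  Field sampling is trilinear with clamp-to-edge boundaries.

## Initialisation

Each marched trajectory is fitted per Cartesian axis by the trigonometric
design system (`P` rows, `2N+1` columns) via an SVD pseudoinverse with
relative cutoff 1e-10; `P >= 2N + 1` is required.  Each sample is then
re-labelled with its temporal mean position (the DC coefficient), which
defines the motion-centred reference frame; the fit is not re-run in the
new frame — the relabelling is exactly the change of anchor the model
needs.  Finally every coefficient channel (`(2N+1) x 3`, independently) is
approximated onto the lattice by **multilevel B-splines**: level `h` has
`2^h` cells (`2^h + 3` nodes) per axis; each level applies the local
weighted least-norm control-point assignment to the residuals of the
previous levels, and the accumulated surface is carried upward by exact
cubic-subdivision refinement.  An affine baseline is fitted first and
added back at the node positions, so constant and linear fields are
reproduced exactly even where samples are sparse.  A direct pseudoinverse
solve of the lattice is available behind a flag for testing; it is less
stable than the multilevel scheme on irregular samples.

The lattice cells span the seed bounding box exactly; the outer ring of
nodes (outside the valid query region) provides the one-cell margin.  We
deliberately do not pad the cell span: padding places control nodes in
regions where the registration fields carry no data, which destabilises
the correction (below).

## Consistency correction

Fourier truncation moves the model away from the raw registration; at the
positions the model itself predicts, the fields prescribe displacements
the model should honour.  At every sample point (control-node reference
positions by default; a denser stride-based set is available) we minimise

    1/2 sum_fields || w (X(t+dt) - X(t)) - w dX[t->t+dt](X(t)) ||^2

over that sample's coefficient block alone — the blocks are independent,
so the optimisation is node-by-node — with a damped Levenberg-Marquardt
(damping 1e-3, x10 on rejection, /10 on acceptance, at most 100
iterations, relative-cost stop 1e-8, absolute floor 1e-18).  The Jacobian
is analytic in the trigonometric part and uses the field's spatial
gradient (analytic for synthetic exact fields, central differences for
gridded ones).  The lattice is then rebuilt by solving the B-spline
blending system for the minimum-norm *update* relative to the current
lattice (same SVD cutoff), which reproduces the optimised blocks exactly
at the samples while leaving weakly-constrained boundary nodes at their
initialised values.  The reported cost therefore never increases; this is
asserted on every run.

By default only the neighbour-chain fields with uniform weight
participate; any extra weighted field is included by selecting
`fields="all"` or passing an explicit list.  The stroke-volume constraint
is such an extra field: both segmentation masks are binarised, smoothed
with a 9x9x9 Gaussian kernel of standard deviation 2 voxels (soft edges),
registered by a user-supplied callback, and the resulting field labelled
ED->ES enters with weight 10 — strong enough to pin the volume extremes
without constraining the path between them.

**Domain barrier.**  Clamp-to-edge sampling creates a degenerate optimum:
outside the data domain a constant-offset trajectory reproduces the
clamped edge displacement exactly at zero cost, so a fully converged
node optimisation on noisy fields can walk out of the image.  Extra
residual rows penalise the per-axis excess of the model-predicted
positions outside each field's domain (weight 10x the field weight).
They are identically zero for any model that stays inside the data, so
noise-free behaviour is untouched.

**Anchored (MAP) mode.**  With noisy fields the fully converged node
optimum can sit far from the initialisation even inside the domain (the
cost constrains frame-to-frame *differences* strongly but absolute
position only through the fields' spatial gradients).  The option
`anchor=a` appends rows `a ||w||_2 (F - F_init)` — a Tikhonov prior
holding the refinement near the initialised coefficients; scaling by the
weight norm keeps the argmin invariant under uniform weight rescaling.
The default is `anchor=0` (the pure formulation, whose optimum is exact
on noise-free fields); `anchor=0.2` is the configuration used by the
noisy-data benchmark and recommended for real registration output.
Because the anchored objective equals the data cost at the start, the
data-cost non-increase guarantee is preserved.

## Inverse mapping and tracking

To track a point observed at physical `x` at time `t`, Levenberg-Marquardt
descends the squared Euclidean distance between the trial reference
coordinate's evaluation and `x`, starting from `x` mapped through the
inverse lattice affine, clamped to the support.  Convergence is declared
below 1e-6 (squared mm); smooth models need a handful of iterations
(median 1 on our synthetic audits, far below 50).  If progress stalls
above the threshold, a seeded Gaussian jitter of 0.25 lattice units
perturbs the iterate — degenerate flat regions are escaped while runs
stay reproducible.  The track is then the model evaluated at the mapped
reference coordinate for every frame; it is cyclic by construction.

## Model-selection guidelines

`choose_modes` picks the smallest `N` whose Fourier modes 1..N carry at
least 95 % (configurable) of a waveform's dynamic spectral power (the DC
term carries no motion and is excluded); applied to a ventricular
inflow/outflow waveform this keeps the E- and A-wave features, and N >= 4
is the typical outcome for fetal-like inflow profiles.  `suggest_grid`
targets a feature-length/grid-spacing ratio of 0.5 (band 0.4-0.6 — one
feature within one standard deviation of the Gaussian approximation to a
cubic B-spline, sd ~ 0.577 cells) and returns the smallest refinement
level whose cells cover the domain at no more than that spacing.

## Evaluation utilities

The landmark error is the temporally averaged Euclidean distance to
ground truth over the closed cycle: the printed normalisation sums frames
t = 0..P (the endpoint duplicating frame 0) and divides by `P`, so a
constant 1 mm offset reads (P+1)/P mm; an `"open"` convention (mean over
the P distinct frames) is available.  Manually tracked ground-truth
landmarks that do not move for more than 3 consecutive frames are
excluded (a likely annotation artefact), and an observer's whole block is
dropped when more than half its landmarks are excluded.  Dice overlap,
mesh volume curves (divergence-theorem volume of the deformed surface per
frame, spectral temporal gradient — which integrates to zero over the
cycle), and the det(J) audit complete the toolbox.

## Synthetic data: what it emulates, and what it does not

`make_ground_truth` draws a fold-free cyclic motion in the model class
itself: identity DC channel, spatially low-pass random dynamic channels
with 1/(1+f) amplitude decay, peak displacement = `amplitude` (audited
for `det(J) > 0`; folding amplitudes are damped with a warning).
`make_registration_set` produces the neighbour chain and frame-0 fields:
with `noise=0` the fields carry an exact analytic sampler
(inverse-mapping the generator, Newton iterated to ~1e-12) and are
therefore exactly consistent with the model at any position — gridded
storage alone cannot be, since trilinear interpolation of a smooth
nonlinear field errs at the 1e-2-voxel level; with `noise>0` the fields
are gridded values plus Gaussian noise filtered to a correlation length
of `corr_length` voxels and scaled to `noise` voxels pointwise, drawn
independently per field.  Spatially-correlated noise mimics the smooth
errors of real registration; what it does *not* capture is the
anatomy-locked, temporally shared error structure of real registration
(which tends to favour the consistency correction), image-derived effects
(shadowing, signal dropout, valve blur), or through-plane acquisition
artefacts.  Passing tests therefore demonstrate correctness and the
qualitative stage ordering of the machinery, not clinical accuracy
figures.

Study conditions, chosen once: the noise-free parameter-recovery run uses
a 64^3 voxel domain, P = 28, N = 4, levels = 3 (11^3 lattice), seeds on a
stride-3 grid with a 10-voxel margin; the noisy replicate benchmark uses
a 24^3 domain, P = 12, N = 2, levels = 2 (7^3), amplitude 2 voxels,
sigma = 0.5 voxel, correlation length 5 voxels, 20 landmarks, 20 seeded
replicates, with the correction in anchored mode on all fields.  The
phantom is an ellipsoidal shell with optional multiplicative speckle,
rendered by inverse-mapping each voxel per frame, with cavity masks at
the extreme-volume (ED/ES) frames.

## Slice synchronisation

Asynchronously acquired 2D cine slices are aligned by the zero-mean
normalised cross-correlation map between two slices' frames: each frame's
circularly-unwrapped best match in the other slice defines offset
samples, and the intercept of a slope-1 line (circular mean of the
offsets) is the fractional phase shift — the slope is fixed at 1 because
the slices share a frame rate.  Large regression residuals raise a
low-confidence flag.  Stacking applies cumulative shifts by circular
linear temporal resampling with slice 0 as the phase anchor; noiseless
integer shifts are recovered exactly.

## Known limitations

- The cyclic prior is wrong for arrhythmic cycles; nothing in the model
  can represent beat-to-beat variation.
- Accuracy is bounded by the pairwise registration quality; the
  correction redistributes information but cannot manufacture it.
- Diffeomorphism is audited, not enforced; a strongly folded registration
  input can produce a folded model.
- Only axis-aligned image geometries are supported in IO.
- The node-wise correction treats blocks independently; a jointly coupled
  solve might extract slightly more from very noisy data at much higher
  cost.
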