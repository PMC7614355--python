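# Methods

## Problem and model

`metareg` implements weakly-supervised, volume-to-sparse deformable
registration whose network initialization is meta-learned so that a few
gradient steps on interactively acquired sparse slices adapt it to a new
subject.  The motivating application is alignment of a pre-operative 3D
volume (e.g. MR) to a handful of intra-operative 2D frames (e.g. a TRUS
probe sweep) at known positions.

A registration network `f_phi` maps a stacked input — source image,
frame-masked target image, and a binary acquisition mask channel — to a
dense displacement field (DDF) `u(x)` on the target grid.  The warped
source is resampled at `x + u(x)` (backward/pull-back warping, trilinear
interpolation, clamp-to-edge).  Displacements are expressed in voxels;
physical spacing enters only when converting Gaussian scales from mm and
reporting registration error in mm.

### Training objective

With intensity similarity deliberately disabled (the two "modalities"
share no usable intensity relationship), the loss is

    L = alpha_label * (1 - MSD(warp(l_src, u), l_tgt)) + alpha_def * BE(u)

* **MSD** — multiscale soft probabilistic Dice: both label maps are
  smoothed by an isotropic Gaussian at each scale `sigma` of a fixed set
  and the soft Dice scores (squared-sum denominator, `eps = 1e-7`) are
  averaged.  Coarse scales inflate the overlap of near-miss structures,
  giving gradients even when labels do not intersect.  Default scale set
  {0, 1, 2, 4, 8, 16, 32} mm; the desk profile uses {0, 1, 2, 4} mm,
  scaled with its ~4x smaller grids.
* **BE** — bending energy: mean over interior voxels, summed over the
  three displacement components, of
  `dxx^2 + dyy^2 + dzz^2 + 2(dxy^2 + dxz^2 + dyz^2)` by central
  differences in voxel units.  Exactly zero for any affine field.
* Both weights default to 1.0.

Inside the loss, Gaussian smoothing uses zero (constant-value) padding:
a symmetric kernel with zero padding is an exactly self-adjoint linear
operator, so the analytic gradient of MSD is exact.  The public
`gaussian_filter3d` defaults to reflective boundaries (which preserve
constants); for the interior-supported labels this is immaterial, and
the loss path exposes the `constant` mode explicitly.

### Network

A compact 3D encoder–decoder with skip connections stands in for the
LocalNet family.  `levels` 2x-pooling stages double `base_channels` each
stage; each decoder resolution carries a 3-channel displacement head,
and the per-scale fields are trilinearly upsampled and summed — the
defining property (a DDF summed over multiple resolutions) without
replicating any particular block inventory, since the meta-learning
protocol is network-agnostic.  Heads are zero-initialized so the
untrained network predicts the identity transform, which stabilizes
early meta-training.  The masked target is zero-filled outside acquired
frames and an explicit binary mask channel distinguishes "zero
intensity" from "not acquired".

Because no deep-learning framework is part of the runtime, the network
and loss run on a small reverse-mode automatic-differentiation engine
(`_autodiff.py`) written for exactly these ops.  Every analytic
gradient is tested against central finite differences, and every linear
op's backward pass against the adjoint identity `<Ax, y> = <x, A'y>`.
Training may run in float32 (`set_default_dtype`); metrics and tests
default to float64.

### Interaction model

An interaction is a set of `F` acquired frames (2D slices along the
volume's slice axis).  During meta-training, `F ~ U[F_min, F_max]` and
frames are drawn without replacement from the slices intersecting the
gland segmentation.  At meta-test, acquisition is a deterministic
single sweep: `F_max` positions uniformly spaced across the gland
extent, visited in descending slice order.  Update `j` of few-shot
adaptation uses the first `F_min + j - 1` frames (the first update uses
`F_min` = 2 frames, providing minimal spatial context; the last uses
`F_max - 1`), and inference runs with all `F_max`, so adaptation costs
exactly `F_max - F_min` gradient updates.

### Meta-learning

Reptile over per-subject tasks.  One episode: sample a task, snapshot
`phi`, run `k` inner Adam steps (fresh optimizer state per episode;
snapshots are weight-space objects) on freshly sampled interactions of
that task, then

    phi <- phi - beta_meta * mean_m (phi - phi*_m),

with the mean taken over all `k` intermediate snapshots (the default
reading of the update); `final_only=True` selects the common variant
that uses only the last snapshot.  `beta_meta` decays linearly
from 0.5 to 1e-5 over the episodes.  During meta-training the loss uses
the *complete* target labels (the input stays sparse), so the
initialization learns from full supervision; at meta-test only the
sparse gland label on acquired frames drives adaptation, with both the
warped source label and the target label masked to those frames
(slice-restricted similarity).

For `k = 1` the procedure reduces exactly to joint training over the
task mixture with step `beta_meta * beta_task` (verified against an
explicit joint loop in the tests).

## Synthetic study conditions

No clinical data ship with the package; the generator produces
per-subject tasks with the statistical structure the method assumes:

* a randomized superellipsoid gland (per-subject centre, radii,
  exponent; soft boundary) with 2–4 spherical landmarks (two at the
  poles along the slice axis, emulating apex/base, plus interior
  structures), radius 2 voxels;
* a ground-truth pull-back field: random translation (12% of grid
  extent per axis) plus a Gaussian-smoothed random control-point
  residual with peak 15% of extent, rejected/rescaled until the
  Jacobian determinant of `x + u(x)` is positive everywhere.  These
  magnitudes were fixed so that unregistered misalignment is comparable
  to the gland radius — the severity regime of the clinical problem —
  and so the unregistered gland Dice stays below 0.9 on average;
* two renderings: the source with smooth contrast and mild additive
  noise; the target with an inverted, compressed contrast curve and
  multiplicative speckle-like noise, so intensity similarity is
  uninformative and the label-driven loss must do the work.

What the generator does **not** emulate: biomechanically plausible
prostate deformation, ultrasound physics (shadowing, anisotropic point
spread), probe-pressure artifacts, segmentation errors in the target
labels, or pose noise in frame positions.  Passing tests therefore show
that the meta-learning mechanism works under the assumed statistical
structure, not that clinical accuracy transfers.

## Profiles and problem sizes

The `paper` preset records the clinical-scale protocol (0.8 mm spacing,
F in [2, 10], minibatch 4, inner Adam rate 1e-5, 25 000 episodes).  All
experiments that actually run here use the `desk` preset, chosen for a
single CPU: 16^3 grids at 1 mm, F in [2, 6], scale set {0, 1, 2, 4} mm,
`k = 10`, minibatch 2, inner Adam rate 1e-3 (a few hundred episodes in
place of 25 000 requires a proportionally larger step), meta step 0.5
decaying to 1e-5, cohorts of 30 training / 20 test subjects.  The
headline comparison trains one initialization per cohort seed and
evaluates four regimes on the shared held-out tasks: no registration
(identity), gland-centroid translation, meta-init with and without
few-shot adaptation, and a random init with few-shot adaptation.

## Numerical choices and edge cases

* Soft Dice of two identically-zero labels is 0 by the eps convention.
* Warping clamps to the volume edge; a clamped coordinate axis
  contributes zero gradient for that axis only.
* Gaussian kernels truncate at 3 sigma; sigma = 0 is the identity.
* Bending energy requires at least 3 voxels per axis (central second
  differences) and is normalized by interior-voxel count, making its
  magnitude grid-size independent.
* Affine augmentation resamples until the linear part has positive
  determinant (no flips); bounds default to <=10 deg rotation, scale in
  [0.9, 1.1], shear <=0.05, translation <=5% of extent.
* Fold-free ground-truth fields: draws with a non-positive Jacobian
  determinant are rescaled by 0.7 and redrawn (up to 20 attempts).
* Episodes with non-finite inner losses are logged and skipped; the
  outer loop continues from the pre-episode weights.

## Known limitations

* The stand-in network is far smaller than LocalNet/VoxelMorph; absolute
  desk-scale errors are not comparable to clinically reported
  registration errors, only the orderings and trends are meaningful.
* Reptile only; second-order meta-gradients (MAML/FOMAML) are out of
  scope.
* Isotropic spacing only; no diffeomorphic parameterization, no
  sequential modelling of interaction history, and no pose noise on
  frame positions.
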