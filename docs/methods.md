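# Methods

## Model and assumptions

The classifier treats a 3D intensity volume as three ordered sequences of
2D slices, one per anatomical view.  The working assumptions are:

* adjacent slices are strongly correlated (no rigid registration is
  performed, so discriminative structure is *spatially smeared* across
  neighbouring slices rather than pinned to fixed coordinates);
* class-discriminative signal is focal — localised intensity deficits on
  a smooth baseline — so 2D convolutional features of single slices carry
  most of the information, while the ordering of slices carries the rest;
* labels are per subject, but every slice of a subject can inherit that
  label for pre-training, at the cost of label noise in slices that carry
  no signal (this is why weak slice groups are pruned afterwards).

Stage 1 (intra-slice): the slice sequence of a view is cut into
overlapping groups — by default 15 slices per group with stride 9, i.e. a
6-slice overlap between neighbours — and each group is given its own 2D
CNN sharing one architecture.  The reference architecture is five 3×3
unpadded convolutions (filters 16, 16, 32, 32, 64; the first with stride
2), 2×2/2 max-pooling after the second and fourth, dense layers of 512
and 256 units and a 2-way softmax; on a 1×150×150 slice the layer sizes
are 74, 72, 36, 34, 32, 16, 14, 12544, 512, 256, 2.  The windowed
arithmetic `out = floor((in − k)/s) + 1` is only consistent with *valid*
(unpadded) convolution, so padding is not configurable.  Training is SGD
with momentum 0.9 and L2-coupled weight decay, cross-entropy loss,
dropout before each dense layer, Xavier-uniform initialisation, and early
stopping on slice-level validation error.

Stage 2 (inter-slice): each retained group contributes m = 4 equally
spaced slices (indices `round(j·(L−1)/(m−1))`, halves up); their 256-d
embeddings from the frozen CNNs are spliced, in ascending slice order,
into one feature sequence per (subject, view).  The sequence model is two
stacked bidirectional GRU layers — the cell is bias-free, exactly the
update/reset-gate recurrence documented in `slicegru.gru` — whose
per-step outputs (forward state and time-aligned backward state,
concatenated, dimension 2H) feed two dense layers and a softmax.  It is
trained with Adam on subject labels; the CNNs stay frozen.

Fusion: the three view scores are combined by a weighted average with
weights grid-searched over the probability simplex (step 0.1, 66
candidates) to maximise fused validation accuracy; ties break toward the
most uniform triple, then lexicographically.  Because the grid contains
the degenerate corners (1,0,0) etc., fused validation accuracy can never
fall below any single view's.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| group size L / stride s | 15 / 9 | slices | window wide enough for inter-slice context, overlap 6 smooths group boundaries |
| crop | 150 (reference), 48 (desk) | pixels | common in-plane size so all group CNNs share one architecture |
| feature layer | second dense (256-d) | – | the last hidden layer; the 512-d first dense layer is selectable |
| m slices per group | 4 | slices | recurrent input length per group; equal spacing spans the window |
| hidden units H | 256 (reference), 32 (desk) | – | recurrent state width |
| pruning threshold | 0.55 | slice-level val. accuracy | drops groups near chance for binary tasks; best group always kept |
| CNN optimiser | SGD, lr 1e-4, momentum 0.9, decay 1e-6, batch 40 | – | reference settings; desk runs raise lr to 2e-3 and cap epochs at 8 so small phantom runs converge in minutes |
| sequence optimiser | Adam, lr 1e-3, batch 40 | – | standard for recurrent heads |
| dropout | 0.5 dense (reference), 0.3 desk; 0.2 on BGRU inputs/outputs | – | regularisation; none on recurrent connections |
| early-stopping patience | 10 (reference), 3/8 (desk CNN/GRU) | epochs | stop when validation error stops decreasing |
| occluder square / stride | 25 / 12 (reference), 8–12 / 4–6 (desk) | pixels | stride ≈ half the square balances resolution and cost |

## Synthetic phantoms

`slicegru.synthetic` generates the study conditions: 48³ volumes, 40
subjects per class, a shared smooth baseline (plateau 1.5 plus broad
Gaussian bumps, per-subject amplitude jitter 3%), three ellipsoidal
deficit regions of radius 6 voxels where class-1 subjects lose 0.8
intensity units, additive Gaussian noise (SD 0.3) clipped at zero, and a
random integer translation of up to 3 voxels per subject standing in for
the absence of rigid registration.  `region_truth` records each subject's
post-jitter deficit mask and is the ground truth for attention tests.

What the phantoms do *not* emulate: scanner point-spread and partial
volume effects, attenuation, anatomical variability beyond translation,
multi-site intensity differences, and class overlap in region topology.
Passing tests therefore demonstrate that the machinery recovers a planted,
well-posed focal contrast under jitter and noise — not clinical
performance on real cohorts.

## Numerical choices

* All arithmetic is float64; the recurrent forward pass matches a
  scalar-loop evaluation of the gate equations to < 1e-10 (tested on 200
  random instances).
* The recurrence is bias-free by default (the trainable cell has an
  optional bias flag; oracle tests run bias-free).  The candidate
  activation is tanh — required for the interpolation
  `h = (1−z)h̃ + z·h_prev` to stay bounded.
* Centre-cropping drops (or zero-pads) the extra row/column on the
  high-index side when a margin is odd; slice indices are 0-based.
* Group windowing defaults to `drop_incomplete` (starts 0, s, 2s, … while
  a full window fits); `anchor_last` appends a window anchored at
  `n − L` when slices remain uncovered.  For the reference geometry the
  floor formula gives 20/16/17 groups for 193/153/163 slices; published
  counts of 20/17/18 for the same geometry imply some other unstated tail
  convention, so both policies are provided and neither is claimed
  canonical.
* The view-to-axis mapping is explicit on every `Volume` (default
  sagittal/coronal/axial → 0/1/2, derived from the NIfTI affine when one
  is present).  The reference 193×153×163 brain box is stored
  coronal-first, i.e. `{coronal: 0, sagittal: 1, axial: 2}`.
* Ties in the fusion grid break toward uniform weights; ties in pruning
  and top-group selection break toward the lower group index.
* The occlusion grid starts at offset 0 with an extra border-anchored
  position so edges are always covered; rendering assigns each pixel the
  drop of the nearest occluder centre.  Maps are computed only for
  correctly classified subjects (drops are sign-ambiguous otherwise) and
  aggregated by per-voxel means.
* `compute_metrics` flags SEN/SPE as undefined (None) rather than 0 when
  a class is absent; the ROC is a threshold sweep whose trapezoidal area
  equals the tie-aware pair-counting statistic exactly.

## Desk-scale experiment design

`slicegru.experiments` fixes the reference phantom studies: the
three-view signal run uses one rotation of the stratified 10-fold
protocol (8 test subjects); the null run (effect size 0) pools the test
folds of four rotations — each subject still tested exactly once — so the
Monte-Carlo 95% null band for the pooled AUC (n = 32) is informative; the
attention study trains a single-view model per seed on 20 subjects per
class at effect 1.0 and checks that the aggregate attention peak falls
inside the union of contributing subjects' deficit masks dilated by half
the occluder side.  Layer widths are scaled down (8/8/16/16/32 filters,
64/32 dense, H = 32) while keeping every structural element; the 150×150
reference architecture is used as-is for all shape arithmetic.  These
sizes keep a full run in the minutes range on one CPU.

## Known limitations

* The five-convolution topology needs inputs of at least 45×45; smaller
  slices require a custom (shallower) architecture.
* The numpy implementation is single-threaded beyond BLAS and not suited
  to full-resolution (150×150, 256-d, 20-group) training; the reference
  settings are provided for fidelity of specification, not for speed.
* The sequence model requires equal-length sequences across subjects
  (same retained groups), which holds when all volumes share a common
  shape — heterogeneous cohorts must be resampled/cropped to a common
  grid first.
* Fold-level metric averaging and pooled-score AUC can differ on small
  folds; the experiment drivers report pooled quantities and say so.
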