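# Methods

## The problem and the model

Proteins imaged by cryo-electron microscopy are averages over many
instantaneous conformations: regions that fluctuate strongly are blurred in
the reconstructed density, and regions that are rigid are sharp.  cryoflex
exploits this physical coupling to predict per-atom structural flexibility —
the root-mean-square fluctuation

    RMSF_i = sqrt( (1/T) * sum_t || x_i(t) - x̃_i ||^2 )

of atom *i* about its mean position x̃_i — directly from a cryo-EM density
map and the atomic model fitted to it, without running molecular dynamics.

The predictor is a 3D UNet++ with three down-sampling levels (L3) applied to
40^3-voxel density boxes.  The map and the model are combined as input
channels; four variants are supported:

| variant | channels | input |
|---------|----------|-------|
| `cryo`  | 1 | experimental density |
| `pdb`   | 1 | simulated density of the fitted model |
| `pdb01` | 2 | one-hot encoding of the 3-sigma-thresholded simulated map |
| `dual`  | 2 | experimental + simulated density (the flagship) |

Two auxiliary networks make the cryo-only route interpretable: `occ`
predicts per-voxel structure occupancy probabilities (2 x 40^3, softmax) from
the density alone, and `occ2rmsf` feeds those two probability channels —
with the occupancy network frozen — into a second-stage RMSF regressor.

## Pipeline

1. **Resampling.**  Maps are resampled to an isotropic 1.5 Å voxel size
   (about one heavy atom per voxel) with order-3 spline interpolation and
   edge-value padding; the world origin is preserved.  Axis order is
   normalized to (x, y, z) on reading, honoring the MRC axis-correspondence
   header; the origin comes from the ORIGIN record, falling back to start
   indices x voxel size.
2. **Simulated model density.**  Each heavy atom contributes an isotropic
   Gaussian with standard deviation 0.225 x nominal resolution (the molmap
   convention), integral equal to its atomic mass, truncated at 4 sigma.
   The default nominal resolution is 5 Å for synthetic data; for
   experimental maps the deposited resolution should be passed.
3. **Binarization (pdb01).**  sigma is the standard deviation of the
   simulated map's values about their mean; voxels above 3 sigma are encoded
   1 and the map is expanded to two one-hot channels.
4. **Boxing.**  Grids are zero-padded by 15 voxels per side (plus far-side
   padding to a multiple of 10) and cut into 40^3 boxes on a stride-10
   lattice, so the 10^3 central subboxes tile the original grid exactly
   once and merging is exact and overlap-free.  A box is kept only if its
   central subbox contains at least one atom-occupied voxel (at inference
   the model-derived occupancy provides this screen).  Within each box,
   negative densities are clamped to zero and values divided by the box
   maximum.
5. **Ground truth.**  Ensembles are rigid-body aligned (Kabsch, proper
   rotations only): all frames to the first frame, then twice to the
   refined heavy-atom mean structure; RMSF is computed against the final
   mean.  Per-atom values are deposited on nearest voxels (collisions
   average), defining the label mask.
6. **Training.**  Masked MSE over labeled voxels (regression) or
   class-weighted cross-entropy with weights 0.05:0.95
   (occupancy).  Adam at learning rate 0.004, batch 32, Kaiming
   initialization, up to 100 epochs; the learning rate is halved after 10
   consecutive epochs without a strictly lower validation loss and again
   after 20; training stops after 30, restoring the minimum-validation
   parameters.  Mirror augmentation over the three axes (the 8 sign-flip
   combinations, labels transformed jointly) expands training data
   eightfold when enabled.  Cross-validation splits are made at the entry
   (map) level, never at the box level, with the remainder split 3:1 into
   train:val.
7. **Evaluation.**  Pearson correlation between predicted and reference
   RMSF at the voxel level (over the intersection of label masks) and at
   the residue level (after averaging atom values per residue).  Per-entry
   correlations are aggregated as mean/median/std across entries.  RMSF
   values are z-scored with the population standard deviation only for
   visualization and residue-profile comparison; training targets are raw
   Å, since Pearson evaluation is scale-free.

## Network

Each UNet++ node is one 3x3x3 convolution + batch normalization + ReLU
(configurable via `convs_per_block`); channel widths are base x {1, 2, 4, 8}
with base 16 by default (8 in the desk-scale studies); down-sampling is 2^3
max pooling and up-sampling trilinear interpolation.  Dense nested skips
follow the standard UNet++ wiring.  The regression head is two pointwise
(1-kernel) convolutions reducing to one channel, followed by a center crop
to the 10^3 subbox; because the head is pointwise, cropping before the head
is exact.

**Interior ("telescoped") evaluation.**  Only the central 10^3 of the final
feature map feeds the head — that is why the boxes carry a 15-voxel margin.
The regression forward therefore computes each nested node only on the
interior window the central output actually depends on, using valid
convolutions (e.g. the last nested node on 10^3 instead of 40^3).  In eval
mode this equals the full-box forward up to float32 summation order; in
training mode batch-norm statistics are computed over the interior windows
rather than the full box.  This cuts the regression cost by roughly an
order of magnitude and is what makes CPU-only training practical.  The
occupancy network must emit the full 40^3 field, so it cannot telescope;
its convolutions instead use a tap-sum lowering (27 shifted GEMMs in a
channel-last layout) that moves data in long contiguous runs.

The networks and their training run on a small reverse-mode automatic
differentiation engine written on numpy (im2col/tap-sum + BLAS GEMM
convolutions).  Every primitive's gradient is verified against central
finite differences in the test suite.  All computation is float32 and
deterministic given the seed; max-pooling ties resolve to the first maximum.

The occupancy head's bias is initialized so that the initial output matches
the class-weighted nominal occupancy prior (1 % occupied) — the standard
prior-matching initialization for sparse detection, which saves the early
epochs a zero-initialized head spends rediscovering the base rate.

## Synthetic data generator

The generator replaces an experimentally derived corpus with entries whose
ground truth is known in closed form:

- **Pseudo-protein**: a self-avoiding random walk of carbon-like
  pseudo-residues with fixed 3.8 Å steps (the Cα–Cα virtual bond), minimum
  non-bonded distance 3.0 Å, confined to a sphere of radius
  3.0 x n_atoms^(1/3) Å (protein-like packing); one chain, one residue per
  atom; 300 atoms by default.
- **Ensemble**: per-atom per-axis Gaussian amplitudes sigma_i ramp linearly
  from 0.3 Å at the centroid to 1.5 Å at the periphery (the
  periphery-flexible pattern real proteins show); 300 frames of mean +
  i.i.d. isotropic displacement.  Expected RMSF is sigma_i * sqrt(3)
  (0.5–2.6 Å, a realistic range).
- **Map**: the frame-averaged simulated density at 5 Å nominal resolution
  plus white noise of 5 % of the noise-free maximum, on a grid enclosing
  all frames with a 10-voxel margin (~50-64 voxels per edge).  Flexible
  regions are genuinely blurred, so the map carries the physical signal the
  cryo channel is supposed to learn; local density is anticorrelated with
  sigma_i by construction (asserted in tests).  The mean-model simulated map
  correlates with the generated map above 0.7, the screening criterion used
  for real map/model pairs.

What the generator does **not** emulate: secondary-structure geometry and
side chains, correlated (collective) motions, non-isotropic or non-Gaussian
fluctuations, reconstruction artifacts (CTF, masking, sharpening,
non-uniform local resolution), and the heavy-atom density of real residues
— each pseudo-residue is a single atom, so occupied voxels are roughly ten
times sparser than in a real 1.5 Å-sampled protein.  Passing the synthetic
studies therefore demonstrates that the pipeline is correct and that the
networks can learn the blur-flexibility relation; it does not certify
accuracy on experimental maps.

## Desk-scale study conditions

The benchmark studies (driven by `cryoflex.benchmark` and
`scripts/acceptance.py`) use 10 generated entries with the default spec,
split 7/1/2 into train/val/held-out:

- **Regression**: dual variant, base width 8, batch 16, 10 epochs, no
  augmentation (the mirrored copies matter for generalizing across deposited
  map orientations, not for the isotropic synthetic ensemble).  A full run
  takes minutes on one CPU core and reaches held-out voxel-level
  correlations far above the 0.5 sanity bar.
- **Occupancy**: base width 4, a capped budget of 12 boxes per entry, and a
  short schedule.  The nearest-voxel occupancy of a Cα-like pseudo-protein
  is a much sparser target (~1 % positives) than real heavy-atom occupancy,
  so this study measures a harder detection problem than the real-data one;
  see the limitations note below.

## Numerical choices

- Population (not sample) standard deviation in z-scoring; deterministic.
- "Improvement" in the schedule means a strictly lower validation loss.
- Voxel indices are 0-based; a voxel's world position is its center;
  world-to-voxel assignment is nearest-center (floor(x/h + 1/2)).
- Box normalization of an all-non-positive box yields all zeros; an
  all-zero simulated map binarizes to all zeros (sigma = 0 guard).
- Pearson correlation on constant input raises instead of returning NaN.
- Checkpoints are npz archives embedding the network configuration.

## Known limitations

- The synthetic occupancy task is much harder than its real-data analogue.
  Real heavy-atom occupancy at 1.5 Å sampling is dense within the molecular
  envelope, so classifying it is close to foreground segmentation.  The
  generator's single-atom pseudo-residues sit 3.8 Å apart under a 5 Å blur:
  neighboring atoms are unresolved, positives are ~0.5 % of voxels, and
  recovering the exact nearest-atom voxel requires sub-voxel deconvolution
  of merged blobs.  An ideal local-maximum detector on the clean map reaches
  only F1 ≈ 0.3 on this target; the trained classifier beats that bound but
  climbs slowly, and the shipped short schedule reports the threshold sweep
  wherever it lands rather than a converged optimum.
- Batch-norm statistics over interior windows (training mode) mean the
  regression network's training dynamics differ slightly from a full-box
  implementation; the eval-mode function is identical.
- Nucleic acids, ligands and membranes are out of scope; B-factor-weighted
  densities and electron scattering form factors are not modelled.
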