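# Methods

## Problem and approach

A pneumothorax is air in the pleural space between lung and chest wall.
Its clinical management depends on its size relative to the hemithorax:
small collections are observed, larger ones drained.  `ptxquant`
quantifies pneumothorax size from a chest CT volume as the relative
volume

    V_ptx = V_air / (V_air + V_lung)

where `V_air` is the volume of pleural air and `V_lung` the volume of
aerated lung parenchyma, both obtained by segmentation in Hounsfield
Units (HU).

The pipeline is deliberately simple — a two-tier design rather than
multi-pass region growing:

1. **2D processing** (per axial slice). Each slice is smoothed with a
   discretised Gaussian (σ = 0.5 px, 5×5 kernel, renormalised, reflective
   boundary). A fixed cutoff Th_M = −500 HU separates the patient from
   surrounding scanner air; morphological hole filling (complement →
   reconstruction from a border marker → complement) restores lung
   parenchyma and intrathoracic air inside the body mask. The HU
   histogram of body-masked voxels then yields two adaptive cutoffs:
   Th_A between the air mode (≈ −1000 HU) and the parenchyma mode, and
   Th_L between parenchyma and soft tissue. Voxels below Th_A are
   labeled AIR, voxels in [Th_A, Th_L) LUNG.
2. **3D processing.** AIR voxels are grouped into 3D connected
   components (26-connectivity by default). A component is excluded in
   full — reconstruction semantics: the unit of decision is the whole
   connected component — when it is continuous with spaces outside the
   pleural cavity, when it is the tracheal lumen, or when it is smaller
   than a noise guard. Surviving air is the pneumothorax mask.
3. **Measurement.** Voxel counts are scaled by the physical voxel
   volume (product of the slice, row and column spacings in mm) and
   combined into V_ptx.

## Morphology substrate

Dilation, erosion, reflection and the erosion chain rule are implemented
directly from their set definitions on Z²; structuring elements carry an
explicit anchor. Boundary handling: cells outside the grid are
background, dilation results are cropped to the grid. The "2×2 disk"
element used for mask propagation is realised as the full 2×2 square
anchored at (0,0) — a disk of that size has no other discrete
realisation. `erode_decomposed` pads the grid with background before
chaining so that the decomposition identity holds on the whole grid,
not only away from the frame.

Reconstruction from a marker returns the union of the connected
components of the mask that contain at least one marker pixel. It is
computed by component labeling (`scipy.ndimage.label`) rather than by
iterated conditional dilation — the results are identical by definition,
and the labeling route is one pass; the iterative form is retained in
the test suite as an independent oracle. Hole filling uses
8-connectivity for the background by default (configurable): with
4-connectivity, diagonal one-pixel channels to the border would be
treated as sealed and anatomy-adjacent notches would fill too eagerly.
The description of mask propagation by "dilation then erosion" admits a
closing-based reading; we implement border-marker reconstruction, which
is the standard hole-filling construction and leaves border-connected
background untouched.

## Adaptive threshold estimation

The histogram uses 10-HU bins over [−1100, 300] HU. Modes are local
maxima with prominence ≥ 0.1 % of the masked voxel mass; each HU window
(air ≤ −900, parenchyma in (−900, −300), soft tissue ≥ −300) contributes
its most massive peak. The prominence floor is deliberately low: the air
class (tracheal lumen plus a small pocket) is legitimately well under
1 % of thorax voxels, and a spurious low bump in a window is harmless
because only the most massive peak per window is used. Cutoffs are
placed at the minimum-count valley between adjacent modes; when the
valley is a flat (near-empty) plateau the middle tied bin is taken, so
the cut sits centred in the gap. If fewer than three modes are found the
estimator falls back to fixed defaults Th_A = −870 HU, Th_L = −200 HU
and tags the result `fixed_default`. Thresholds are estimated once per
volume, not per slice: the per-volume histogram is stabler and the
cutoffs are global properties of the acquisition.

Comparisons are half-open (a voxel exactly at Th_A is LUNG), fixing the
boundary behaviour deterministically. Estimation sees only the
histogram, so it is invariant to voxel order.

## 3D exclusion rules

"Continuity with air spaces outside the chest cavity" is operationalised
as: any voxel of the component 26-adjacent to a non-body voxel, or lying
on the top/bottom slice face of the scanned range (the trachea and the
bowel always reach a volume face or exterior air in a chest
acquisition). The tracheal lumen that is fully inside the scanned range
is additionally caught by an automatic airway seed: among the surviving
components, the one whose centroid in its topmost slice is nearest the
body centroid of the most cranial air-containing slice. The seed is
accepted only if that distance is within 0.35 of the body's equivalent
in-plane radius — the trachea is a mid-mediastinal structure, whereas
pleural air hugs the chest wall; without this centrality gate a
peripheral pocket could be mistaken for the trachea in a scan whose
airway lies outside the range. Components below
`min_component_voxels = 8` are discarded as noise speckle; the guard is
kept small because genuinely tiny residual airway air is a known trace
signal (sub-0.5 %) rather than something to mask aggressively. Per-slice
component centroids are computed and reported; beyond airway seeding
they do not gate any decision.

V_lung counts only parenchyma-labeled voxels: vessels and airway walls
excluded by the intensity thresholding stay excluded, so the denominator
is aerated lung plus pleural air rather than the full anatomic pleural
region. Relative volumes are therefore slightly higher than those from
manual pleural contours that include vascular structures.

## Synthetic thorax phantom

No CT datasets accompany the method, so validation uses a phantom with
voxel-exact ground truth. Defaults: grid 40×384×384, spacing
(2.5, 0.7, 0.7) mm — axial resolution and slice thickness typical of a
chest MDCT reconstruction, giving a body of ≈ 19×24 cm. The in-plane
grid is chosen so the anatomy has realistic proportions at the stated
pixel spacing; on a much coarser grid the one-voxel partial-volume shell
around the pleural pocket would be a double-digit share of its volume
and dominate the measurement, which is a property of the toy grid, not
of the method. The through-plane extent (10 cm) is a scaled-down chest;
it spans lungs, an air column reaching the top face and sub-diaphragm
slices, which is what the exclusion logic needs.

Contents: an elliptical body (+40 HU) with a bone insert (+700 HU),
two ellipsoidal lungs (−850 HU, between Th_A and Th_L so adaptive
thresholding is exercised non-trivially), a tracheal air column
(−1000 HU) reaching the top slice face, optional bowel gas reaching the
bottom face, and a pleural pneumothorax pocket (−1000 HU) carved from
the lateral aspect of one lung. The pocket is the top-k voxels of a
score combining elliptical radius and lateral direction, with k chosen
so that the analytic fraction n_air/(n_air + n_lung) equals the target
exactly; the achieved fraction is recorded from the noiseless geometry.
Voxel values are class means plus additive white Gaussian noise
(default sd 20 HU). Geometry is seed-independent; only the noise field
varies with the seed, and a fixed seed is bit-reproducible.

The default cohort preset spans fractions 0–0.353 (normal through
large), mirroring the spread of a published 8-case validation cohort.

What the phantom does *not* model: partial-volume voxels at class
interfaces beyond what Gaussian smoothing induces, CT streak and
beam-hardening artifacts, respiratory/cardiac motion, pleural effusion,
emphysema, and anatomical variability. Two consequences matter for
interpreting tests. First, the inter-mode valleys of the phantom
histogram are nearly empty, so the estimated cutoffs sit mid-gap
(Th_A ≈ −935 HU, Th_L ≈ −405 HU) rather than at the values real,
partial-volume-filled histograms produce (≈ −870 / −200 HU); any cut
inside an empty valley yields the same labeling, so this affects the
reported threshold values, not the segmentation. Second, passing
recovery tests on phantoms demonstrates correct mechanics of the
pipeline — thresholding, reconstruction, exclusion, volumetry — not
clinical accuracy on patient data.

## Numerical and design choices

- Axis convention: axis 0 is the through-plane (slice) axis; grids are
  indexed `[slice][row][col]`, 0-based; physical spacing is carried
  separately. Slices read from DICOM are ordered by position along the
  slice normal, never by file name; missing rescale tags are an error,
  never silently assumed HU.
- HU values outside [−1100, 3100] are clipped with a logged warning
  (scanner padding values), not a failure.
- Threshold coherence requires Th_A < Th_L; the body-mask cutoff Th_M
  normally lies between them and is validated independently.
- The paired t-test on automated−reference differences is two-sided
  with n−1 degrees of freedom. With zero-variance differences the t
  statistic is reported as 0 with a warning; a zero-variance series
  makes Pearson r undefined and it is reported as NaN with a warning.
- The trendline is ordinary least squares of automated on reference
  values with an intercept, and the reported r² is the square of the
  Pearson r of that fit. Note that the published scatter-plot
  determination coefficient of the 8-case cohort (0.989) is not
  reproduced by either a with-intercept (0.992) or a through-origin fit
  of the printed values; the convention behind that figure is not
  recoverable, so the with-intercept value is reported and the
  discrepancy documented rather than chased.
- Problem sizes in the test suite: module tests use 32×192×192
  phantoms; end-to-end recovery and exclusion checks use the default
  40×384×384 phantom, 8 cohort fractions × 10 seeds for recovery and 20
  seeds for exclusion. `scripts/acceptance.py` uses 4 replicates per
  fraction and 10 exclusion runs; recovery error is geometry-dominated
  and essentially seed-invariant, so few replicates suffice.

## Known limitations

- Thresholding at the air/tissue interface erodes the pocket by up to
  one voxel along its chest-wall surface (a voxel needs a ≈ 90 %-air
  neighbourhood to stay below Th_A against +40 HU tissue), giving a
  small systematic underestimate of V_ptx that grows with the pocket's
  surface-to-volume ratio (≤ ~1.5 percentage points on the default
  phantom at the largest cohort fraction).
- No handling of pleural effusion, hemothorax or underlying lung
  disease; such cases are outside the method's assumptions.
- The airway seed assumes a roughly centred trachea; severe mediastinal
  shift could defeat the centrality gate (the exterior-continuity rule
  still catches any airway reaching the scanned boundary).
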