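# Methods

`sgrt-autoroi` automates the definition of the registration region of
interest (ROI) for surface-guided radiotherapy (SGRT) of the whole breast.
Two constructions are implemented, sharing everything except their first
step:

* **body-contour-based ROI** — the superior–inferior (S-I) borders come
  from body joint locations (the two collar joints and the mid-spine joint
  "Spine2") predicted from a coronal body image by a regression model
  trained purely on synthetic humans;
* **breast-contour-based ROI** — the S-I borders come from the delineated
  ipsilateral breast's S-I extent, extended by per-category constants.

This note records the model, the numerical choices, and what the synthetic
data do and do not establish.

## Coordinate conventions

Patient frame: x = patient-left positive, y = anterior positive,
z = superior positive, all in mm. Coronal images and masks are stored with
row 0 at the most superior edge and column 0 at the most patient-right edge
(the radiographic "facing the patient" convention), so the patient-left
collar projects to a *larger* column index than the patient-right collar.
The pixel with index (r, c) on a grid with origin (x0, z_top) and spacing s
has its center at `(x0 + (c + 0.5) s, z_top - (r + 0.5) s)`; label
coordinates are real-valued (row, col) indices in this center-index space.

## Parametric body model

A procedural parametric body replaces learned statistical shape models: the
surface is assembled from closed tubes of elliptical cross-sections (legs,
torso, neck, two arms) plus an ellipsoidal head, posed with both arms
abducted ~20° from vertical overhead — the fixed arms-raised position of
breast SGRT patients. The skeleton (Pelvis, Spine1, Spine2, collars,
shoulders, Head, Nose) sits at fixed offsets of the segment stack. Four
multiplicative shape scales (torso width, torso depth, shoulder width, limb
length) are drawn uniformly from [0.8, 1.2] by default, a range wide enough
to cover a realistic adult anthropometric spread without degenerate bodies.
Each part is a watertight component; the template is mirror-symmetric
across the mid-sagittal plane.

Bodies are scaled isotropically so the S-I vertex extent (head-to-foot,
including the raised arms) equals a target height, 1617 mm by default (the
average US adult female height). Isotropic scaling preserves all
inter-joint distance ratios.

## Synthetic imaging

Meshes are projected orthographically along the anterior-posterior axis
with a z-buffer rasterizer (numba); the pixel value encodes the normalized
anterior depth of the frontmost surface, rescaled per image to (0, 1], with
background exactly 0. Depth shading rather than a binary silhouette gives
the regressor weak 3-D cues at no extra cost; per-image normalization makes
the rendering invariant to anterior-posterior translation.

The torso crop emulates the scan range of breast CT: the superior edge is
drawn uniformly between the Nose and Head joint rows, the inferior edge
uniformly between the Spine2 and Spine1 rows. Because only the vertical
bounds are anatomically defined, the window is made square by symmetric
lateral extension about the body midline (bounding-box center of the
silhouette within the band), then resampled to 200×200 px — bilinear
inside the body, nearest-neighbour membership so background stays exactly
zero. Aspect ratio is therefore preserved (no stretching); pixel spacing is
recorded per image, so labels convert losslessly to mm. A crop that would
exclude a target joint is redrawn (at most 10 times), keeping the dataset
size exact.

The default dataset is 3000 image/label pairs split 85:15 (2550/450) by a
seeded shuffle. The full-body working render uses 3 mm/px; at the default
crop sizes this resamples to roughly 2–3 mm/px in the 200×200 crop, which
keeps generation around half a minute on one CPU without visibly affecting
joint-label accuracy (labels are stored analytically, not read off pixels).

## Joint regression

The regressor maps one cropped grayscale image to six numbers: (row, col)
for LeftCollar, RightCollar, Spine2, regressed internally in normalized
[0, 1] coordinates (scale-free loss) and converted back at the interface.
Training minimizes mean squared error with Adam and stops at a fixed epoch
budget (default 2000); train/validation loss is recorded every epoch and a
non-finite loss aborts with an explicit error.

The backbone is pluggable. The default is a small multilayer perceptron
(hidden layers 128/64, L2 penalty 1e-4, batch 32, learning rate 1e-3 with
optional per-epoch decay) on anti-aliased 32×32 downsampled pixels,
normalized by a single per-channel mean/std. This choice is deliberate: the
construction only consumes the joints' S-I coordinates, so the backbone
needs to be *sufficient*, cheap, and deterministic on a CPU, not
state-of-the-art. The epoch loop drives one Adam pass per epoch while
keeping optimizer moments across epochs.

MPJPE (mean per-joint position error) is the Euclidean distance between
predicted and true joint positions in mm; because clinical reports quote
per-axis numbers, the report also carries mean ± sd of the absolute S-I and
L-R coordinate errors separately. The Euclidean mean always dominates each
per-axis mean.

## ROI construction

Given upper/lower borders `upper_z > lower_z`:

1. **S-I borders.** From joints: `upper_z = mean(collar z) + upper_shift`,
   `lower_z = Spine2 z − lower_shift`, defaults 10 mm and 30 mm (the values
   recovered by DSC tuning; see below). The two collar joints are averaged
   since they are level on the template and no aggregation rule is
   anatomically privileged. From the breast contour:
   `upper_z = superior + sup_ext`, `lower_z = inferior − inf_ext`, with
   (27, 12) mm for breast-only contours and (−24, 17) mm for PTV contours
   that include nodal volumes — the negative superior extension pulls the
   ROI border *inferior* of the PTV's superior border.
2. **Chest width** is the lateral silhouette extent at the row midway
   between the borders; edge positions are outer pixel edges so a phantom
   of known width measures exactly.
3. **Lateral span** is `lr_fraction` (default 3/4) of the chest width,
   anchored at the *ipsilateral* silhouette edge and extending
   contralaterally. The institutional protocol runs from the ipsilateral
   A-P midline — which projects to the ipsilateral silhouette edge in
   coronal view — to the middle of the contralateral breast.
4. **Curation** replaces the ipsilateral-superior corner by a straight
   chamfer between the points 80 mm along the two adjacent edges, removing
   a right triangle (area 80²/2 = 3200 mm²) that would otherwise cover the
   mobile arm/armpit. A chamfer, not a rectangular notch, is used: a notch
   would reintroduce a corner near the armpit, and the intended cut-away is
   a sloped one. If the retraction exceeds an edge length the corner is
   left uncurated with a warning rather than producing a degenerate
   polygon.

The result is a simple 5-vertex polygon (4 without curation) carrying its
construction landmarks, from which it can be rebuilt bit-identically.
Right-sided patients are handled by mirroring inputs across the
mid-sagittal plane, constructing the left-sided ROI, and mirroring back —
one code path, and mirror equivariance holds exactly by construction.

## Evaluation and tuning

DSC is computed on rasterized masks (pixel in iff its center is inside the
polygon) over a common 1 mm/px grid covering both regions; sub-millimeter
raster differences are below clinical relevance. Two empty masks are
defined as DSC 1 with a warning. The S-I shifts are tuned by a joint grid
search (0–45 mm in 5 mm steps per axis, 10 candidates each) maximizing the
mean DSC between the constructed body-based ROI and the reference ROIs;
ties break toward the smallest (upper, lower) pair lexicographically. The
joint sweep contains the two 1-D sweeps as slices.

Mean boundary distance is the signed S-I distance between reference-ROI and
breast borders, positive when the ROI border lies beyond the contour border
*away* from the breast; the PTV category's superior distance is negative by
this convention.

## Synthetic cohorts

Since no clinical cohort ships with the package, tuning and evaluation run
on synthetic patients: a randomized body, its 2 mm/px silhouette,
ground-truth joints, a breast contour, and a pseudo-clinical ROI. The
breast contour is placed at joint-derived offsets chosen so the cohort is
internally protocol-consistent — the pseudo-clinical ROI equals both the
joint construction at the true shifts and the breast construction at the
true per-category extensions. Inter-planner variability is modeled as
independent Gaussian jitter on the four boundary positions (upper, lower,
ipsilateral, contralateral) of the pseudo-clinical ROI, because planners
drawing without a ruler err at the level of borders, not of vertices. The
default category mix keeps the 30:9 breast-only-to-PTV proportion.

What this does and does not show: noise-free recovery of (10, 30) and of
(27, 12)/(−24, 17) verifies the estimators are exact inverses of the
construction; jittered recovery verifies robustness of the argmax at
realistic noise. None of it validates the constants against real patients,
whose chest shapes, breast contours and hand-drawn ROIs are not generated
by this geometry. Likewise the toy regression benchmark (a rendered dot
whose position determines the labels affinely) establishes that the
training loop learns image-to-coordinate maps, not that the default
backbone reaches clinical-grade MPJPE on real silhouettes.

## Numerical choices and degenerate inputs

* Raster grids place pixel centers at half-integer offsets, so polygons
  with integer-mm edges never have centers exactly on a boundary.
* Silhouette connectivity: projections keep the largest connected
  component; validation rejects empty or split masks.
* Inverted bounds (upper ≤ lower), empty mid-rows, and collapsed
  rectangles raise a dedicated degenerate-geometry error (CLI exit 3);
  invalid parameters and inputs raise invalid-input errors (CLI exit 2).
* All randomness flows from explicit integer seeds; one global seed fans
  out to stage seeds through a BLAKE2 hash (stable, < 2³¹). Two runs with
  the same seed are bit-identical.

## Known limitations

* The procedural body is a stylized stand-in: no soft-tissue deformation,
  no breast surface relief, no pose variation. Models trained on it will
  not transfer to real depth images without domain adaptation.
* The construction and its evaluation live entirely in the coronal plane;
  mapping the planar ROI onto the 3-D camera surface is vendor-side and out
  of scope, as are proprietary ROI export formats.
* The breast contour is reduced to its S-I extent; contour shape is not
  used anywhere in the construction.
* DSC grids at 1 mm/px bound the tuning resolution well below the 5 mm
  candidate step, but very small ROIs (< a few cm) would deserve a finer
  grid.
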