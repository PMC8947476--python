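# Methods

## Segmentation algorithms

**Variable threshold (reference).**  The lesion maximum is not known before
the lesion is delimited, so it is found by fixed-point iteration: start from
the hottest voxel in the 3×3×3 neighborhood of the seed click, threshold the
image at `fraction × max` (default 0.40), keep the 26-connected
supra-threshold component containing that voxel, recompute the maximum
inside the component, and repeat (at most 10 rounds).  The component
maximum is non-decreasing and bounded, so the iteration converges; in
practice it stabilizes in one or two rounds.  Membership is inclusive
(`≥ fraction × max`).

**Texture region growing.**  The start volume is the 27-voxel cube centered
on the seed; smaller start regions do not support meaningful texture
estimates.  Each iteration forms six candidates by shifting the current
region one voxel along each axis direction and unioning with itself
(growth clipped at the image faces, never removing voxels).  Every
candidate is evaluated as a whole: the configured feature is computed on
the full candidate region, and the candidate is accepted iff the value is
*strictly* on the accepted side of the threshold (a value exactly at θ is
rejected).  The iteration result is the union of accepted candidates; by
default all six candidates grow from the same parent region
(`sequential=True` instead feeds each accepted candidate into the next
direction, for sensitivity analysis — with anisotropic voxels the two
variants can differ near boundaries).  If the start cube itself violates
the criterion, the cube is returned unchanged and flagged
(`terminated_at_start`).  Growth halts when an iteration changes nothing;
a `max_iterations` cap (default 200) guards against degenerate thresholds
and is flagged as non-convergence, never silent.

Volume growth is monotone, so termination is guaranteed by the finite grid.
The whole pipeline is deterministic: image + seed + feature spec fully
determine the mask.

## Texture features

All features are computed over the member voxels only; voxel pairs and
zones never cross the region boundary.

* **Kurtosis** uses the population (1/N) standard deviation, matching the
  1/N normalization of the defining sum, and the non-excess convention
  (Gaussian → 3, Pearson lower bound 1).  Regions with zero variance are a
  hard error rather than a sentinel value.
* **Co-occurrence / Local Entropy.**  The 3D GLCM aggregates the 13 unique
  direction vectors at Chebyshev distance 1, counts each pair in both
  orders (symmetric matrix), and normalizes to probabilities.  Entropy is
  `−Σ p log₂ p` over nonzero cells, hence bounded by `2 log₂ G`.
* **Size-zone / Long-Zone Emphasis.**  Zones are maximal 26-connected
  components of equal gray level; `LZE = Σ M4_ij j² / Σ M4_ij ≥ 1`.

**Discretization.**  Matrix features require gray levels
`clamp(⌊G (x − lo)/(hi − lo)⌋ + 1, 1, G)`.  Three binning modes exist:

* *fixed-global* (default, G = 64): edges computed once per run from the
  intensity range inside the start cube's bounding box dilated by 30 mm,
  so the feature trajectory stays on one gray scale across grow steps;
* *explicit edges* (`FeatureSpec.bin_edges`): protocol-constant absolute
  edges, the fixed-bin convention of quantitative radiomics, making values
  comparable across images acquired under one protocol;
* *per-region*: every candidate is re-binned over its own min/max.

The experiment defaults choose per feature: kurtosis needs no binning;
entropy uses fixed protocol edges with a *coarse* G = 8 — a 27-voxel start
region yields only a few hundred voxel pairs, and entropy estimated over
64² = 4096 cells is dominated by small-sample bias (measured: the start
cube's apparent entropy exceeds that of a region ten times larger, which
inverts any calibration);  long-zone emphasis uses per-region binning,
because with any fixed gray scale LZE grows with region size (zone sizes
scale with the region), so no threshold can simultaneously admit the
27-voxel start and reject overgrowth — with per-region binning the
intensity-range expansion at the lesion edge collapses the interior into
one giant zone and LZE jumps by orders of magnitude exactly where the stop
belongs.

## Threshold calibration

Stop thresholds belong to the acquisition protocol and are never built in.
`calibrate_threshold(image, tumor_mask, background_mask, spec)` computes
the feature in two disjoint reference regions (≥ 27 voxels each), places θ
at the midpoint and accepts the side the tumor value lies on; equal values
are an error ("feature not discriminative").  For matrix features both
regions share one gray scale (explicit edges, or edges spanning both
regions).

The choice of reference regions matters more than the midpoint rule.  The
feature of a *growing region* is not the feature of a tissue patch: a
region that has overreached is a mixture of lesion and background, and its
feature value can be far from either tissue's.  The phantom experiments
therefore calibrate between two *region states*: the lesion eroded by one
voxel layer (the last state the growth should fully accept) and the lesion
dilated by k layers (an overreached state it must refuse; k = 1 for the
matrix features, which detect first boundary contact, and k = 3 for
kurtosis, which detects the bimodal intensity histogram of a fully
overreached region).  Thresholds are calibrated once per method on the
largest sphere of a dedicated noisy *static* calibration acquisition and
then reused for every sphere and for motion-blurred data, as a fixed
clinical protocol would.

## Synthetic phantom

The generator emulates a motion phantom carrying fillable spheres of 3, 12
and 26 ccm filled at 1.2 MBq/ccm, imaged at a 128×128 matrix with 5 mm
slices and a 5 mm Gaussian post-reconstruction filter, optionally driven
sinusoidally in z with 15 mm peak-to-peak excursion at 12 cycles/min.
Free parameters not fixed by that protocol:

| parameter | default | rationale |
|---|---|---|
| in-plane pixel | 4 mm | 128 matrix over a typical ~51 cm field of view |
| slices | 40 × 5 mm | spheres + motion excursion + blur padding |
| noise coefficient | 0.05 | SD = 0.05 × local intensity + floor; calibrated so 20-repeat relative SDs of the reference method land in the low single-digit percent range |
| noise floor | 0.005 MBq/ccm | electronic/scatter baseline in cold regions |
| noise correlation | = PSF FWHM | reconstructed, post-filtered PET noise is correlated at the resolution scale; the field is smoothed white noise renormalized so the stated per-voxel SD is exact |
| motion phases | 32 | time-average converges well below voxel scale |
| supersampling | 4 per axis | partial-volume fractions at sphere boundaries |

The imaging chain is analytic rasterization → Gaussian PSF → additive
noise; it deliberately replaces iterative reconstruction with a blur+noise
forward surrogate, which reproduces partial-volume behavior and repeat
variability but not reconstruction artifacts, attenuation or scatter.
Motion is z-only (cranio-caudal dominates respiratory displacement) and
the phantom moves as a rigid whole.  An optional mean-preserving lognormal
background texture (`background_texture_sigma`, default off) stands in for
the heterogeneous uptake of healthy tissue in lesion-in-lung scenarios;
it is a fixed pattern per phantom (anatomy), not per-acquisition noise.

`truth_mask` uses voxel-center-in-sphere membership; on the default grid
the 26 ccm sphere voxelizes to 24.96 ccm, which is the appropriate
reference for segmentations on that grid.

## Stability experiment

For each of 20 repeats a fresh noise realization is drawn and the seed
click is jittered uniformly within a 1-voxel Chebyshev radius (manual-click
variability); every method segments every sphere and the volumes are
summarized as mean, range, absolute and relative (100·SD/mean) standard
deviation, with the sample (N−1) SD.  Reported percentages are rounded to
one decimal half-away-from-zero in two stages (two decimals, then one),
the convention under which published difference columns reproduce from
their printed volume pairs.  All RNG streams (calibration, jitter,
per-repeat noise) derive from one master seed, so the experiment is fully
reproducible; failed repeats are warned about, counted and excluded.

## What the phantom experiments do and do not show

The homogeneous zero-background sphere phantom exercises the *machinery*
(growth, stopping, statistics) under controlled conditions, but it is a
hostile environment for texture criteria: its only texture contrast is the
lesion edge itself, while the tissue-vs-tissue contrast that motivates
texture segmentation in patients is absent.  Consequences measured with
this package:

* The reference threshold method behaves like the published experience:
  accurate on the large sphere (−4% noiseless), partial-volume-limited on
  the small one, relative SDs of ~1–6%, and larger volumes on uncorrected
  (motion-blurred) data.
* The texture methods segment plateau-edge contact rather than tissue
  texture here.  Their volumes are biased (long-zone emphasis stops inside
  the blurred skirt; kurtosis overgrows until the region histogram turns
  bimodal), and their repeat variability is dominated by whether the noisy
  start-region feature falls on the accept side of θ — a bimodal
  stop-state distribution that inflates large-sphere relative SDs beyond
  the small sphere's.  The expected "smaller lesions are less stable"
  ordering therefore holds for the threshold method but not reliably for
  midpoint-calibrated texture methods on this phantom.
* Motion smearing *shrinks* the always-covered full-intensity plateau
  (half-height extent ≈ r − A/2 in z) even as it widens the 40%
  isocontour.  A criterion that stops at the plateau edge — entropy here —
  yields *smaller* volumes on uncorrected data, the opposite of the
  intensity-threshold behavior.  This is a genuine property of
  time-averaged motion blur on homogeneous objects, and a caution against
  transferring phantom behavior of texture criteria to patient data.

Passing tests on this phantom therefore validate correctness of the
algorithms and statistics, not clinical performance of the texture
criteria; the calibration experiments below probe the latter's mechanism
directly.

## Two-texture recovery experiments

Calibration sanity is checked on single-sphere phantoms with a genuine
two-texture structure, where the sphere must be recovered within ±25%
(median over 5 noise realizations) from a threshold calibrated on
interior vs boundary-straddling reference regions.  Each feature detects a
different texture contrast, so each variant matches its mechanism:

* **kurtosis** — background at the *same mean uptake* but with
  heavy-tailed fine-grained speckle (lognormal σ=0.9, 3 mm grain): the
  region's kurtosis rises monotonically toward the heavy-tailed background
  value as it overreaches; interior noise (coefficient 0.15) provides the
  graded tolerance that keeps boundary-skirt voxels from triggering early.
* **local entropy** — a warm lumpy background (0.36 MBq/ccm, lognormal
  σ=0.5 at 12 mm) below a hot sphere: crossing the uptake step creates
  co-occurrence pairs across many gray-level combinations and entropy
  jumps at the boundary.
* **long-zone emphasis** — same-mean speckle with per-region binning: at
  boundary contact the in-region range explodes, the interior collapses
  into one giant zone, and LZE jumps by orders of magnitude.

A single fixture for all three was explored extensively and is not
attainable: kurtosis requires high interior noise where entropy requires
low, and the LZE range-explosion contrast requires a same-mean background
where entropy requires an uptake step.

## Numerical and interface choices

* 0-based voxel indices (i,j,k) ↔ world (x,y,z), world = origin +
  index·spacing; oblique orientations are rejected at load time, never
  resampled.  All geometry is computed in mm/ccm, supporting anisotropic
  spacing.
* Maximal diameter is the largest center-to-center distance between member
  voxels, computed exactly (convex-hull reduction for large masks, full
  pairwise scan otherwise).
* World-mm seed points map to the nearest voxel center with ties toward
  the lower index; `--seed-mode hottest` relocates the seed to the hottest
  voxel within a search radius, a standardized alternative to the manual
  click.
* DICOM series are sorted by position along the slice normal, require one
  series UID, uniform slice spacing and identity orientation, and apply
  rescale slope/intercept.
* Reports embed the resolved configuration and are byte-reproducible for
  identical inputs.

## Known limitations

No scanner model (no sinograms, attenuation, scatter, reconstruction
artifacts); rigid z-only motion; homogeneous sphere activity (real lesions
are heterogeneous — the texture criteria were motivated by exactly that
heterogeneity, which the phantom lacks); midpoint calibration is sensitive
to the choice of reference regions, and thresholds do not transfer between
acquisition protocols or gray-scale conventions; 2D slice-wise feature
variants and full radiomics panels are out of scope.
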