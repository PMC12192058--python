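# Methods

`renovasc` implements a quantitative comparison of renal vascular density as
measured by two modalities — in vivo super-resolution ultrasound (SRUS, also
called ultrasound localization microscopy) and ex vivo contrast-perfused
micro-CT — together with the geometric machinery needed to compare them in
co-registered anatomical regions. Because the modalities live in different
spaces (a 2D imaging plane versus a 3D volume), the package's core is a
partitioning-and-projection scheme that maps both measurements onto the same
(segment × region-of-interest) cells of a kidney. Everything runs on
synthetic phantoms with known ground truth, so every stage is testable
without external data.

## Coordinate conventions

Voxel arrays are indexed `(i, j, k)` along world `(x, y, z)`, 0-based,
right-handed. World coordinates and detections are in mm; voxel and pixel
pitch metadata are in µm. In phantoms the long (cranio-caudal) axis is x,
the hilus points along +y, and the imaging plane is the x–z plane.

## Kidney partitioning

Given a binary kidney mask, a PCA of the voxel world coordinates defines an
oriented bounding box; the box centre is **point 0**. The short box axis
best aligned with a user-supplied hilus direction meets the box face at
**point 1**. The partition apex (**division point**) is placed 20% of the
way from point 0 to point 1; from this apex the kidney is fanned into three
equal 120° sectors in the plane spanned by the long axis and the hilus
axis, and the labels are extruded along the third principal axis. Shifting
the apex toward the hilus enlarges the central sector on the side opposite
the hilus — the side that sits in the ultrasound near field, where
detection is most reliable. Conventions that the geometry does not itself
determine are fixed as follows: the central sector's bisector points away
from the hilus; the point0→point1 axis is the cranial/caudal boundary;
PCA sign ambiguity is resolved by orienting the long axis along the
supplied cranial direction and the short axis along the hilus direction; a
voxel exactly at the apex (undefined direction) is assigned to the central
sector; the extrusion axis is the third principal component.

Regions of interest are pure mask algebra on four nested input masks:
total = kidney; cortex = kidney ∧ ¬arcuate-boundary; medulla =
vasa-recta-boundary ∧ ¬pelvis.

## Co-registered plane extraction

A plane pose (origin, two in-plane unit vectors, normal, pixel pitch,
default 22.6 µm) is an input — the registration of the ultrasound plane to
the volume is assumed done elsewhere. Intensity volumes are sampled by
trilinear interpolation on a fan of planes offset along the normal within a
2 mm slab (step: half the smallest voxel spacing, endpoints included) and
reduced by per-pixel maximum (MIP). Label volumes are sampled
nearest-neighbour on the central plane only, since a maximum over
categorical labels is meaningless.

## Microbubble tracking and the velocity ceiling

Detections are linked frame to frame by globally optimal gated assignment
(Hungarian algorithm) against a constant-velocity prediction, in two
passes: established tracks (two or more points, hence a velocity estimate)
claim detections first under a strict gate (half the full gate), then all
remaining tracks and detections are matched under the full gate. Every
link must additionally satisfy an absolute per-step displacement limit
equal to the full gate — this is deliberate, and is what turns
`gate × frame_rate` into a hard ceiling on reconstructable speed. With the
default gate of 0.28 mm at 54 Hz the ceiling is ≈15 mm/s. Tracks need at
least three consecutive frames (no gaps) to be kept. Near the ceiling the
gate truncates the fastest noisy steps, so reconstructed speeds there are
biased low rather than high; the test suite measures a mean bias of about
−0.4 mm/s over the top fifth of the detectable range at 20 µm localization
noise. Speeds are finite differences of consecutive positions times the
frame rate; per-vessel-class speeds average three vessels per class, and a
class with fewer than three vessels in a scan is excluded rather than
averaged thin.

The gate, the Kalman-style prediction, and the two-pass structure are
configurable; the defaults were chosen so the emergent ceiling lands at
15 mm/s at the 54 Hz default frame rate.

## Super-resolved vascular map

Detections of accepted tracks are accumulated into per-pixel counts on a
22.6 µm grid, one increment per detection. Pixels with **more than one**
detection over the whole acquisition are kept; the kept skeleton is then
dilated with a square footprint of ceil(42.25 / 22.6) = 2 pixels,
representing the estimated track diameter at the system's resolution.
(Thresholding before dilation is a choice; the even footprint makes the
2-pixel band half-a-pixel asymmetric about the skeleton, which is
unavoidable at that diameter/pitch ratio.) SRUS density is the vascular
pixel fraction within a 2D ROI.

Resolution is estimated by Fourier ring correlation between count images
of two interleaved half-datasets (odd/even detection order), using the
half-bit information threshold standard in localization microscopy; a
curve that never crosses returns the Nyquist floor of twice the pixel
pitch.

## µCT densitometry

Vasculature is segmented by a global intensity threshold (inclusive `>=`,
fixed for reproducibility). Thresholds from multiple raters are averaged
per scan into a consensus; agreement across a rater × scan table is
summarised by ICC(2,1) (two-way random effects, absolute agreement, single
measure). Density is segmented vascular volume over ROI volume, in 3D or
on an extracted plane thresholded at the same consensus value.

## Synthetic phantoms and cohorts

The phantom kidney is a superellipsoid (exponent 2.5) with a concave hilar
notch carved from the +hilus face, so the PCA box and hilus direction are
non-trivial. The arcuate-boundary, vasa-recta-boundary and pelvic masks
are concentric scaled copies (0.70 / 0.50 / 0.25) intersected with the
kidney, which guarantees the nesting chain. A random vessel tree —
segmental vessels radiating from the hilar core, arcuate arcs at
mid-depth, short cortical microvessels — is rasterized at per-branch radii
via a Euclidean distance transform; ground-truth density per ROI is the
exact rasterized voxel ratio. Default class flow speeds (segmental artery
40 mm/s, segmental vein 12, arcuate artery 8, arcuate vein 4, microvessel
1.5 mm/s) are free parameters chosen to put segmental arteries above and
all veins below the 15 mm/s tracking ceiling, so the censoring phenomenon
is reproducible; they are not measured rat values (renal vein flow is of
order 40 mm/s, arterial flow far higher).

Microbubble streams hold a fixed budget of bubbles in circulation, each
advancing along its branch at the branch flow speed and respawning
(length-weighted) when it exits; detections are the (x, z) projection plus
isotropic Gaussian localization noise, with Poisson false positives
uniform over the field.

Cohorts are drawn through a Gaussian copula: MAP, HR and anaesthesia time
get uniform marginals over the configured ranges (defaults 38–119 mmHg,
84–346 bpm, 109–263 min), with the latent normal correlation between MAP
and HR inflated to `2·sin(πr/6)` so the post-transform Pearson correlation
matches the target (default 0.5324). A latent detection-yield multiplier
is linear in MAP (+0.004 /mmHg) and anaesthesia time (−0.004 /min) plus
Gaussian noise (SD 0.15), centred at 1 and clipped positive; the pipeline
scales each animal's microbubble budget by it. These slopes give
cohort-level correlations of roughly +0.45 (MAP) and −0.86 (anaesthesia)
with the yield, strong enough that a planted negative anaesthesia→density
association is recoverable with high power at n = 100.

What the phantoms do **not** emulate: realistic renal branching
morphometry, acoustic wave propagation and beamforming, tissue attenuation
gradients, in vivo motion, and contrast-perfusion artefacts (vessel
dilation, filling defects). Passing tests therefore demonstrate the
correctness of the measurement and statistics chain, not in vivo imaging
performance.

## Statistics

The battery wraps scipy/statsmodels/pingouin: Pearson correlation
matrices (pairwise, NaN for constant columns), OLS with interactions
(overall F vs intercept-only, adjusted R² by the (n−1)/(n−p−1)
correction), one-way ANOVA with Tukey HSD, ANCOVA (group × covariate,
type-II table), two-way repeated-measures ANOVA (modality × ROI within
animal; incomplete blocks dropped listwise with a warning; no sphericity
correction), the two-sided two-sample Kolmogorov–Smirnov test, the
pooled-variance two-sample t test (df = n₁+n₂−2), and ICC(2,1). Type-I
calibration of Pearson/F/KS/t at α = 0.05 is verified over 2000 null
replicates each in the test suite.

## Problem sizes and numerical choices

Default phantom grids use 200–350 µm voxels (≈10⁵–10⁶ voxels) and
acquisitions of a few seconds at 54 Hz; these sizes make the full pipeline
and its tests run in seconds to a couple of minutes while leaving every
rate and threshold at its physical default. The acquisition duration,
grid pitch and cohort size scale up freely through `PipelineConfig`.
Degenerate inputs are rejected early with diagnostics (masks under 10
voxels or rank-deficient covariance, zero hilus vectors, empty ROIs,
non-positive rates); empty vessel trees and empty track lists are valid
and produce empty outputs with warnings where silence could mislead.

## Known limitations

- The tracker is a two-pass gated constant-velocity linker, not a full
  hierarchical Kalman filter with per-track covariance adaptation; it
  preserves the two behaviours that matter downstream (the ≥3-frame rule
  and the hard velocity ceiling).
- Greenhouse–Geisser sphericity correction is not implemented for the
  repeated-measures ANOVA.
- Plane poses are inputs; there is no automatic 2D–3D registration.
- The FRC estimate interpolates no sub-ring precision; its floor is twice
  the pixel pitch.
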