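# Methods

This note documents the models, parameter choices and numerical decisions
behind cytomap3d, and what the synthetic study conditions do and do not
establish about real data.

## Synthetic Nissl volumes

**Populations.** Each built-in population preset carries a mean soma volume
and an SD recovered from the published SEM as SD = SEM·√n:

| preset | n | mean (μm³) | SD (μm³) | shape | role |
|---|---|---|---|---|---|
| giant_pyn | 286 | 3101.31 | 1796 | pyramidal | giant PyN, manual-segmentation statistics |
| other_pyn | 345 | 1004.32 | 250.6 | mildly prolate | non-giant PyN |
| betz_pyramidal | 93 | 5065.95 | 1053 | pyramidal | Betz shape panel |
| betz_spindle | 45 | 5223.36 | 1220 | spindle | Betz shape panel |
| betz_flat | 118 | 4551.30 | 1292 | flat (oval/triangular 59/59) | Betz shape panel |
| betz_spheroid | 30 | 1369.57 | 324 | spheroid | Betz shape panel |

The giant-PyN mean (3101 μm³, from manual segmentation of a mixed sample)
and the Betz shape-class means (up to 5223 μm³, from automatic segmentation
of selected cells) are mutually inconsistent source statistics; the presets
keep them as separate fixtures and do not reconcile them.

**Volume sampling.** Volumes are drawn from a lognormal (positivity,
right-skew of soma-volume distributions) moment-matched to (mean, SD). When
a preset is truncated, σ is kept from the untruncated match and the location
parameter μ is re-solved (Brent's method on the closed-form truncated-
lognormal mean) so the truncated distribution retains the population mean.
Sampling is by inverse CDF on the truncated quantile range, so a fixed seed
gives identical draws regardless of truncation.

**Placement.** Cells are placed by rejection sampling as a hard-core point
process: pairwise center separation ≥ max(min_sep, r_i + r_j + 1 μm), where
r_i is a conservative per-cell bounding radius derived from the target
volume and shape. The radius term guarantees rendered cells can never
overlap; min_sep (default 12 μm) sets a floor for small cells. Placement
aborts with `PlacementError` after 10 000 rejected proposals for any cell.
Largest cells are placed first; output order is the caller's.

**Shape renderers.** Six implicit solids (see `shapes.py`): near-isotropic
spheroid; mildly prolate ellipsoid (axis ratio 1.4) for generic pyramidal
neurons; spindle — prolate with axis ratio 2.6 and poles tapered faster
than an ellipsoid; flat oval — oblate ellipsoid with shortest/longest
= 0.4; flat triangular — flattened, rounded-edge triangular prism; and
pyramidal — a cone–tetrahedron blend (rounded-triangle cross-section
shrinking linearly toward the apex) with a thick apical stub. Rendering
calibrates each cell's size scale iteratively against the voxelized volume
(stop at 2% relative error, ≤ 8 refinements), so labeled volumes track
target volumes to ~2% at 1-μm voxels.

**Appearance.** Bright-field polarity by default: background 200, giant
soma gray 80 ± 8, other-PyN gray 130 ± 8 (truncated at ±2.5 SD), noise
SD 6, multiplicative illumination gain 1 + 0.05(cos x̃ + cos ỹ) (one period
across the scene). These intensity values are package choices: only their
ordering and separation matter. The fig4_mixture fixture additionally
truncates volumes (giant ≥ 1800 μm³, other ≤ 1700 μm³), encoding the
separability that motivated two distinct clusters in the source analysis.
Optional thin dendrite stubs (radius 1 μm, length 8 μm, probability 0.3 per
cell) are rendered into the gray channel only — never labeled — to exercise
the segmentation cleanup.

**Fixtures.** `fig4_mixture` (631 cells in a 400-μm cube), `betz_shapes`
(286 cells in 450 μm; the 118 flat cells split 59 oval / 59 triangular
since no split is published), and `eval_blocks` (5 × 200 giant-scale cells
in independent 512-μm blocks). `eval_blocks` is centers-only by default:
the accuracy harness never needs imagery, and rendering five 512³-voxel
blocks would cost minutes for no information. Fixture voxels are 1 μm
isotropic for desk-scale runtime; the full 0.33 × 0.33 × 1 μm mode is
exercised in geometry tests.

**Detection degradation.** The `eval_paper` preset deletes each true center
with probability 0.1264, jitters survivors with 1-μm isotropic noise, and
adds round(0.0585 × kept) uniform false detections — calibrated so expected
recall is 87.36% and expected precision 1/(1 + 0.0585) = 94.47%.

## Block data model and geometry

Blocks are `round(edge_um / voxel_size)` voxels per axis (512 μm default);
edge blocks are padded with a fill value and the manifest records the true
extent, so reassembly is bit-exact. Conventions: 0-based voxel indices,
half-open crops, voxel-center physical coordinates (center of voxel i at
origin + (i + 0.5)·voxel). Cube crops are centered on the voxel containing
the query point and record which sub-box is real data, so downstream noise
estimates and truncation flags ignore the constant padding. MIP over
dark-cell data is a minimum projection (maximum staining intensity), with
an explicit polarity override. Reslicing projects a slab and resamples to
square pixels at min(voxel) by linear interpolation. Illumination
correction divides by the smoothed (moving average, window 15) column-mean
profile normalized to its median. Downsampling mean-pools in windows of
round(target/voxel) voxels, dropping trailing partial windows.

## Soma localization

Scale-normalized Laplacian-of-Gaussian blob detection over physical scales
σ ∈ {3, 4, 5, 6, 7, 8.5, 10} μm (per-axis sigmas σ/voxel handle
anisotropy), with the detection radius reported as √2·σ*. The published
pipeline used a separately published localization algorithm whose internals
are not reproduced here; this detector satisfies the same contract (centers
and radii from foreground) and that substitution is deliberate. Candidates
must be local maxima of the best-scale response, exceed 6 robust SDs
(MAD-based, smallest scale) of the background response, lie on the
extracted foreground (Otsu by default; for dark-cell data foreground is
≤ threshold), and exceed the robust background intensity by 4 MAD-SDs —
the last gate matters when cells are sparse and a smooth gain field pulls
the histogram split into the background mode. Greedy non-maximum
suppression keeps the higher score within
max(15 μm, 0.9·(r_i + r_j)); ties break lexicographically by center. The
threshold multiplier was raised from a conventional 3 to 6 because at 3 the
smallest scale passes noise maxima on clean scenes; both are configurable.

## Volumetric segmentation

The built-in segmenter is classical and deterministic; a registry
(`register_segmenter_plugin`) admits alternative segmenters (e.g. a trained
3D network) under the same contract, validated at call time (single
connected component containing the seed; empty output maps to
`SeedRejected`).

Steps: (1) background statistics from the cube's 2-voxel margin shell,
median and 1.4826·MAD, restricted to the non-padded region; (2) seed must
exceed background by 4 SDs, else `SeedRejected`; (3) adaptive growth —
re-threshold the cube at |I − region mean| ≤ 3σ_bg, keep the connected
component containing the seed, update the mean, iterate to stability (≤ 12
iterations, vectorized equivalent of voxel-by-voxel adaptive growth);
(4) if another detection's seed falls inside the region, split by watershed
on the Euclidean distance transform with all seeds as markers; (5) closing
then opening. Growth and morphology run inside an 80-μm working box around
the seed, falling back to the full cube if the region reaches the box
boundary.

Morphological radii map to k-fold openings/closings by a unit ball of
radius max(voxel): k = floor(r/max(voxel)). The B, B², B³, … structuring-
element family is a true granulometry, so mask volume is exactly monotone
non-increasing in the opening radius — which discrete Euclidean-ball
openings do not guarantee. Defaults: closing 1 μm, opening 1.5 μm (removes
1-μm dendrite stubs while preserving somata of radius ≥ 3 μm). The cleanup
costs ~3–4% of giant-cell volume (tapers and stubs are shaved), well inside
the 10% recovery tolerance; small smooth cells lose < 1%.

## Morphometry

Volume = voxel count × voxel volume. Mean gray is reported on raw stored
intensity. Longest radius = max distance from the staining-intensity-
weighted centroid (inverted gray under dark-cell polarity) to a surface-
voxel center; an alternative reading — half the maximum Feret diameter — is
not used but the centroid convention is isolated in one function if it must
change. Principal axes come from the second-moment tensor of voxel centers
in physical coordinates; extents are projection ranges.

The three shape ratios are reconstructions (their defining document is not
publicly available): rect_axial_ratio = longest/shortest extent of the
principal-axes bounding box; the max-section is the largest-area planar cut
through the centroid normal to one of the three principal axes, sampled by
trilinear interpolation at half the smallest voxel;
maxsec_distance_ratio = max/min centroid-to-contour distance on that
section (sub-voxel marching-squares contour); maxsec_axial_ratio = √ of the
eigenvalue ratio of the section's second moments. All ratios are ≥ 1 and
rotation-invariant to within ~10% discretization scatter.

## Cell typing

K-means is our own Lloyd implementation (k-means++ init, 10 restarts, 300
iteration cap, per-iteration objective exposed for the monotonicity
invariant); scikit-learn serves as an independent cross-check in tests.
The typing features are z-scored per column by default — their scales
differ by orders of magnitude and unstandardized Lloyd would be volume-
dominated; `standardize=False` preserves the literal raw-feature reading.
The source describes the three features as "principal components"; we read
this as the three features themselves (no PCA), and expose both modes. The
cluster with the larger mean volume is labeled giant.

Shape assignment is nearest-archetype in z-scored ratio space (the z-frame
comes from the archetype signatures so a single cell classifies identically
in any batch). The archetype table is derived at first use from noiseless
axis-aligned renders of the generator's own shape archetypes (4000 μm³;
1400 μm³ for the spheroid) and cached. The table has four classes; the flat
class carries two signatures (oval and triangular) because the two flat
variants sit far apart in ratio space and a single averaged signature would
misclassify both. A deterministic nearest-archetype rule is used rather
than unsupervised k = 4 because the classes were identified before being
separated in ratio space; an exploratory `kmeans_cluster(k=4)` path remains
available.

## Evaluation and export

Matching is greedy one-to-one in ascending pair distance within 10 μm (the
co-detection criterion is not published; greedy ascending-distance is
deterministic and near-optimal for well-separated somata). Recall and
precision are percentages of the manual and automatic counts; per-block
reports aggregate mean ± SEM (SD/√blocks), excluding blocks with empty
manual sets with a warning. SWC export writes one type-1 node per soma with
parent −1 (a point-cloud use of the format); the density grid floor-bins
centers at 20 μm and always conserves the cell count (out-of-extent centers
clamp to edge bins with a warning).

## Pipeline

Per-stage seeds derive from the global seed as
`SeedSequence((seed, stage_index))` with a fixed stage table, so stages are
independently rerunnable and whole runs are byte-reproducible. Problem
sizes used throughout (400–450-μm scenes, 1-μm voxels, 631- and 286-cell
panels, five 512-μm evaluation blocks) were chosen as the smallest
conditions that reproduce the population statistics they encode.

## What the synthetic conditions do not show

The generator emulates soma-scale geometry, staining polarity, noise and
smooth illumination bias. It does not emulate tissue texture (neuropil,
fiber tracts, blood vessels), sectioning artifacts, dense cell packing with
true contact, partial-volume effects at 0.33-μm resolution, or the
morphological continuum between cell types — the fixtures are deliberately
separable where the source analysis treated separability as given. Passing
recovery tests therefore validates the pipeline's internal consistency and
its statistical machinery, not its performance on real tissue. Whole-brain
counts (~10⁴ giant cells across ~10¹³ voxels) are out of desk-scale scope.
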