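# Methods

## Problem and scope

`chondromorph` quantifies the 3D morphology of chondrons — chondrocytes
together with their pericellular matrix — in desktop micro-CT volumes of
dried articular cartilage. In such volumes the cells' water is gone, so
chondrons appear as hypo-intense lacunae inside brighter extracellular
matrix (ECM). The pipeline selects candidate chondrons automatically,
segments each one, and reports per-chondron volume, surface area, Wadell
sphericity, depth from the articular surface, depth zone, and zone-wise
densities and descriptive statistics. Manual quality control is supported
through exported orthogonal-view montages and a decision CSV rather than an
interactive viewer, so every verification step is scriptable and
reproducible.

No public micro-CT chondron data exist, so the package ships a synthetic
phantom generator that plants known chondrons into a cartilage-like slab;
all quantitative validation in the test suite runs against this planted
ground truth.

## Candidate selection

The working volume is cropped to the cartilage slab (see *Tissue frame*),
thresholded with the Otsu criterion (256-bin histogram, maximal
between-class variance), taking the dark phase as candidate foreground, and
labeled into 3D connected components (26-connectivity by default). A cheap
size pre-screen (default 25 to 1e6 voxels) removes single-voxel noise and
tissue-scale components before the expensive per-candidate work; the
morphological minimum-volume rule proper is applied after segmentation.
Each surviving component yields a sub-VOI: its bounding box dilated by a
margin (default 20 voxels) so probe spheres fit, with the component
centroid — snapped to the nearest foreground voxel, since centroids of
concave clusters can fall outside the object — carried along as the seed.

Note that Otsu class assignment is invariant to affine intensity transforms
but not to arbitrary monotone ones (between-class variance depends on bin
values, not only their order), so detection invariance is only guaranteed,
and only tested, for `a*I + b` with `a > 0`.

## Segmentation

Each sub-VOI is first contrast-enhanced by global 3D histogram
equalization (256 bins): intensities are mapped through the normalized
cumulative histogram, a monotone map onto [0, 1]. Equalized values are
intensity ranks, which makes everything downstream invariant to affine
transforms of the input and gives "dark" an absolute meaning within the
sub-VOI.

Segmentation grows a region from the seed (breadth-first, 26-connected).
A voxel is accepted when both:

1. **Darkness.** Its equalized intensity is within the contrast margin
   (default 0.1) of the seed's equalized intensity, capped at the
   sub-VOI's own Otsu split in rank space. Since chondrons are the
   minority phase, seed values are small ranks; this test reproduces the
   chondron/ECM partition with voxel accuracy. The Otsu cap keeps the
   darkest tail of the matrix noise from qualifying, which would otherwise
   let growth bridge between nearby chondrons; a seed on the bright side
   of the split is rejected outright as a false candidate.
2. **Volumetric continuity.** Its multiscale interiority score reaches the
   threshold tau (default 0.25). The score probes the gray-level
   distribution on the surfaces of concentric spheres: for each radius r,
   f_r is the fraction of n near-uniform surface samples (deterministic
   Fibonacci lattice, default 64; trilinear interpolation) that are still
   chondron-dark, and the score pools f_r over radii with weights
   proportional to r^2 (surface area). 1 means deep interior at every
   probed scale, 0 means background.

The score alone cannot place the boundary: a probe sphere of radius
comparable to the object sees mostly ECM even at the true interface (for a
locally flat interface a voxel at depth d has f_r ≈ (1 + d/r)/2, and
convex curvature lowers this further), so any fixed threshold on the score
erodes small objects in a size-dependent way. Hence the two-condition
design: darkness fixes the boundary, the score severs thin spurious
bridges and stops growth through bright chondrocyte remnants treated as
background texture.

Probe radii default to fractions (0.15, 0.3, 0.45, 0.6) of the candidate's
equivalent-sphere radius (from the dark connected component containing the
seed), floored at one voxel, so the probes scale from single cells to
clusters automatically; a fixed radius list can be configured instead.
The acceptance suite measures the resulting per-object Dice agreement and
volume accuracy against planted phantom truth.

After growth the mask is morphologically closed (radius-1 ball) to fill
pinholes left by bright remnants, and the single connected component
containing the seed is returned. Masks below the minimum volume (default
400 um^3, inclusive at the boundary — at 1.6 um voxels, 97 voxels are
rejected and 98 kept) are discarded as probable artifacts. Finally,
near-duplicate masks (pairwise Dice > 0.3, resolved transitively) are
reduced to the largest-volume member of each overlap group.

## Morphometry

* **Volume** V: voxel count x voxel volume (exact).
* **Surface area** S: level-0.5 marching-cubes mesh of the (zero-padded)
  binary mask, relaxed with a Humphrey filter (alpha 0.2, beta 0.5,
  20 iterations) before measurement. Raw marching cubes on binary data
  overestimates the area of smooth objects by ~8% (staircase bias), which
  would depress sphericity of every round object; the shrink-resistant
  relaxation brings a 24-voxel-radius ball within ~1% of the analytic
  sphere area while keeping a 20-voxel cube within ~5% of exact.
  `smooth_iterations=0` selects the raw mesh.
* **Wadell sphericity** Sph = pi^(1/3) (6V)^(2/3) / S; 1 for a sphere.
  Meshed phantom shapes stay below 1.02 (mesh tolerance). The measure is
  scale invariant in the voxel size.
* **Tissue frame**: the cartilage slab is located along z by Otsu
  separation of air vs tissue; the articular surface is the first slice
  whose tissue-area fraction reaches the threshold (default 0.5), the
  bottom one past the last. Both indices accept manual override. Depth is
  measured from this single flat surface plane — per-column surface maps
  are out of scope — as percent of slab thickness at the chondron centroid
  z-coordinate.
* **Zones**: 1 = [0, 10)%, 2 = [10, 40)%, 3 = [40, 100]% depth — half-open
  bands, zone 3 closed at 100%, so every in-tissue depth maps to exactly
  one zone. Centroids outside the frame are flagged (NaN depth, no zone)
  and excluded from summaries, never dropped silently.
* **Density**: chondrons per mm^3 per zone, with denominator = VOI
  cross-section x zone thickness (tissue is assumed to fill the VOI
  laterally; the phantom satisfies this by construction).
* **Summaries**: per zone (and optional group label): n, density, and for
  volume and sphericity the mean, SD, median, quartiles/IQR and a t-based
  95% CI on the mean. With n < 2 the dispersion statistics are NaN
  markers. Model-based inference (e.g. mixed models) is deliberately out
  of scope; the record CSV is designed to feed any external stats package.
* **Subsampling**: uniform without replacement, seeded, input order
  preserved — mirrors inspecting a fixed number of chondrons per sample.

## Dice validation and manual verification

DSC = 2A/(B + C) with A the common voxel count and B, C the per-mask
counts; masks with different offsets are resolved in the shared parent
frame, so sub-VOI masks compare directly against whole-VOI truth. Two empty
masks are an undefined-metric error. Verification montages show the three
orthogonal planes through the mask centroid with the mask outline in red;
decisions (id, verdict, optional single/cluster classification) are read
back from CSV, with unknown ids and conflicting duplicate verdicts
rejected.

## Phantom generator

The phantom emulates the features the pipeline depends on: air above a flat
articular surface at a known slice; an ECM slab (default intensity 0.65);
hypo-intense ellipsoidal chondrons (default 0.25) with uniformly random
orientation; fused 2–4-ellipsoid clusters with probability 0.3; additive
Gaussian noise clipped to [0, 1] (default SD 0.03); everything derived from
one integer seed, bit-identically reproducible.

Depth structure follows zone-wise planted conditions. The default
("intact-like") parameter set uses densities (3418, 5131, 4349)
chondrons/mm^3 in zones 1–3 and per-zone mean semi-axes derived from mean
zone volumes of roughly 5.6, 5.9 and 11.6 x 10^3 um^3 via abc = 3V/(4 pi),
with 15% SD per axis. An "OA-like" set plants zone 1–3 volumes larger by
~1.5/1.9/1.7x with more elongated axes (analytic sphericity lower by
~0.04–0.05 in zones 2–3) at slightly lower superficial density, for
group-contrast experiments.

Per zone, the object count is drawn from a Poisson law with rate density x
zone volume; each object is then placed fully inside the cartilage slab
with a clearance margin (default 3 voxels) between objects and 2 voxels to
the lateral faces, redrawing the position (and if needed the shape) on
collision up to a bounded retry budget. Counts are therefore exactly
Poisson-consistent with the planted rates; the cost is that centers of
large objects are under-represented immediately below the articular
surface, since objects must fit inside the slab. Densities too high for
non-overlapping placement raise a placement error.

What the phantom does **not** emulate — and what passing tests therefore do
not show about real specimens: reconstruction artifacts (beam hardening,
rings, streaks near the calcified interface), the irregular and shrunken
cartilage surface of dried tissue, intensity inhomogeneity and partial
volume blur, bright intra-chondron remnants, and truly touching chondrons
(the clearance margin separates objects so that detection and segmentation
can be validated independently). Real-data performance near the surface and
the calcified interface must be assessed by manual verification.

## Problem sizes and determinism

Test and acceptance runs use desk-scale volumes chosen by the package:
the default phantom is 230 x 160 x 160 voxels at 1.6 um (~0.024 mm^3 of
cartilage, ~100 chondrons); group-contrast experiments use twenty
150 x 192 x 192 replicates per group, sized so zones 2/3 hold roughly
30/50 chondrons and the planted mean contrasts dominate sampling noise.
One seed governs phantom synthesis and record subsampling; identical
configuration and seed reproduce byte-identical record tables.

## Known limitations

* The depth model assumes a flat articular surface; tilted or eroded
  surfaces bias depth percentages.
* Touching chondrons are not split (no watershed); they are detected as one
  candidate and typically classified as clusters during verification.
* The density denominator assumes tissue fills the VOI laterally.
* Otsu-based candidate selection assumes a bimodal chondron/ECM histogram
  within the slab; strong inhomogeneity would require local thresholding,
  which is not implemented.
* Sub-voxel partial-volume rendering is not simulated; measured volumes on
  real data will carry a small positive staircase bias absent from the
  phantom validation.
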