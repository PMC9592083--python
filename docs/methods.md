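# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `synapsekin`. Conventions throughout: axis order
`(t, channel, z, y, x)`, 0-based voxel indices, micrometres and seconds;
`t = 0` is the frame of cell arrival (first contact between the cell
mask and the 1-voxel-dilated droplet mask).

## Droplet mechanics

The antigen-coated droplet is treated as a sphere of surface tension
`gamma` (mN/m) and radius `R` (um); its stiffness proxy is the Laplace
pressure `dP = 2*gamma/R`, numerically in kPa in these units. Nothing
beyond this scalar is modelled — no wetting or deformation physics.

## Phantom generator

Real doublet movies are not publicly deposited, so correctness is
demonstrated on synthetic phantoms with recorded ground truth. The
generator emulates the live-imaging geometry: 21 z-planes at
dz = 0.7 um, 0.325 um in-plane pixels, one stack per 30 s, a droplet of
radius 4.7 um (the median of the droplet preparation) and a cell of
radius 6 um overlapping the droplet only at a thin contact cap.

Rendering choices:

- **Solids** (cell body, nucleus, droplet) are Gaussian-smoothed
  indicator functions (sigma = 1 voxel); **puncta** (centrosome,
  organelles) are isotropic Gaussians (sigma = 0.5 um). This mimics PSF
  blur without an optics model.
- **The droplet/antigen channel is a filled body, not a thin surface
  shell.** A sub-voxel fluorescent shell is not resolvable at this
  sampling: once blurred, its threshold-and-fill segmentation inflates by
  about 1 um, whereas the smoothed solid keeps its half-maximum boundary
  on the analytic sphere. Antigen accumulation is applied as a purely
  angular modulation (factor `r(t)` inside the contact cap, 1 outside),
  so the programmed synapse/opposite surface ratio is exact before noise.
- **Nucleus invagination**: the nucleus is a sphere whose surface radius
  is reduced by a raised-cosine bowl, `depth * cos^2(pi*phi/(2*theta))`
  inside the cap of angular radius `theta` (defaults: radius 3.4 um,
  depth 1.6 um, theta 55 deg). A hard spherical-cap carve was rejected
  because its sharp rim crease — not the apex — would carry the minimal
  mean curvature; the smooth bowl reproduces the geometry of a
  bean-shaped nucleus, whose most concave point is the bottom of the
  invagination.
- **Noise**: Poisson shot noise at a configurable photon scale plus
  additive Gaussian read noise (the standard two-parameter sCMOS model);
  photobleaching as a per-frame multiplicative decay. All randomness
  flows from one integer seed; identical parameters and seed give
  bit-identical volumes.
- **Kinetic-trace fixtures** are piecewise-linear through programmed
  control points in three families — transient peak, decay-to-plateau,
  decay-minimum-rise — matching the curve classes of synapse enrichment,
  organelle approach and nucleus transport. **Migration fixtures** are
  correlated random walks with fixed step length whose turning angle is
  `(1 - persistence) * U(-pi, pi]`.

What phantoms do *not* emulate: realistic intensity texture, cell
deformation over time, organelle shape (clouds are point sets), optical
anisotropy of the PSF, or drift. Passing tests demonstrate that the
measurement chain recovers known ground truth under controlled imaging
physics, not that segmentation is robust to every real-data artifact.

## Segmentation

- **Droplet**: automatic Otsu threshold on the antigen channel, hole
  filling, largest connected component (ties broken by total intensity);
  a warning is issued if the result's sphericity falls below 0.7. The
  droplet mask is computed once at arrival and held fixed — droplets are
  trapped and immobile; multi-droplet mode labels every component
  per frame.
- **Cell**: per frame, subtract a Gaussian-blurred (sigma 4 px)
  empty-field reference (flat median fallback), blur with sigma 2 px
  in-plane, threshold with Huang's fuzzy-entropy criterion, keep the
  largest component, fill holes. The source recipe's "radius" is read as
  the Gaussian sigma in pixels; both sigmas are arguments.
- **Huang threshold**: exhaustive 256-level scan minimizing the Shannon
  entropy of fuzzy memberships `1/(1 + |g - m_class|/C)`. The entropy is
  exactly flat across empty histogram valleys, so ties are resolved to
  the lowest level on the optimal plateau rather than by floating-point
  summation noise. A known property, documented here deliberately: on a
  blurred object over a clean background Huang settles just above the
  background peak, so the cell mask includes the ~1.3-sigma blur skirt.
  On noise-free phantoms this caps the mask's Jaccard overlap with the
  analytic cell near 0.7 (recall stays above 0.95); tests assert those
  honest figures. Real cortical-reporter images have sharper effective
  edges relative to their noise, where the recipe originated.
- **Punctum detection**: brightest voxel inside the search mask, refined
  to the intensity-weighted centroid of its 3x3x3 neighborhood; a
  detection requires the peak to stand 3 robust standard deviations
  (1.4826 x MAD) above the masked median.
- **Distance maps**: exact Euclidean distance transform with physical
  sampling; zero inside the droplet (organelles should not be inside —
  clamping avoids negative distances).

## Synapse metrics

- **Antigen recruitment**: droplet-surface voxels on the droplet-center
  plane +/- 1 are split into the cap facing the cell-center axis
  (half-angle 60 deg) and the antipodal cap; the ratio of cap means is
  normalized by its value at arrival. The cap aperture and plane count
  are not dictated by the source workflow and are exposed as arguments.
- **Shell enrichment**: channel sum over cell voxels within `width` um
  of the droplet, divided by the whole-cell sum (`cell_total`) and/or
  its arrival value (`t0`). Presets: `actin2um` (2 um, both),
  `dag1um` (1 um, t0), `gefh1_1um_1plane` (single synapse-center plane),
  `exoc7_1um_6planes` (6 planes at dz 0.34 um).
- **Multi-synapse scoring**: contact regions are connected components of
  cell voxels within 1 um of any droplet; a merged cap touching both
  droplets counts as one synapse. Per-synapse enrichments for the
  asymmetry score restrict the shell by a Voronoi split (each voxel
  assigned to its nearest droplet).
- **Actin maxima**: h-maxima (prominence default 3x the robust noise
  s.d. of the projection) inside the cell mask on maximum z-projections;
  distances to the droplet boundary on the 2D distance map.

## Kinetics

All characteristic values are extracted from single-cell traces smoothed
with Tukey's 3R running median (window 3, endpoints copied, iterated to
convergence; an iteration cap of 100 guards the loop). 3R is idempotent,
range-bounded, and erases single-sample extrema — hand-built fixtures
therefore carry two-sample troughs. Crossing detection uses strict
inequality at sample points with no sub-frame interpolation: times are
quantized to the 30 s frame interval, the resolution of the data.

- Peak time/value: extremum of the smoothed trace in 0-10 min.
- Plateau: mean of the **raw** values over 25-30 min (whether the source
  workflow smoothed before plateau averaging is unknowable; raw values
  chosen and documented here).
- Polarization times: first smoothed crossing below the
  threshold, gated on a starting distance above `start_gate` —
  centrosome 2/3 um, Golgi 4/5 um, lysosomes 3/4 um.
- Last-local-minimum time (nucleus rearward transport): latest interior
  sample <= both neighbors and < at least one; plateau minima resolve to
  the plateau's last sample; traces without an interior minimum fall
  back to the latest global-minimum sample.
- Orientation time: first smoothed theta_N < 45 deg.
- CV uses the sample (n-1) standard deviation — per-cell frame counts
  are small.

## Nucleus geometry

The nucleus mask (isotropic voxels) is blurred (sigma 1 voxel) so the
0.5 level set interpolates the boundary sub-voxel-accurately, triangulated
by marching cubes, and smoothed with 10 Taubin iterations
(volume-preserving, so curvature is not biased by shrinkage). Mean
curvature is the cotangent-Laplacian estimate with Meyer mixed vertex
areas, signed so a convex sphere is positive (H = 1/R); because
marching-cubes triangles are irregular, the raw pointwise field is
regularized by 15 passes (default) of area-weighted neighbor averaging —
on a voxelized 5 um sphere every vertex then sits within 10% of 0.2 1/um
(at 30 passes), while a 1.6 um dent still carries clearly negative apex
curvature.

The invagination is the vertex of globally minimal mean curvature. When
several local minima lie within 10% of the global minimum (multi-lobed
nuclei) and a previous-frame apex is known, the nearest candidate is
chosen; the 10% band is this package's choice, as the source workflow
states no width. A surface whose curvature range is below 5% of its mean
magnitude (a sphere) has no invagination and raises an error.
Orientation angles are planar angles at the cell-mask centroid
(cell center) toward the droplet-mask centroid; theta_N uses the
invagination apex, theta_centrosome the centrosome position. Their
association is summarized by the Spearman rank correlation over the
first 15 min.

## Profiles

The droplet mask is fitted by moments (centroid + principal axes of the
voxel inertia tensor; semi-axes are sqrt(5) x the principal standard
deviations of a solid ellipsoid — robust on filled masks, no
initialization). The volume is rigidly resampled (trilinear; the 2D
interpolation of the source workflow promoted to 3D) so the principal
axes align with the grid, longest on x and shortest on z. The radial
synapse profile average-projects 25 planes (1 um at SIM sampling; count
and spacing are arguments for other modalities) about the ellipsoid
center and bins by in-plane radius with full azimuthal averaging — the
natural 3D extension of averaging the two directions of a symmetric
linescan — then normalizes to the maximum. The axial polarity profile
sums intensity in equal slabs along the synapse axis and rescales the
abscissa to [0, 1] (0 = synapse).

## Shape and migration

Aspect ratio is the major/minor axis of the second-moment-equivalent
ellipse (the descriptor used by the common image-analysis tools, not a
bounding box); solidity is area over convex-hull area; both from maximum
z-projections. Migration analysis keeps only migrating cells (net
displacement > 20 um over the movie), crops each track from the first
step > 6 um (one cell radius) through the following 30 frames (4-min
sampling), and computes the confinement ratio (net displacement / path
length) and the mean unsigned turning angle per second, with stalled
(zero-length) steps dropped. Both numerator and denominator of the
confinement ratio use the cropped segment.

## Statistics

Group comparisons delegate to scipy: Mann-Whitney U for two groups,
Kruskal-Wallis for more, followed by Dunn's post test (implemented here:
pooled mid-ranks with tie correction, two-sided normal z tests,
Bonferroni adjustment over pairs — no installed package provides it).

## Problem sizes

Tests and the acceptance script run on desk-scale phantoms chosen to
exercise every code path at full fidelity: 21 x 72 x 72 voxel movies of
4-12 frames, 26-44-cube nucleus grids, 40-frame traces with 200 noisy
replicates, and 100 trajectory pairs. These sizes match the native
acquisition geometry per frame; only movie length and replicate counts
are reduced relative to a full experiment.

## Known limitations

- The cell mask inherits Huang's skirt bias on soft-edged objects (see
  above); enrichment metrics normalize per cell, which cancels most of
  the effect, but absolute mask volumes run ~20-40% high on blurred
  noise-free inputs.
- Invagination detection assumes one dominant concavity; multi-lobe
  handling is limited to the nearest-neighbor tie-break.
- No deconvolution, drift correction or denoising beyond the recipes
  described; inputs are assumed pre-reconstructed.
- Characteristic times are frame-quantized; no sub-frame interpolation.
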