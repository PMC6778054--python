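# Methods

This note documents the models and algorithmic choices behind `fibgold`:
what the synthetic phantom emulates, how each pipeline stage works, which
parameters matter, and what the validation does and does not show.

## Coordinate and unit conventions

Volumes are indexed `(z, y, x)`; the physical position of voxel `(i, j, k)`
is `origin + (i·dz, j·dy, k·dx)` in nanometres.  All geometry — distance
transforms, structuring elements, particle coordinates — is computed in nm
on the anisotropic grid (a voxel-count distance would be wrong by 9× along
z at the default 90 × 10 × 10 nm spacing).  Reported volumes are µm³ and
areas µm².  The default acquisition geometry follows slice-and-view
practice: a 30 nm nominal mill with every third face imaged gives 90 nm
between the imaged sections (`effective_section_spacing`).

## The phantom generator

The generator (`fibgold.synthetic`) renders one nucleus per volume with
exhaustive ground truth.  Its defaults define the standard validation
conditions; every stochastic element is driven by one seed.

**Nucleus.**  A superellipsoid (exponent 2 = ellipsoid by default) voxelized
by its centre-inequality; default semi-axes 1620 × 1400 × 1200 nm in a
48 × 320 × 320 grid.  For the exact-ellipsoid case the analytic volume is
carried along (and the surface area: exact for a sphere, Thomsen's
approximation otherwise, flagged approximate).

**Invaginations.**  Type II nucleoplasmic reticulum is modelled as tubular
voids (default radius 150 nm, depth 600 nm) entering the envelope within a
section plane and pointing at the nucleus axis.  Horizontal entry is both
what 90 nm sectioning can resolve and what per-section counting implies.
Tubes are resampled until their axes are ≥ 3 radii apart; placements that
cannot satisfy that merge-avoidance policy raise.

**Labels.**  Gold particles (diameter uniform in 20–30 nm) are planted by
stratified hard-core sampling: exact stratum counts, minimum pairwise
centre distance 50 nm, rejection sampling with an explicit
feasibility bound (random-close-packing fraction 0.64) and a packing error
naming the offending region.  Strata: cytosolic mislabels first (default
10%), then invagination-associated nuclear labels (a configurable share
placed within 50 nm of an invagination surface), then the remaining nuclear
labels split peripheral/central.  Guard bands make the planted truth
unambiguous: associated labels sit ≤ 50 nm from the invagination,
non-associated ones ≥ 180 nm, nuclear labels ≥ 30 nm inside the envelope
and cytosolic ones ≥ 60 nm outside it, so a detector's ≤ 45 nm
z-quantization cannot flip a planted classification at the 100 nm
association criterion.  Region labels are always re-derivable from the
distance transform of the final mask.

**Rendering.**  Intensity ladder (arbitrary units): cytosol 0.2, nuclear
interior 0.35, membrane band 0.7 (voxels within 30 nm of the envelope),
particle amplitude 1.0 as an in-plane Gaussian whose FWHM equals the
particle diameter, placed in exactly one section (20–30 nm ≪ 90 nm
sections).  Three texture fields make the phantom registerable and
segmentable the way real stained sections are: thresholded organelle
bodies in the cytosol (sharp membranes, z-coherent over ~270 nm), chromatin
granularity inside the nucleus (amplitude 0.15, ~100–300 nm domains
persisting across adjacent sections) and a fine cytosolic grain.  Without
such section-spanning fine structure, consecutive-section registration is
genuinely ill-posed: the only shared content would be the smooth envelope,
whose ring-to-ring correlation peaks away from the true shift wherever the
cross-section changes quickly.  Per-slice translational drift is a
reflected random walk (σ = 2 px/section by default, bounded at ±15 px —
operators re-centre the field of view, and an unbounded walk would push
the nucleus out of frame).  Poisson–Gaussian noise is applied last
(scaled-Poisson shot noise at 200 counts per unit, Gaussian readout
σ = 0.08).  The paper-style spot SNR — amplitude over the total background
fluctuation including chromatin texture — is then ≈ 5.7, above the ≥ 5
level at which the detection and registration contracts are validated.
Imaging noise levels are not reported for this kind of experiment; these
defaults are our choice and are documented, not inferred.

## Registration

Consecutive-pair estimation accumulated to slice 0, translation-only (the
drift of a FIB-SEM stage is predominantly translational, and integer
translations invert exactly).  Each pair is band-passed
(difference-of-Gaussians, σ = 1 and 6 px): the lower scale suppresses shot
noise, the upper removes slowly varying intensity whose apparent lateral
motion between sections (the phase drift of any low-frequency field) would
bias the peak.  A first FFT cross-correlation (upsampled 20×) locates the
peak; an agreement mask then drops the worst-disagreeing decile of pixels —
where structure genuinely appears or vanishes between sections, e.g. the
first section of the nucleus — and the shift is re-estimated by an explicit
masked NCC scan, snapped to the integer lattice (default) or refined by
quadratic interpolation (`subpixel`).  Vacated margins after alignment are
filled with the slice mean, which keeps downstream intensity statistics
unbiased.  On phantoms at SNR ≥ 5 the integer walk is recovered exactly and
fractional walks within 0.5 px RMS.

## Particle detection

Per-slice 2D detection with 3D coordinates: a 25 nm particle cannot span
two 90 nm sections, so 3D blob linking would only manufacture artifacts.
Stages per section:

1. **Candidates** — scale-normalised Laplacian-of-Gaussian over scales
   spanning the physical diameter band (default 20–30 nm), computed on the
   residual over an isotropic median background (cancels most of the
   systematic edge response of bright membranes).  Threshold: slice median
   + k·MAD of the response, k = 6.
2. **z-singleness** — a label exists in one section only, while membrane,
   chromatin and organelles persist; the matched-filter amplitude on the
   neighbour-subtracted slice must reach 5 robust s.d.
3. **Oriented residual** — steeply inclined membrane can be single-section
   too, but it is locally linear; the residual over an oriented background
   (max of annular line-oriented medians, 13 px lines with the central
   ±2 px blanked so a punctum cannot raise its own background) must reach
   4 robust s.d.  Kept unsmoothed: averaging would mix in the negative
   ring around a peak and cancel genuine labels sitting on the membrane.
4. A principal-curvature (ridge) test, sub-voxel in-plane centroid,
   diameter from the scale of maximal response, z at the section centre,
   and a 20 nm same-slice duplicate merge.  (The merge radius is smaller
   than the hard-core distance on purpose: a 3D hard-core process
   legitimately projects same-slice pairs to ~22 nm in plane.)

The two verification constants were calibrated on phantom ROC curves; on
the standard phantom both recall and precision are ≥ 0.95.  Residual
misses concentrate at membrane-hugging labels — the genuinely ambiguous
population in single-section data.

## Nucleus segmentation

The nuclear envelope is the most reliable landmark, so segmentation is
envelope-based: smooth at 30 nm, threshold at half-peak between the
nuclear-interior level (median of the above-Otsu class) and the envelope
level (99.5th intensity percentile — Otsu class splits cannot isolate a
structure holding ~1% of the volume); per section, dilate the band by
40 nm to seal noise gaps, flood-fill the closed contour, erode back.  A
coarse gate (in-plane 150 nm smoothing, Otsu, opening, directional
re-dilation bounded to two sections in z) removes bright cytosolic bodies
attached to the envelope and forbids debris beyond the true nuclear
extent.  The boundary is then re-centred on the band by a 15 nm in-plane
erosion (the filled contour follows the outer half-peak crossing) and
regularised by averaging the binary surface over 60 nm laterally
(curvature bias σ²/2R: < 2 nm on the nucleus, ~12 nm inside a 150 nm
invagination tube).  Erosion and regularisation act in-plane only so thin
end-cap sections survive.  On phantoms the Dice overlap with the planted
mask exceeds 0.95 (asserted in the test suite), and downstream recovery
of shell densities and per-section invagination counts (below) bounds
the boundary accuracy much more tightly.

## Morphometry, shell, invaginations

*Volume* is voxel count × voxel volume.  *Surface area* is the area of the
marching-cubes isosurface of the padded, lightly smoothed mask
(σ = 1.5 voxels; on binary data the raw isosurface carries a staircase
excess, and this smoothing makes the error shrink monotonically under grid
refinement — ball and box areas converge to their closed forms within
2% / 5%).  *Sphericity* is Wadell's S; since its absolute value depends on
the area estimator, cross-study comparisons of S should be qualitative.

The *peripheral shell* is the set of nucleus voxels whose anisotropic EDT
to the outside is ≤ 150 nm (boundary-equal voxels are peripheral); the
central region is the exact complement within the nucleus.

*Invaginations* are the residue of a per-section 2D morphological closing
of the section outline (in-plane disk, default radius 500 nm), 3D-labelled
across sections, kept when the maximal in-plane depth beneath the closed
outline reaches 200 nm.  Closing per section rather than with a 3D ball is
deliberate: the z-staircase of a 90 nm-sectioned surface would otherwise
read as deep concavities; the cost is blindness to purely vertical
invaginations, which 90 nm sectioning cannot resolve anyway.  "Per nucleus
section" averages the 2D cross-section counts (ignoring sliver
cross-sections below half a notch area) over all nucleus-intersecting
sections.

*Association* labels a nuclear particle as invagination-associated when
its centre lies within 100 nm (about one NPC diameter; configurable) of
the detected invagination volume, via the anisotropic distance transform.

## Spatial statistics

Minimum separation is the per-particle nearest-neighbour distance in 3D
physical nm, computed with a k-d tree whose output is tested for exact
equality against O(n²) enumeration; histograms (default 25 nm bins) are
built over per-particle minima, pooled across cells by default.  Densities
are counts over region volumes in µm³; the peripheral-to-central ratio is
a count ratio.  Group comparisons use two-tailed Mann–Whitney (independent
groups) or Wilcoxon signed-rank (paired), with the exact permutation null
for n ≤ 10 without ties and the tie-corrected normal approximation
otherwise.  With zero denominators or empty scopes the result is absent
(`None`), never silently zero.

## The cohort experiment

`run_cohort` mirrors a two-condition study at desk scale: nine "grooved"
nuclei (elongated, ~96 labels, 60% planted peripheral) versus nine "flat"
nuclei (rounder, ~44 labels, 30% peripheral), each rendered and pushed
through the complete pipeline.  Counts keep the 2× planted density
contrast; effect sizes were chosen so each planned test is decently
powered at n = 9, because two scaled-down features would otherwise mask
real effects: per-nucleus metrics average over tens (not hundreds) of
labels, and nearest-neighbour distances saturate near the 90 nm section
spacing when labels are too dense.  The cohort validates effect
*directions* and test behaviour, not the absolute magnitudes a full-scale
acquisition would produce.

## Problem sizes used in validation

The standard phantom is one nucleus of ~11 µm³ in a 48 × 320 × 320 voxel
stack with 300 labels; the cohort uses eighteen 24 × 160 × 160 stacks of
~0.7 µm³ nuclei with 26–100 labels each.  These sizes exercise every code
path while keeping the full suite comfortably runnable on a laptop.

## What the phantom does not emulate

No electron–matter interaction, curtaining, charging or milling-thickness
variation; no EDX spectra; membranes are uniform-brightness bands; the
nucleus is a single convex body apart from the planted tubes; textures are
Gaussian fields rather than biological chromatin.  Passing phantom tests
therefore demonstrates correct geometry, bookkeeping and statistical
machinery under controlled conditions — not robustness to every real-world
artifact.  On real stacks the envelope-based segmentation assumes a
stained, closed nuclear envelope, and absolute sphericity values carry the
area-estimator convention above.
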