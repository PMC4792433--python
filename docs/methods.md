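# Methods

## The statistic

A sampling field is a rectangle W (by convention 1×1 mm, coordinates in
micrometres) containing the positions of all cone cell bodies. The Voronoi
domain of cell i is the set of locations closer to i than to any other
cell, intersected with W. Domain areas x₁,…,xₙ are summarised by

* **density** n_total / |W| (cells/mm²), counting *all* cells — boundary
  exclusion applies to the area statistics only;
* **skewness** g₁ = m₃/m₂^{3/2} with mₖ = (1/n)Σ(xᵢ−x̄)ᵏ. Both moments use
  the biased 1/n convention, i.e. g₁ is the third standardised moment of
  the empirical distribution (equal to `scipy.stats.skew(..., bias=True)`);
* **coefficient of clustering** CC = (σₓ/x̄) / [(1/n)Σᵢ σ_{aᵢ}/āᵢ], the
  global coefficient of variation of retained domain areas over the mean
  local CV, where cell i's local CV is taken over the areas of its
  Voronoi-adjacent domains (the focal domain is not a member of its own
  neighbourhood). CC ≈ 1 when local and global variability agree; spatial
  segregation of small and large domains (rings) suppresses the local term
  and pushes CC well above 1.

## Geometry

Clipping is exact, not rasterised. The point set is augmented with its
reflections across the four window edges; inside W no location is ever
closer to a reflection than to its original, so the Voronoi diagram of the
augmented set restricted to W *is* the clipped diagram of the originals.
Every original cell is then a bounded convex polygon contained in W, the
polygons partition W (Σ areas = |W| to ~1e-15 relative in practice; the
package guarantees 1e-6), and shared edges are already clipped. Adjacency
is "shared edge longer than 1e-9 µm". The test suite checks this geometry
against two independent oracles: brute-force half-plane intersection and
nearest-point rasterisation.

**Boundary exclusion.** Default rule `window_touch`: a cell is dropped iff
its clipped polygon meets the window boundary (detected as a Voronoi ridge
against a mirror point, plus a vertex-on-boundary test for corner
contacts). This is the parameter-free reading of "exclude cells around the
boundaries"; `hull_peel` (drop convex-hull cells) is provided for
sensitivity analysis.

**Degenerate input.** Fewer than 4 points or a collinear configuration is
an error; exact duplicate points (< 1e-9 µm apart) are rejected by
`PointField` and removed with a warning by the readers. Constant area
vectors make g₁ and CC undefined (zero-variance error). Cells with fewer
than two eligible neighbours are dropped from the local CV average with a
warning; CC additionally requires `min_interior` (default 10) retained
cells.

**SD conventions.** σₓ and σ_{aᵢ} default to the sample (n−1) convention,
the default of mainstream numerical environments; the population (1/n)
variant is exposed (`sd_convention="population"`). g₁ always uses 1/n, as
its formula dictates. Boundary-flagged cells may contribute their clipped
areas to interior cells' neighbourhoods (`cc_neighbors="all"`, default);
restricting to interior-only neighbours is available but shrinks many
neighbourhoods below the 2-neighbour minimum.

## Group comparison

The experimental unit is the field/animal (3–4 per group), summarised as
mean ± SEM (sample SD / √n). "Student's t-test" is read as the classical
pooled-variance two-sample two-sided test (default); the Welch variant is
exposed because group variances of real densities can be very unequal.
Significance at α = 0.05.

## Synthetic mosaics

The generator produces the two phenotypes the statistics must separate,
over 1×1 mm at 5,600 cells/mm² by default (the reported density scale of
the degenerate retina):

* `ring` — hole centres by sequential inhibition (≥ 2.1× mean radius
  apart), truncated-Gaussian hole radii, `rim_fraction` of the cells
  placed uniformly on annuli [r−w/2, r+w/2] around their hole, the rest
  uniformly over the window; every placement respects the hard-core
  distance `min_spacing` (dart throwing, 10⁵ rejections → packing error
  naming the binding constraint).
* `homogeneous` — simple sequential inhibition at `min_spacing`.
* `poisson` — uniform fixed-count (binomial) placement, the stationary
  reference.

The cell count equals round(density × area) exactly, so paired ring and
homogeneous fields are density-matched by construction. One `numpy`
Generator seeded by `config.seed` drives every draw; a config fully
determines its field, and `ground_truth` regenerates and returns per-point
labels (rim vs background, owning hole).

Background cells are uniform over the *whole* window, holes included, so
`rim_fraction` interpolates continuously from a homogeneous-like mosaic
(rim_fraction 0 reproduces the hard-core reference in distribution) to a
fully ringed one; CC rises monotonically along the way. No published
measurements of the ring geometry exist, so the defaults — 45 holes/mm²,
radius 50 ± 11 µm, rim width 18 µm, rim fraction 0.9, hard core 4 µm —
were calibrated once so the default ring mosaic lands near the clustering
scale reported for degenerate retinas (CC ≈ 1.7–1.8) while the homogeneous
mosaic sits near 1.2, and then frozen. Feasibility limits the parameter
space: placing a fraction ρ of N cells on total rim area A_rim requires
ρN/A_rim to stay safely below the random-sequential-adsorption jamming
density ≈ 0.547/(π(min_spacing/2)²); configurations beyond it fail with a
packing error rather than silently degrading.

What the generator does *not* emulate: soma-size variation, local density
gradients across the retina, anisotropic or merged rings, annotation
errors (missed or double-marked cells), and temporal remodelling dynamics.
Passing tests therefore demonstrate the statistics' discriminative power
under idealised geometry, not robustness to every property of real
micrographs.

## Calibration facts computed by the suite

On stationary uniform-random fields (n = 5,000, 1 mm², 20 seeds) the mean
CC is ≈ 1.205 ± 0.009, not 1: Voronoi areas of a Poisson process are
locally positively autocorrelated (a cell in a sparse patch has large
neighbours too), so the mean local CV genuinely falls below the global CV.
CC should therefore be read against a simulated stationary reference, not
against the naive null value 1. Default ring fields exceed matched
homogeneous fields by ≈ 0.5 in mean CC, and with 3 fields per group the
pooled t-test detects the phenotype in ≥ 18 of 20 replicate experiments.

## Problem sizes

Unit tests run on quarter-scale (0.5×0.5 mm, 1,400-cell) fields; the
calibration test and the acceptance script use full-scale fields
(5,600 cells, plus twenty 5,000-cell stationary fields), chosen to keep a
complete run in the low minutes on one CPU while preserving the study's
sampling geometry.

## I/O conventions

Coordinate tables: CSV/TSV/XLSX, optional header, first two fully numeric
columns are x and y; units unknown in general, so readers expose
`unit_scale` (µm per input unit) and a window override — published
densities assume the window forced to the 1×1 mm sampling area.
Coordinates are Cartesian, origin bottom-left, y up; dot-image centroids
(row/col, y down) are converted on extraction. Dimensionless statistics
(g₁, CC) are invariant under `unit_scale`; density scales as
`unit_scale⁻²` (property-tested).
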