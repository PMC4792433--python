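# conemosaic

Voronoi-domain spatial statistics for cone photoreceptor mosaics.

In advanced retinal degeneration (e.g. the S334ter-line-3 rat model of
Retinitis Pigmentosa) the surviving cones abandon their near-regular mosaic
and crowd onto the rims of roughly circular, photoreceptor-free holes —
"cone rings". Disrupting the glial scaffold that maintains the rings
redistributes the cones homogeneously at essentially unchanged density, so
plain cell counts cannot tell the two arrangements apart. `conemosaic`
quantifies the *arrangement*: it treats each annotated field as a planar
point pattern, tessellates it into Voronoi domains, and summarises the
domain-area distribution with statistics that discriminate ring-patterned
from homogeneous mosaics.

For a field of n cells with Voronoi-domain areas x₁,…,xₙ (boundary-affected
cells excluded):

* **density** — cells per mm² of sampling window (all cells counted);
* **skewness** g₁ = m₃ / m₂^{3/2}, with central moments
  m_k = (1/n) Σᵢ (xᵢ − x̄)^k — the long right tail produced by cell-free
  ring centres drives g₁ up;
* **coefficient of clustering**

      CC = (σ_x / x̄) / [ (1/n) Σᵢ σ_{aᵢ} / ā_ᵢ ],

  the global coefficient of variation of domain areas divided by the mean
  local coefficient of variation, where āᵢ and σ_{aᵢ} are the mean and SD
  of the areas of the domains Voronoi-adjacent to cell i. When small and
  large domains segregate spatially (rings), local variation is suppressed
  relative to global variation and CC rises well above 1.

The tessellation is clipped exactly to the rectangular sampling window by a
mirror-point construction (the clipped polygons partition the window to
machine precision), and cells whose polygon touches the window border are
excluded from the statistics to remove edge artefacts.

The package also ships a seeded generator for both phenotypes — ring
mosaics (cells on hard-core annuli around inhibited hole centres) and
homogeneous hard-core mosaics at matched density — plus per-group
mean ± SEM summaries and the pooled/Welch two-sample t-test.

## Worked example

```python
from conemosaic import SyntheticConfig, generate_mosaic, MosaicAnalyzer

field = generate_mosaic(SyntheticConfig(mode="ring", seed=42))   # 1x1 mm, 5,600 cells
an = MosaicAnalyzer().fit(field)
print(f"cells: {an.n_total_}  interior: {an.n_interior_}")
print(f"density: {an.density_:.0f} cells/mm^2")
print(f"g1 skewness: {an.skewness_g1_:.2f}")
print(f"CC: {an.cc_:.2f}")
```

prints

```
cells: 5600  interior: 5420
density: 5600 cells/mm^2
g1 skewness: 3.87
CC: 1.64
```

5,600 cells were simulated on ring rims at the density of the degenerate
retina; 5,420 survive boundary exclusion. The strongly right-skewed
domain-area distribution (g₁ ≈ 3.9) and CC ≈ 1.6 are the ring signature —
the same field regenerated in `mode="homogeneous"` gives g₁ ≈ 0.98 and
CC ≈ 1.18.

`MosaicAnalyzer` is a scikit-learn-style estimator (`fit`,
`get_params`/`set_params`, fitted attributes with trailing underscores);
the same computations are available as plain functions
(`analyze_field`, `compute_voronoi`, `skewness_g1`,
`coefficient_of_clustering`, …).

### Command line

```sh
conemosaic simulate --mode ring --seed 7 --out-prefix scratch/ring7
conemosaic analyze scratch/ring7_coords.csv --out stats.csv --areas-out areas.csv
conemosaic histogram areas.csv --bin-width 50 --out hist.csv
conemosaic compare ring_stats.csv homog_stats.csv --statistic cc
conemosaic dots2coords annotated.png --threshold 0.5 --pixel-size 0.62 --out coords.csv
```

`analyze` accepts CSV/TSV/XLSX coordinate tables (header optional, first
two numeric columns are x and y, `--unit-scale` converts to micrometres,
`--window` forces the sampling rectangle); `dots2coords` extracts cell
centroids from white-dot annotation images.

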