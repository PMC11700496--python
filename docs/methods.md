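# Methods

## Grid model and conventions

All layers live on one projected planar grid in metres. Cell (r, c) has
its center at (origin_x + (c + 0.5)·s, origin_y − (r + 0.5)·s) for cell
size s; rows increase southward. Membership decisions — which cell
contains a point, whether a cell is inside a polygon or a buffer — are
made by the cell-center test throughout. This is one consistent choice
among several defensible rasterisation rules (any-overlap, area-weighted);
it is exact in the limit of fine grids and makes every operation
checkable against a per-cell oracle.

Missing data is NaN and is never conflated with 0: any missing input at a
cell makes every derived value at that cell missing, so absent data can
never count as either suitable or unsuitable. Rasters are persisted as
ESRI ASCII grids written with 17 significant digits, so write/read
round-trips are bit-exact.

## SED site suitability

Each criterion is a {0, 1, missing} layer:

| criterion | rule | default |
|---|---|---|
| slope | keep cells ≤ `slope_max_deg` (strictly exceeding values excluded) | 5° |
| land cover | exclusion list; everything not excluded is suitable | urban/built-up, wetland, open water, forest, snow/ice |
| substation proximity | Euclidean distance from cell center to nearest substation ≤ `buffer_radius_m` | 8 046.72 m (5 statute miles) |
| protection | cell center outside every protected polygon | — |

The layers are summed; SESA is the cells whose sum equals
`required_sum` (default 4 — strict AND, no weighting). The SED map is
SESA ∩ the top `ghi_top_fraction` (default 0.30) of GHI values. The GHI
quantile is computed over all non-missing cells of the study extent by
default; a switch (`ghi_quantile_within_sesa`) restricts it to SESA cells
instead, since either reading of "mask, then rank" is defensible.
Because the land-cover rule is exclusion-based, classes absent from the
exclusion list count as suitable; the kept classes are logged loudly.

The quantile is the linear-interpolation empirical quantile, with all
ties at the cut retained. With the cut interpolated between order
statistics the retained fraction can undershoot the target by less than
one cell at small n; this is inherent to the interpolated definition and
documented rather than patched.

Distances are planar Euclidean. Synthetic scenes are planar by
construction; the distance operation is a narrow contract behind which a
geodesic backend could be swapped for real geographic data.

## Maxent SDM

The model is the Gibbs distribution over the landscape,
q(x) = exp(λ·f(x)) / Z, with Z normalised over the background sample.
Fitting minimises

F(λ) = −(1/m) Σ_presence λ·f + log Σ_background exp(λ·f) + Σ_j β_j |λ_j|,

a convex objective, with per-feature penalty
β_j = reg_scale · sd_j(f over background) / √m. Optimality is the L1
(KKT) box condition: |empirical presence mean of f_j − model expectation
of f_j| ≤ β_j for every feature.

**Features.** Linear and quadratic terms act on covariates standardised
by the background mean/sd; hinge features act on the raw scale,
max(0, (x − k)/(max − k)) plus the reflected form, with knots at
background quantiles (10 per variable by default; product features are
available but off by default). Zero-variance covariates are dropped with
a warning. Defaults (`linear+quadratic+hinge`, reg_scale 1.0, cloglog
output) follow widely used Maxent practice while keeping the fit convex
and testable against closed forms as reg → 0.

**Optimiser.** FISTA proximal gradient with monotone backtracking on the
smooth part and gradient-based adaptive restart, run to KKT residual
1e−6 (max 20 000 iterations; non-convergence raises, reporting the final
residual). Non-convergence is reachable with genuinely degenerate inputs
— e.g. a presence feature mean outside the background feature hull, for
which no finite optimum exists — and is reported rather than masked.

**Output.** Suitability is the cloglog transform 1 − exp(−e^H q(x)) with
H the entropy of the fitted background density; with zero features this
reduces to the constant 1 − 1/e. The transform is strictly monotone in q,
so rank-based quantities (AUC, Spearman recovery) are identical on either
scale.

**Data handling.** Cleaning drops non-finite, out-of-extent and
duplicate records, then keeps one uniformly random point per occupied
cell (seeded). Background points are cell centers sampled uniformly with
replacement from covariate-complete cells — pure background, not
pseudo-absences, so presence cells may be re-drawn; this matches standard
Maxent usage. The train/test split reserves round(n · 0.2) points
(round-half-away-from-zero, minimum one on each side).

**Variable selection.** A full model is fitted; variables are ranked by
permutation importance (mean training-AUC drop over seeded permutations,
floored at 0, normalised to percentages; ties broken alphabetically) and
scanned in rank order, dropping any variable whose Spearman |ρ| with an
already-retained variable exceeds 0.7, ρ computed on the background
covariate sample (a documented alternative would use the full raster).
The model is refitted on the retained set.

**Evaluation.** AUC is the Mann–Whitney estimator (ties 0.5), which
equals the trapezoidal ROC area exactly. The binarisation threshold
maximises sensitivity + specificity over the observed score values, with
sensitivity = fraction of presences ≥ t and specificity = fraction of
background < t; objective ties break toward the smallest t (the most
inclusive presence map). TSS = sensitivity + specificity − 1. The binary
presence map is clipped to the species range polygons: cells outside the
range are missing, so overlap denominators never count out-of-range
cells.

## Overlap

overlap % = 100 · #(presence = 1 ∧ SED = 1) / #(presence = 1). Cells
where presence = 1 but SED is missing stay in the denominator and out of
the numerator (conservative: unknown SED status never inflates the
conflict estimate). Critical areas are the cellwise intersection;
the SED-opportunity map keeps SED cells where every priority-habitat mask
is 0 or missing. Resident and breeding ranges are carried as separate
masks and reported as separate rows.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes,
not any real geography:

- **Covariates**: i.i.d. Gaussian fields smoothed by a Gaussian kernel
  (`smoothing_length`, default 5 cells), empirically whitened and then
  coloured by the Cholesky factor of the target correlation matrix, so
  the sample correlations equal the target exactly; standardised to mean
  0, sd 1.
- **GHI**: a smooth surface at 5.75 ± 0.5 kWh/m²/day, the realistic
  range for arid-region horizontal irradiance.
- **Slope**: a scaled half-normal of a smoothed field (sd 4°), so both
  sides of the 5° rule occur (~20% of cells exceed it).
- **Land cover**: a smoothed field sliced at quantiles matching the
  class proportions (defaults dominated by shrubland/grassland with
  minority excluded classes, as in arid-region mosaics).
- **Structures**: uniform random substations (15) and facilities (25);
  protected areas as non-overlapping random rectangles covering ~10% of
  the extent; one rectangular species range covering a random 40–80%.
- **Virtual species**: true suitability = logistic(β·[z, z²]). The
  default β give every covariate a unimodal niche response with mean
  suitability ≈ 0.10 — suitable habitat rare, as for arid-land habitat
  specialists — which makes the signal strong enough to be recoverable
  (the true model itself separates presences from background at
  AUC ≈ 0.86). The logistic family is deliberately different from the
  Gibbs estimator, so recovery tests are not circular; recovery is judged
  by rank correlation, which ignores the monotone transform between the
  two. 500 occurrence cells are drawn without replacement with
  probability proportional to suitability inside the range, jittered
  uniformly within their cells, and 10% of points are duplicated exactly
  so the cleaning stage is exercised.

Scene generation is a pure function of the configuration (seed
included). What passing tests on these scenes do **not** show: robustness
to sampling bias, positional error, non-stationary covariates, irregular
range boundaries, or geodesic geometry — all properties of real data the
generator does not emulate.

## Reproducibility

All randomness derives from one master seed: each stage uses
SHA-256("<master>:<stage>") mod 2³¹. Outputs are hashed into the run
manifest; the same configuration reproduces every file byte for byte.

Recovery of the true suitability is measured inside the species range —
the region the occurrences inform and the region to which all suitability
maps are clipped; extrapolation outside the range is not scored.

## Problem sizes

The default study conditions are a 100×100 grid (1 km cells), 500
presences, 10 000 background points, 4 covariates. The test suite runs
the full pipeline at this size and exercises unit properties on grids up
to 50×50 with brute-force oracles; the acceptance script reports the
default-size pipeline plus a 5-replicate recovery estimate.

## Known limitations

- Single shared CRS; no reprojection or geodesic buffering.
- Facilities are points; real facility footprints (polygons) are not
  modelled, and synthetic facilities are placed uniformly rather than
  preferentially in suitable areas, so the facility-inclusion percentage
  on synthetic scenes is near the SED base rate by construction.
- One virtual species per scene; multi-species suites are supported by
  the overlap reporting but not by the generator.
- The permutation-importance ranking is Monte-Carlo (seeded); with few
  replicates the ordering of near-tied variables can depend on the seed.
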