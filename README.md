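# solarconflict

Tools for quantifying the conflict between utility-scale solar energy
development (SED) and the habitat of species of conservation concern, on
fully synthetic landscapes.

Arid regions attractive for photovoltaic development — high irradiance,
flat open terrain — are often also home to habitat-specialist species.
`solarconflict` implements the combined analysis used to map that tension:

1. **Site suitability for SED.** Four binary criteria — slope ≤ 5°,
   suitable land cover (an exclusion list of urban, wetland, open-water,
   forest and snow/ice classes), location within a 5-mile (8 046.72 m)
   buffer of a substation, and location outside protected areas — are each
   reclassified to {0, 1} and summed; cells with sum 4 form the SESA map
   ("sites suitable for solar energy"). Intersecting SESA with the top 30%
   of the global-horizontal-irradiance (GHI) distribution gives the SED
   map. Existing PV facility points are scored against it as a
   plausibility check.
2. **Species distribution model (SDM).** A presence-background
   maximum-entropy model: occurrences are cleaned and thinned to one per
   grid cell, 10 000 background points are drawn, and the Gibbs density
   q(x) ∝ exp(λ·f(x)) over the landscape is fitted by minimising the
   L1-penalised convex objective

   F(λ) = −mean_presence(λ·f) + log Σ_background exp(λ·f) + Σ_j β_j |λ_j|,

   with β_j = reg_scale · sd_j / √m. Features are linear, quadratic and
   hinge expansions of the covariates; collinear covariates are pruned by
   a contribution-ordered Spearman filter (|ρ| ≤ 0.7). Suitability is
   reported through the cloglog transform 1 − exp(−e^H q(x)), evaluated on
   a 20% hold-out by AUC and the True Skill Statistic
   (TSS = sensitivity + specificity − 1) at the
   max(sensitivity + specificity) threshold, then binarised and clipped to
   the species' range polygons.
3. **Overlap.** The headline statistic,
   overlap % = 100 · #(presence ∧ SED) / #(presence), plus the map of
   critical areas (cells in both 1-sets) and the complementary
   SED-opportunity map (SED cells free of priority habitat).

A seeded synthetic-landscape module generates every input — correlated
autocorrelated covariate surfaces, GHI, slope, a land-cover mosaic,
substations, facilities, protected areas, a species range, and a virtual
species with known suitability — so the entire pipeline runs and can be
validated without any downloaded data.

## Worked example

```python
import solarconflict as sc

manifest = sc.run_all(sc.RunConfig(seed=7, out_dir="demo_run"))
rep = manifest["overlap"]["reports"][0]
ev = manifest["sdm_eval"]
print(f"SED-suitable cells : {manifest['sed']['cells_suitable']} "
      f"({manifest['sed']['area_km2']:.0f} km^2)")
print(f"facility inclusion : {manifest['sed']['facility_inclusion_pct']:.1f}%")
print(f"held-out AUC / TSS : {ev['auc']:.3f} / {ev['tss']:.3f}")
print(f"overlap            : {rep['overlap_pct']:.2f}% of {rep['n_presence_cells']} presence cells")
```

prints, for the default 100×100 scene:

```
SED-suitable cells : 364 (364 km^2)
facility inclusion : 8.0%
held-out AUC / TSS : 0.845 / 0.594  (threshold 0.423)
overlap            : 5.49% of 2312 presence cells
```

364 of 10 000 cells satisfy all four siting criteria plus the GHI rule;
8% of the (uniformly placed) synthetic facilities fall on those cells; the
SDM separates held-out presences from background with AUC 0.845; and 5.5%
of the cells predicted as species presence inside the range are also
SED-suitable — the critical areas written to `critical_areas.asc`.

The same pipeline is available from the shell:

```sh
solarconflict run-all --seed 7 --out demo_run -v
```

Every run writes a `manifest.json` with the configuration hash, the
per-stage seeds derived from the master seed, and SHA-256 checksums of all
outputs; re-running the same configuration reproduces every file byte for
byte.

## Layout

- `src/solarconflict/raster_core.py` — grid model, raster/vector
  primitives, plain-text I/O
- `src/solarconflict/sed.py` — siting criteria, SESA/SED maps, facility
  inclusion
- `src/solarconflict/sdm.py` — occurrence handling, Maxent fit,
  evaluation, variable selection
- `src/solarconflict/overlap.py` — overlap statistic, critical areas,
  opportunity map
- `src/solarconflict/synthetic.py` — seeded synthetic landscapes and the
  virtual species
- `src/solarconflict/cli.py` — configuration, pipeline orchestration, CLI

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
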