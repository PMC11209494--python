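# soilsource

Quantitative source apportionment of heavy metals in agricultural soils,
with pollution-pathway identification.

Receptor models answer the question "how much of the contamination measured
at each sampling site came from which emission source?".  `soilsource`
implements a distance-based receptor model for soil surveys around mixed
industrial areas (the motivating setting is paddy fields amid chemical,
metal-manufacturing and non-metal-manufacturing factories), built from four
stages:

1. **Parent material** — the lithogenic share of each element is removed
   with enrichment factors against a crustal reference element C (Mg, Ca or
   Zn):

   EF = ([M]/[C])_soil / ([M]/[C])_crust,
   [M]_excess = [M]_soil − [C]_soil · (bg_M / bg_C)

   so [M]_excess is the anthropogenic excess and EF ≈ 1 marks a purely
   natural origin.

2. **Source identification** — standardized PCA with strict Kaiser
   retention (eigenvalue > 1) and varimax rotation groups elements into
   source factors; a *mixed* factor (more than three elements with
   |loading| > 0.7) is re-decomposed by a grouped PCA (GPCA) on its own
   elements, yielding sub-factors such as `PCA1-1`, `PCA1-2`.  Factor
   scores are matched to factory types through the GeoDetector q-statistic,

   q = 1 − Σ_h N_h σ²_h / (N σ²),

   the share of a response's spatial variance explained by a categorical
   stratification (here: 200-m bins of the distance to the nearest factory
   of each type).

3. **Pathway identification** — the interaction detector computes q on the
   overlay of two stratifications; a pair with q(X1∩X2) > q(X1) + q(X2)
   (*nonlinear enhancement*) marks a pollution pathway.  Up to two pathway
   variables per (element, factory type) are kept: road distance → traffic
   emission, river distance → irrigation water, deposition flux →
   atmospheric deposition, altitude → terrain effect.

4. **Quantification** — the anthropogenic excess is regressed, without
   intercept, on products of a pathway covariate and a transformed source
   distance,

   [M]_excess = Σ_n B_n · P_n · T(d_n),   T ∈ {d^a (a<0), log d, identity},

   by forward/backward stepwise selection (enter p ≤ 0.05, remove p ≥ 0.10)
   on a seeded 80/20 site split, gated on held-out R² > 0.5.  Per-source
   percentage contributions (plus the parent-material share) and marginal
   pathway-effect curves come from the fitted terms.  The classical
   distance-only variant (no pathway covariates) is kept as the baseline
   comparator.

Because survey datasets of this kind are typically not public, the package
ships a seeded synthetic-landscape generator (`soilsource.simulate`) whose
defaults emulate the motivating survey — 109 paddy sites, three spatially
clustered factory types with distinct emission profiles, roads, rivers, an
industrially driven deposition field, a crust-consistent parent baseline
and lognormal noise — together with a ground-truth ledger of every additive
contribution, so every stage can be validated against a known answer.

## Worked example

```python
import soilsource as ss

study = ss.simulate(seed=0)                      # synthetic survey + truth
model = ss.SourceApportionment(study.samples, study.layers, study.background)
results = model.fit(seed=0)
print(results.summary())
```

prints (abridged):

```
Factor solution (leaf factors): PCA1, PCA2, PCA3
cumulative explained variance: 86.6%

Regression diagnostics (test R2, modified vs baseline):
  Cd: modified 0.976 | baseline 0.974
  As: modified 0.922 | baseline 0.897
  Pb: modified 0.954 | baseline 0.958

Contributions (% of cumulative input):
         chemical_factory  metal_factory  nonmetal_factory  parent_material
Cd                   60.2           13.8               0.0             26.0
As                   10.5           43.3              14.4             31.8
Pb                   30.0            9.8               5.7             54.4
```

Each contribution row sums to 100%: for this landscape the generator's
ledger attributes Cd as 55.1 / 18.4 / 0.0 / 26.6, so the fitted shares are
within a few percentage points of the truth.  `results.models["Cd"]`
carries the selected regression terms, coefficients and diagnostics;
`ss.pathway_effect_curve(results.models["Cd"], "river")` returns the
predicted excess along the river-distance range and the change per 1000 m.

The same pipeline runs from the shell:

```bash
soilsource simulate --seed 0 --outdir data
# write a config.yaml pointing at data/samples.csv, features.geojson, background.csv
soilsource apportion --config config.yaml --seed 0 --outdir out
```

Inputs are plain formats: a CSV sample table (`site_id, x, y, altitude`,
element columns in mg/kg, optional `AD_<element>` deposition columns), a
GeoJSON FeatureCollection of typed factories/roads/rivers, and a CSV
background table.  Coordinates must be planar meters.

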