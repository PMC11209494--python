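# Methods

This note documents the model implemented by `soilsource`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the limitations we know about.  Every number quoted
here is recomputed by the test suite or by `scripts/acceptance.py`; the
note states no result that those runs do not themselves produce.

## Model overview and assumptions

Soil concentrations are assumed to decompose additively into a
parent-material (lithogenic) part and anthropogenic inputs from typed point
sources (factories), delivered along pathways (traffic emission, irrigation
water, atmospheric deposition, terrain-driven transport) whose influence
decays with the shortest Euclidean distance between the sampling site and
the source or carrier feature.  The stages and their assumptions:

**Enrichment (parent material).**  The crustal reference element (default
Mg; Ca and Zn are accepted, and a two-reference mode averages per-reference
excesses) is assumed free of anthropogenic input and perfectly correlated
with the local parent material, so that

    excess = conc_M − conc_C · (bg_M / bg_C)

removes the lithogenic share exactly when the assumption holds.  Negative
excesses (sites below the crustal expectation) are preserved in the
diagnostics but clipped to zero as regression targets, since cumulative
anthropogenic input cannot be negative.  `natural + excess` reconstructs
the measured concentration to machine precision by construction.

**Factor analysis.**  Correlation-matrix PCA on z-scored concentrations;
strict Kaiser retention (eigenvalue > 1); varimax rotation with Kaiser row
normalization (rotated loadings are exactly `L0 @ R` with `R` orthonormal,
so per-element communalities are invariant); regression factor scores,
standardized per factor — for a component model these are exactly mutually
uncorrelated.  Signs are flipped so each factor's largest-magnitude loading
is positive.  Elements with |loading| > 0.7 (strict) are a factor's major
elements; a factor with more than three major elements is *mixed* and is
re-decomposed by PCA on its own element subset (GPCA).  If the subset
retains fewer than two factors under Kaiser, the decomposition is rejected
and the parent factor kept, with a warning.

**GeoDetector.**  The q-statistic uses population (divide-by-N) variances
so that q = 1 − SSW/SST holds as an exact identity (verified against an
independent one-way ANOVA decomposition on 1000 random cases).  Distances
are discretized into half-open 200-m equal intervals; deposition and
altitude into 10 classes by Fisher–Jenks natural breaks (an exact O(k·n²)
dynamic program over unique values weighted by multiplicity, so tied
observations always share a class; it matches exhaustive enumeration for
small n).  Empty strata are absent; singleton strata contribute zero
variance and are tallied in the diagnostics — no minimum stratum size is
imposed.  Interaction detection classifies the overlay q12 of two
stratifications into the standard taxonomy (nonlinear/bivariate
enhancement, independence, weakening); pathway assignment keeps, per
(element, factory type), up to the two pathway variables whose interaction
with the factory distance is nonlinearly enhancing, ranked by q12.  An
optional noncentral-F significance for q is provided as a diagnostic; no
p-value gate is applied.

**Stepwise distance-pathway regression.**  Candidate regressors are
products (pathway covariate) × (transformed factory distance); distances
enter through the grid {d^a for a ∈ −0.5, −1, −1.5, −2; log(d+1); identity}
with a fixed +1 m offset guarding sites that lie on a feature; deposition
and altitude enter untransformed.  The model has no intercept.  Selection
is forward entry (partial-F p ≤ 0.05) with backward elimination (p ≥ 0.10)
and at most one term per (source, pathway) pair — the collinearity guard
the transform grid requires.  Because same-pair transform variants are
nearly collinear, classical greedy stepwise often locks in a wrong
transform early; the selection loop therefore adds a within-pair
transform-substitution pass and, when progress stalls, a two-pair joint
substitution (all computed from precomputed Gram matrices).  With these,
data generated exactly from in-grid terms are recovered with fit R² = 1 and
the correct term set.  Models are fitted on a seeded uniform 80/20 site
split and flagged as rejected when held-out R² ≤ 0.5; the final selected
model is refit through statsmodels OLS for standard errors.

**Quantification.**  Per site, a source's input is the sum of its fitted
term values clipped at zero; the parent share is the (clipped) natural
part.  Percentages are totals over all sites, normalized to 100 per
element.  Pathway-effect curves hold all other covariates at their sample
medians and report the finite-difference change in predicted excess per
standard increment (1000 m for distances, 0.1 µg/m²/day for deposition,
1 m for altitude).  The distance-only formulation (one transformed distance
per factory type, same stepwise machinery) is retained as the baseline
comparator, and a four-variant ensemble (reference element and background
table choices) can be orchestrated through `SourceApportionment` with
`contribution_ranges` reporting min–max spans.

## The synthetic generator

`SimulationConfig` defaults define the reference study conditions; they
were fixed once against the published survey's descriptive statistics:

| parameter | default | rationale |
| --- | --- | --- |
| domain | 6 × 6 km, 109 sites on a jittered grid | survey size; nearest-feature distances span a handful of 200-m bins |
| site standoff | ≥ 150 m from any feature | paddy fields are set back from roads, rivers and factory footprints |
| factories | 12/10/10 per type, clustered in separated districts (σ = 0.08 L, centers ≥ 0.3 L apart) | factory types occupy different parts of such study areas; separation keeps source signatures identifiable |
| roads / rivers | 3 / 2 polylines crossing the domain | irrigation-farmland road/river density |
| emission profiles | chemical → Cd, Pb (As); metal → Cu, As, Zn (Cd, Pb); non-metal → As, Cr, Ni (Pb) | the emission-profile hypothesis, with small cross-emissions so no element is perfectly single-sourced |
| pathway weights | one dominant pathway per type (0.7/0.3): chemical→traffic, metal→deposition, non-metal→irrigation | sources must be spatially distinguishable for any distance-based receptor model |
| decay | factory distance (d+1)^−1.5; road/river carrier (d+1)^−0.5 | inside the candidate grid, so noiseless recovery is exact |
| deposition | long-range all-factory kernel (1500 m mixing length), 50% industrial share, 30% sampling noise | atmospheric transport smooths plumes; quarterly roof-cylinder sampling is noisy |
| parent field | lognormal multiplier, CV 25%, crust-ratio-consistent across elements | enrichment removes it exactly pre-noise |
| noise | multiplicative lognormal, CV 12% | with the parent CV this reproduces the survey's Mg CV of ≈ 29%, treating survey dispersion as mostly spatial signal |

Emission strengths are calibrated so parent-material shares approximate the
published contribution structure (Cd ≈ 20%, As ≈ 30%, Pb ≈ 50%).  The truth
ledger records every pre-noise addend per site, element, factory type and
pathway; components sum to the noiseless concentration exactly.

What the generator does **not** emulate: atmospheric dispersion physics
(kernels are phenomenological, not Gaussian plumes), soil-type-specific
backgrounds, spatially autocorrelated measurement error, temporal dynamics,
and non-factory sources (agrochemicals, sewage sludge).  Passing recovery
tests therefore show that the pipeline inverts its own generative
assumptions at survey-realistic noise — not that those assumptions hold in
any particular field data set.

## Numerical choices

* Population variances inside q (exact SSW/SST identity); sample (n−1) SD
  and bias-adjusted skewness/excess kurtosis in descriptive tables.
* Jenks classes are intervals of unique values (ties never split); k is
  clamped to the number of distinct values with a warning.
* Candidate columns are scaled to unit RMS inside the selection engine for
  conditioning; coefficients are unscaled afterwards.  Selection SSEs come
  from Gram-matrix least squares (`lstsq`, SVD-backed) so near-singular
  trial sets degrade gracefully; a fit is treated as numerically exact when
  SSE ≤ 1e−12 × Σy².
* IDW interpolation uses power 2 over all sites; a grid node within 1e−12 m
  of a site takes that site's value.
* The split uses `numpy.random.default_rng(seed)`; fit size is
  ⌊0.8 n⌋ (87/22 at n = 109).

## Design decisions where the method was open

* Mixed-factor trigger: more than three major elements (configurable) — the
  smallest rule consistent with decomposing a four-element factor.
* Two-reference enrichment combines per-reference excesses by averaging.
* Stepwise thresholds 0.05/0.10 are the classical defaults.
* The dependent variable for pathway analysis is the clipped anthropogenic
  excess (a switch allows raw concentrations).
* Contribution aggregation clips negative per-site term values at zero;
  contributions are shares of cumulative input.
* Effect curves hold covariates at medians (the averaging convention is not
  dictated by the model).

## Known limitations

* **Interaction-based pathway ranking is fragile at n ≈ 109.**  With 200-m
  equal intervals and 10-class covariates, two-variable overlays on 109
  sites contain many near-singleton cells, so the overlay q is inflated in
  proportion to stratification granularity rather than explanatory
  content — demonstrably so even when the response is the noiseless true
  source component.  Moreover the nonlinear-enhancement gate
  (q12 > q1 + q2) structurally excludes pathway variables that are
  marginally informative: a deposition flux that truly drives a source's
  input appears in the response multiplicatively and therefore carries a
  large marginal q of its own.  In the package's constructed tracer
  scenario (Cd entering only from non-metal factories via river
  irrigation) the river pathway is selected in roughly three quarters of
  seeded replicates — well above the 50% of chance-level top-2 selection,
  but far from certainty.  Treat assigned pathways as hypotheses to be
  checked against the regression fit, not as conclusions.
* Stepwise selection among heavily collinear transform products can
  misattribute contributions between sources whose spatial signatures
  overlap; the held-out R² gate catches poor predictive fits but not
  well-predicting misattributions.  Contribution ranges across model
  variants are a better summary than any single model's point estimate.
* Extrapolation: power-law terms evaluated at distances below the fitted
  range can produce extreme predictions; the gate flags such models, but
  users should inspect sites closer to features than any fitting site.
* No geodesic support: coordinates must be planar meters; project
  geographic data upstream.
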