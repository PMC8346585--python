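# diazosip

A tested, reusable implementation of the quantitative workflow behind
stable-isotope-probing (¹⁵N₂ / ¹³C-DIC) studies of N₂ and CO₂ fixation in a
stratified lake chemocline:

- **depth_align** — reassign upcast bottle depths to the water mass they came
  from by matching percent-normalized conductivity/temperature/pressure
  against the continuous downcast profile (internal-wave correction).
- **bulk_rates** — bulk N₂/CO₂ fixation rates from endpoint isotope
  incorporation, autotrophic N demand from a bulk C:N ratio,
  detection-limit censoring, and the labelled-gas contamination-check
  arithmetic (mole fraction in ppm).
- **flux_budget** — steady-state Fick's-law ammonium flux into the
  chemocline, conversion to a volumetric assimilation rate over the mixed
  layer, and the N-source budget (fixation vs ammonium vs unexplained).
- **single_cell** — nanoSIMS per-plane ROI ion counts → accumulated isotope
  fractions, Poisson counting-error QC (<5% relative ratio error),
  prolate-spheroid biovolume, allometric carbon/nitrogen content, and
  cell-specific fixation rates; running-mean convergence check and a
  rank-based FISH-effect comparison.
- **population_scaling** — FISH field-of-view counts → volumetric abundances
  with standard errors, population rates (abundance × mean single-cell rate)
  with propagated SEs, and percent contributions to the bulk rate.
- **synthetic_data** — seeded generators for every input above with known
  ground truth, so each stage and the full pipeline are testable by
  parameter recovery with no external data.

## CLI

All stages are exposed under one entry point:

```bash
# write a full synthetic scenario (inputs + ground_truth.json)
diazosip simulate --seed 3 --outdir scenario/

# depth-correct upcast stations against the downcast
diazosip depth-align --downcast scenario/downcast.csv \
    --stations scenario/stations.csv \
    --params conductivity,temperature,pressure -o aligned.csv

# bulk rates, N demand, fixation fractions
diazosip bulk-rates --incubations scenario/incubations.csv \
    --cn-ratio 8.6 --lod-multiplier 3 -o bulk.csv

# diffusive flux + N-source budget (config keys: diffusivity_m2_s,
# window_top_m, window_bottom_m, layer_top_m, layer_bottom_m, n_demand, n2_rate)
diazosip flux --profile scenario/nutrients.csv --config flux.yaml -o budget.json

# per-cell enrichments, QC, and rates (config keys: at_excess_15N_medium,
# at_excess_13C_medium, time_d, cn_ratio)
diazosip single-cell --rois scenario/rois.csv --geometry scenario/geometry.csv \
    --config sc.yaml -o cells.csv

# population abundances, rates, and bulk contributions
diazosip populations --fish scenario/fish.csv --cell-rates cells.csv \
    --bulk bulk.csv --depth 13.7 -o populations.csv
```

## Notes

- The canonical areal-flux unit is mmol m⁻² d⁻¹ (numerically equal to
  µmol L⁻¹ d⁻¹ after division by a layer thickness in metres); the flux CLI
  also prints the µmol cm⁻² d⁻¹ rendering.
- Bulk rates use the pool-minus-control denominator; single-cell rates use
  excess enrichment over natural abundance for cell and medium separately.
  The two coincide only when the control sits at natural abundance.
- Detection-limit policy: a rate is censored when its excess enrichment is
  below `lod-multiplier` × SD of the control atom% across replicates; the
  policy is recorded in the output.
- Population-rate standard errors use the exact product variance
  (a²σᵣ² + r²σₐ² + σₐ²σᵣ²), which reduces to the usual quadrature form for
  small CVs.
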