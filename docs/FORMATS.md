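# File formats

All tabular artifacts are plain CSV with a header row, written with
`%.10g` floats. The pipeline writes them into the configured output
directory; `manifest.json` lists every artifact with its SHA-256 hash.

## Inputs / simulated inputs

### regions.csv
One row per agricultural region.

| column | meaning |
|---|---|
| region_id | unique region identifier |
| area | surface in km² |
| agroecosystem | `arable` / `livestock` / `mixed` (or scenario target labels) |
| farmland_prop_current, farmland_prop_future | farmland-habitat proportion of land area, in [0, 1] |
| permanent_grassland … forage_crops | the nine crop shares of utilized agricultural area; sum to 1 |

### species.csv
One row per species: `species_id`, `specialization`
(`farmland`/`generalist`), `migrant_second_visit_only`, the true simulation
coefficients (`alpha`, `beta_climate`, `beta_farmland`, `beta_effort`,
`beta_<crop>` per crop), random-effect SDs (`random_sd_region`,
`random_sd_year`, `random_sd_obs`) and the four sub-habitat abundances
`abund_unimproved_grassland`, `abund_improved_grassland`, `abund_mixed`,
`abund_cropland` used for the specialization index.

### grid.csv
One row per 0.5°-style grid cell: `cell_id`; land-cover class fractions
`pasture_{current,future}`, `cultivated_{current,future}`,
`mosaic_{current,future}`; per-species suitability columns
`suit_{current,future}_<species_id>` in [0, 1].

### overlaps.csv
`cell_id`, `region_id`, `fraction` — the share of the region's area lying
in the cell. Fractions are region-normalized: they must sum to 1 per
region (tolerance 1e-6).

### projections.csv
Per-model suitability layers: `model_id`, `cell_id`, `period`
(`current`/`future`), `value`, `species_id`.

### surveys.csv
Two-visit point counts: `species_id`, `region_id`, `year`, `square_id`,
`point_id`, `visit1_count`, `visit2_count`, `point_is_farmland`.

### scenarios/*.yaml
`name`, `transitions` (agroecosystem → target label) and `constraints`
(per target label: `lower`/`upper` per-crop bounds, `groups` with
`crops` + `min`/`max`, `primary_crop_cap`, `fixed_crops`). A bound is a
number (absolute) or a mapping with `abs`, `rel` (× current), `shift`,
`cap`, `floor`.

## Derived artifacts

### suitability.csv
Consensus climatic suitability downscaled to regions: `species_id`,
`region_id`, `current`, `future`.

### abundance.csv
Prepared regional abundances: `species_id`, `region_id`, `year`,
`abundance` (non-negative integer), `n_points` (farmland points in
retained squares — the effort covariate).

### future_shares_<scenario>.csv
Post-optimization crop shares per region (`region_id`, target
`agroecosystem`, nine crop columns).

### national_shares.csv
Area-weighted national crop shares per scenario: `crop`, `current`,
`future`, `delta`, `scenario`.

### fits/<species_id>.json
Per-species model fit: original-scale `params` and `se` (keyed `alpha` +
covariate names), variance components, `loglik`, `converged`,
`r2_marginal`, `r2_conditional`, `overdispersion`.

### species_guilds.csv
`species_id`, `guild` (`grassland`/`cropland`/`mixed`/`generalist`),
`specialization`.

### changes.csv
Per-cell symmetric changes: `species_id`, `scenario`, `combo`,
`region_id`, `change` (in [-2, 2]), `weight` (area / n_points).

### summary.csv
Weighted group summaries: `scenario`, `combo`, `group` (`all`,
`farmland`, `generalist`, `grassland`, `cropland`, `mixed`), `n`, `mean`,
`sd` (Cochran), `t`, `p`.

### pairwise.csv
Tukey HSD contrasts on the full driver combination: `scenario`,
`grouping` (`specialization` or `guild`), `group1`, `group2`, `diff`,
`lower`, `upper`, `p_adj`.

### manifest.json
`version`, `seed`, the full config echo, and `artifacts` (relative path →
SHA-256).
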