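# farmbird

Scenario forecasting of breeding-bird abundance in agricultural landscapes.

Farmland birds respond to three interacting drivers that are usually
projected separately: climate (shifting climatic suitability), land use (the
area of farmland habitat) and farmland cover (the crop/grassland composition
of the farmed area). `farmbird` links the three in one pipeline: it
calibrates a regional abundance model on point-count survey data, projects
abundance under combinations of future drivers — including policy-style
farmland-cover scenarios built by constrained optimization — and summarizes
the responses by habitat guild. It is aimed at quantitative ecologists and
agricultural-policy modellers who want a tested, reproducible harness for
this class of analysis; a synthetic-landscape module generates survey,
climate-suitability and land-cover inputs with the exact statistical
structure the analysis assumes, so every stage runs and is tested without
any data download.

## The model

Abundance N of a species in region *i* and year *j* follows a Poisson
log-normal mixed model (a Poisson GLMM with an observation-level random
effect, OLRE):

    N_ij ~ Poisson(lambda_ij)
    log lambda_ij = alpha + beta_1 C_i + beta_2 F_i + beta_3 P_ij
                    + sum_k beta_k X_ik + u_i + v_j + eps_ij

    u_i ~ N(0, sigma_region^2),  v_j ~ N(0, sigma_year^2),
    eps_ij ~ N(0, sigma_obs^2)

with C climatic suitability (in [0, 1], from a rank-weighted ensemble of
distribution-model projections), F the farmland-habitat proportion, P survey
effort (number of farmland count points) and X_k the nine crop shares of the
utilized agricultural area. The model is fitted by maximizing the
Laplace-approximated marginal likelihood. Projected abundance change is the
symmetric ratio

    (RA_future - RA_current) / ((RA_current + RA_future) / 2)  in [-2, 2],

computed per region with subsets of drivers toggled to future values, and
aggregated with weights area / n_points. Guild membership uses the
grassland specialization index SSIg (abundance-weighted mean of sub-habitat
coefficients 4, 3, 2, 1; > 2.2 grassland, < 1.8 cropland, else mixed).
Future crop compositions come from six built-in farmland-cover scenarios:
each relabels agroecosystems and imposes per-crop constraints, and the new
composition is the L1-closest feasible point of the 9-crop simplex (an LP).

## Worked example

```python
>>> import numpy as np, farmbird as fb
>>> np.round(fb.ensemble_weights(7, decay=1.6), 2)
array([0.39, 0.24, 0.15, 0.1 , 0.06, 0.04, 0.02])
```

The ranked weights given to seven distribution models under geometric decay
1.6 — the best model contributes 39% of the consensus, the worst 2%.

```python
>>> fb.compute_ssig([0.1, 0.2, 0.3, 0.4])
2.0
>>> fb.classify_main_habitat(2.0)
'mixed'
```

A species with 10% of its abundance in unimproved grassland, 20% in improved
grassland, 30% in mixed grass/crop and 40% in cropland scores SSIg 2.0 and
is classified as a mixed-habitat farmland species.

Run the demo pipeline (50 regions, 6 species, 5 years, all 6 scenarios):

```bash
farmbird run-all --out-dir demo --seed 1
```

`demo/summary.csv` then holds the guild summaries; for the full driver
combination (climate + land use + farmland cover) over all species:

```
                 scenario   mean    sd      t     p
           global_biofuel -0.170 0.386 -3.381 0.001
   global_extensification -0.187 0.354 -4.061 0.000
livestock_extensification -0.195 0.357 -4.211 0.000
         regional_biofuel -0.153 0.395 -2.969 0.004
 regional_extensification -0.193 0.364 -4.085 0.000
               status_quo -0.198 0.353 -4.323 0.000
```

Each `mean` is the area/effort-weighted mean symmetric abundance change
across regions and species (negative = projected decline), `sd` its Cochran
ratio-estimator spread, and `t`/`p` a weighted one-sample test against zero
change. The per-driver decomposition for one scenario shows how the drivers
stack — here the climate signal dominates the projected decline while the
cover change alone is mildly positive:

```
              combo   mean    sd
        all_drivers -0.198 0.353
       climate_only -0.131 0.120
farmland_cover_only  0.015 0.053
      land_use_only -0.087 0.326
land_use_plus_cover -0.072 0.333
```

(These numbers describe the synthetic demo landscape, not any real survey.)
`demo/pairwise.csv` holds Tukey HSD contrasts between guilds, and
`demo/manifest.json` the SHA-256 hashes of every artifact — identical
config and seed reproduce identical bytes.

CSV schemas are documented in [docs/FORMATS.md](docs/FORMATS.md); the
modelling choices and their rationale in
[docs/methods.md](docs/methods.md).

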