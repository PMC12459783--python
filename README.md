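# carst

Bayesian spatio-temporal disease mapping for areal count panels.

`carst` implements the full analysis pipeline used in small-area studies
of rare-event counts — originally motivated by district-year homicide
panels, but applicable to any area-by-year counts with populations at
risk: exploratory spatial statistics, a hierarchical negative-binomial
space-time model with structured random effects, model comparison,
risk surfaces, and one-year-ahead prediction. It is aimed at
epidemiologists, criminologists and spatial statisticians who want a
scriptable, fully reproducible alternative to GUI- or INLA-centred
workflows.

## The model

Counts `Y_it` for area `i` in year `t` with expected counts `E_it`
(indirect standardization) follow an NB1 negative binomial,

    Y_it | θ_it, r ~ NegBin(mean = μ_it, variance = r μ_it),   μ_it = E_it θ_it
    log θ_it = α + U_i + V_i + γ_t + φ_t + δ_it

with

- `U_i` iid normal (unstructured area heterogeneity),
- `V_i` intrinsic CAR on the contiguity graph (BYM convolution with `U`),
- `γ_t` second-order random walk (smooth trend), `φ_t` iid year effects,
- `δ_it` one of the four Knorr-Held space-time interaction types
  (I: iid⊗iid, II: iid⊗RW2, III: ICAR⊗iid, IV: ICAR⊗RW2),
- Gamma(1, 0.001) hyperpriors on every random-effect precision,
  a wide normal intercept prior, and log(r−1) ~ N(0, 10²).

Inference is by blocked Metropolis-within-Gibbs MCMC with
IWLS Gaussian-approximation proposals; sum-to-zero/detrending
constraints on the intrinsic blocks hold exactly by construction (each
block is parameterized on the row space of its structure matrix). Model
fit is compared across interaction types by DIC and WAIC; per-cell
exceedance probabilities `P(δ_it > 0)` flag areas whose temporal
behavior departs from the national trend. Moran's I and local Moran
(LISA) with permutation inference cover the exploratory stage.

## Worked example

```python
import numpy as np
from carst import (ModelSpec, annual_summary, build_model, build_weights,
                   crude_rates, expected_counts, fit_mcmc, grid_graph,
                   moran_permutation_test, posterior_summary)
from carst.model_eval import compare_models, variance_fractions
from carst.synthetic_data import elsalvador_like_fixture

sp = elsalvador_like_fixture(seed=0)          # 262 areas x 20 years
panel = sp.panel

print(annual_summary(panel).head(3).round(2))
#       overall_rate  median    sd   iqr  min    max  pct_zero
# year
# 2002          6.68    3.64  6.88  7.07  0.0  56.98     20.99
# 2003          6.82    3.97  5.31  6.11  0.0  28.00     17.56
# 2004          6.39    4.61  5.04  5.56  0.0  29.98     17.18

g = grid_graph(16, 17, queen=True,
               drop=(0, 16, 33, 67, 100, 152, 203, 238, 255, 271))
w = build_weights(g)
res = moran_permutation_test(crude_rates(panel).mean(axis=1), w,
                             n_perm=999, seed=1)
print(f"Moran I = {res.statistic:.4f}, pseudo-p = {res.pseudo_p:.3f}")
# Moran I = 0.0983, pseudo-p = 0.002
```

The positive Moran statistic with a small pseudo-p indicates spatial
clustering of the period-average rates — expected, since the generator
plants spatially structured risk. Fitting the model on a scaled-down
panel and comparing interaction types (see `scripts/acceptance.py` for
the full recipe) ranks the generating Type IV specification best by DIC
in most replicates and attributes the dominant variance share to the
space-time interaction.

## Command line

```bash
carst simulate --rows 6 --cols 6 --years 8 --out sim/
carst rates    --panel sim/panel.csv --out out/
carst moran    --panel sim/panel.csv --adjacency sim/adjacency.txt --out out/
carst lisa     --panel sim/panel.csv --adjacency sim/adjacency.txt --out out/
carst fit      --panel sim/panel.csv --adjacency sim/adjacency.txt \
               --interaction IV --out fit/
carst compare  --panel sim/panel.csv --adjacency sim/adjacency.txt --out cmp/
carst predict  --draws fit/draws.npz --e-new e2022.csv --out pred/
```

Every stage writes a JSON manifest with the seed, config and input
hashes alongside its outputs.

## Using the published data

The original data behind the motivating analysis (homicide counts and
official population projections for El Salvador's 262 districts,
2002–2021, plus the municipal map) are not redistributed here. To run
the data-dependent acceptance tests, convert them to the package's
dialect and place them under `data/elsalvador/`:

- `homicide_panel.csv` — long format with columns
  `area_id, year, count, population` (merge the counts file with the
  population projections; one row per district-year);
- `adjacency.gal` or `districts.geojson` — district contiguity, either
  as a GAL file or as polygons (convert the shapefile with e.g.
  `ogr2ogr -f GeoJSON districts.geojson map.shp`).

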