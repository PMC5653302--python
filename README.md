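# soilrich

Nationwide mapping and predictive modelling of soil bacterial richness.

`soilrich` is a Python toolkit for the analysis chain used in national
soil-monitoring surveys of microbial diversity: it turns per-sample 16S
rRNA reads into OTU richness, maps richness geostatistically with formal
model validation, attributes its ecological drivers by variance
partitioning over environmental and spatial predictor groups, and fits a
polynomial model that predicts richness from a handful of routine soil
measurements. It is written for soil ecologists and biogeographers
working with gridded survey designs (sites every ~16 km over a
~550,000 km² territory), and ships a synthetic survey generator that
reproduces such a design with known ground truth, so the entire pipeline
runs and is tested without any external data.

## The statistics at the core

* **OTU richness** — abundance-greedy clustering at 95% similarity
  (homopolymer-insensitive identity), single-singleton filtering, and
  rarefaction to a common depth; richness S = number of OTUs per sample.
* **Geostatistics** — method-of-moments semivariogram γ̂(h), Matérn-family
  model fits (WLS or profiled maximum likelihood), ordinary kriging, and
  leave-one-out validation via standardized squared prediction errors
  θᵢ = (zᵢ − ẑ₋ᵢ)²/σ²₋ᵢ, which are ~χ²₁ (mean 1, median 0.455) under a
  valid model. The bundled reference map model is a Matérn with
  effective range 111.6 km and nugget ratio c₀/(c₀+c₁) = 0.73.
* **Spatial eigenvectors** — PCNM descriptors from the truncated distance
  matrix, selected by permutation-tested Moran's I and classified into
  coarse/medium/fine scales by their Gaussian-variogram range.
* **Variance partitioning** — Ezekiel-adjusted R² decomposed into unique
  and shared fractions across soil, land-use, climate, geomorphology and
  space groups by inclusion–exclusion, with Freedman–Lane permutation
  tests of marginal effects.
* **Predictive model** — collinearity screening (|r| ≤ 0.7, VIF ≤ 4),
  Kennard–Stone 90/10 calibration split, exhaustive best-subset search
  (BIC / adjusted R²), polynomial OLS with Shapiro–Wilk and Breusch–Pagan
  diagnostics, and sensitivity via standardized regression coefficients
  SRC = (σ_X/σ_Y)·β̂.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import pandas as pd
from soilrich import (generate_survey, simulate_richness, FieldParams,
                      empirical_variogram, fit_variogram, loo_validate,
                      build_pcnm, variance_partition, fit_polynomial)
from soilrich.varpart import standardize
from soilrich.polymodel import REFERENCE_RICHNESS_MODEL_TERMS

# a 600-site survey on the jittered 16-km grid, richness from the
# built-in polynomial + Matérn field + noise model
sites = generate_survey(n_sites=600, seed=7)
truth = simulate_richness(sites, field=FieldParams(seed=7))
sites = sites.assign(richness=truth.richness)

coords = sites[["x_km", "y_km"]].to_numpy()
z = sites["richness"].to_numpy()
model, _ = fit_variogram(empirical_variogram(coords, z, cutoff=250, n_bins=25),
                         families=("matern",))
val = loo_validate(coords, z, model, n_sim=500, seed=8)

basis = build_pcnm(coords, n_perm=199, seed=7)
groups = {"soil": standardize(sites[["pH", "clay", "CN_ratio", "C_org"]]),
          "landuse": pd.get_dummies(sites["land_use"], drop_first=True).astype(float),
          "space": basis.selected_vectors()}
y = (z - z.mean()) / z.std(ddof=1)
part = variance_partition(y, groups, n_perm=199, seed=7)

m = fit_polynomial(sites, z, list(REFERENCE_RICHNESS_MODEL_TERMS[1:]))

print("richness: mean %.0f, sd %.0f, range %.0f-%.0f"
      % (sites.richness.mean(), sites.richness.std(ddof=1),
         sites.richness.min(), sites.richness.max()))
print("fitted Matern: effective range %.1f km, nugget ratio %.2f"
      % (model.effective_range, model.nugget_ratio))
print("LOO SSPE mean %.3f (95%% envelope %.3f-%.3f), median %.3f"
      % (val.mean, *val.envelope_mean, val.median))
print("variance partition: total %.3f | unique soil %.3f, land use %.3f, space %.3f"
      % (part.total, part.unique["soil"], part.unique["landuse"], part.unique["space"]))
print("polynomial model: R2 %.2f, R2adj %.2f; top sensitivity: %s (SRC %.2f)"
      % (m.r2, m.r2adj, m.src.iloc[0]["term"], m.src.iloc[0]["src"]))
```

This prints:

```
richness: mean 1269, sd 200, range 534-1915
fitted Matern: effective range 58.8 km, nugget ratio 0.81
LOO SSPE mean 1.000 (95% envelope 0.874-1.128), median 0.476
variance partition: total 0.451 | unique soil 0.393, land use -0.002, space 0.000
polynomial model: R2 0.51, R2adj 0.50; top sensitivity: pH^4 (SRC 0.65)
```

Reading it: the synthetic survey reproduces realistic richness (mean
~1,270 OTUs, sd ~200). The fitted variogram at 600 sites is noisy (the
spatial structure is estimated much more precisely at the full 1,798-site
design — see below), but the SSPE mean of 1.000 sits in the middle of its
own 95% simulation envelope, confirming the fitted model is a valid
description of the field's spatial variation. Soil chemistry dominates
the variance partition, land use and space contribute marginally (small
negative fractions are an adjusted-R² artifact and are reported as-is),
and the polynomial model explains half the variance with pH⁴ as its most
sensitive term — the qualitative structure the generator builds in.

The same chain is available from the shell:

```bash
soilrich synth survey --n-sites 600 --seed 7 --out sites.csv
soilrich geo fit sites.csv --out model.json
soilrich geo validate sites.csv model.json
soilrich pipeline all --seed 7 --outdir run/
```

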