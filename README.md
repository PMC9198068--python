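# pdindex

**pdindex** builds a *physical distancing index* (PDI): a household-level
composite measure of missing essential private infrastructure — the kind of
deprivation that makes it impossible to keep physical distance during an
epidemic because water, sanitation, space, transport and communication all
have to be shared or fetched outside the home.  It targets analysts working
with DHS-style clustered household surveys who need comparable country and
subnational (admin-1) risk indices and high-resolution risk surfaces.

## The index

Five deprivation-oriented indicators are derived per household *i*:

1. `share_toilet` — number of other households sharing the toilet (0 = private),
2. `public_water` — 1 if the only water access is a public/open source,
3. `persons_per_room` — members per sleeping room,
4. `no_ict` — 1 if no mobile phone,
5. `no_vehicle` — 1 if no bicycle, motorbike or car.

Each indicator is z-scored and the household score is the projection onto
the first principal component of the indicator correlation matrix **R**:

```
s_i = Σ_j  v_j (x_ij − μ_j) / σ_j ,        R v = λ₁ v,   ‖v‖ = 1,  Σ_j v_j > 0
```

so a higher score always means more deprivation.  Scores are aggregated to
admin units with weights `w_i = sample_weight_i · ln(1 + density_i)`, where
density (people/km²) is looked up from a raster at the household's cluster
coordinates — dense, deprived places are where distancing fails hardest.
Unit aggregates are min-max normalized to [0, 1]: **PDI = 1 marks the unit
with the least access to private infrastructure**.  A penalized
tensor-product B-spline (P-spline) smoother turns cluster means into
pixel-level surfaces with closed-form posterior standard deviations, and a
validation module correlates regional PDI with cumulative epidemic
caseloads and checks leave-one-indicator-out robustness.

Real survey microdata of this kind is access-restricted, so the package
ships a first-class synthetic generator: a spatially correlated latent
deprivation factor drives all five indicators, with DHS-style cluster GPS
displacement, sample weights, a density raster and caseloads linked to
latent risk.  Default marginals are calibrated to continental survey
averages (45% shared toilets, 40% public water, 3.2 persons per room).

## Worked example

```python
from pdindex import SyntheticConfig, run_study

result = run_study(SyntheticConfig(seed=1, caseload_effect=1.5))

model = result.model
for name, w in zip(model.feature_names, model.loadings):
    print(f"  {name:<17s} {w:+.3f}")
print(f"explained variance share: {model.explained_variance_share:.3f}")
```

prints

```
  share_toilet      +0.440
  public_water      +0.468
  persons_per_room  +0.410
  no_ict            +0.455
  no_vehicle        +0.461
explained variance share: 0.604
```

All five loadings are positive and similar — the indicators share one
deprivation dimension, and the first component captures 60% of their
variance.  The regional table and validation report:

```python
agg = result.aggregates.sort_values("pdi_normalized", ascending=False)
print(agg[["region_id", "pdi_raw", "pdi_density_weighted", "pdi_normalized"]]
      .head(3).to_string(index=False, float_format="%.3f"))
rep = result.report
print(f"Spearman(PDI, latent truth): {rep.truth_spearman:.3f}")
print(f"Spearman(PDI, caseload):     {rep.spearman:.3f}")
```

```
region_id  pdi_raw  pdi_density_weighted  pdi_normalized
     R025    1.720                 1.711           1.000
     R009    1.447                 1.464           0.926
     R018    1.116                 0.902           0.757
Spearman(PDI, latent truth): 0.962
Spearman(PDI, caseload):     0.839
```

Region R025 is the most deprived unit (PDI 1.0); the normalized index
ranks regions almost exactly like the unobserved latent deprivation
(ρ = 0.96) and correlates strongly (ρ = 0.84) with simulated regional
caseloads.

The same stages are available from the shell: `pdindex simulate`,
`pdindex index`, `pdindex aggregate`, `pdindex surface`, `pdindex validate`
and `pdindex run --config pipeline.yaml` for the whole file-based pipeline
(model JSON, scores, aggregates, normalized index, surface grids,
validation report, manifest).

## Layout

```
src/pdindex/
  synthetic.py    # survey-world generator (latent field, households, raster, caseloads)
  indicators.py   # raw records -> five deprivation indicators
  pca.py          # index model: standardization + oriented first component
  aggregation.py  # weighted aggregation, density weighting, normalization
  geosurface.py   # penalized tensor-product spline surfaces
  validation.py   # caseload correlation, leave-one-out, truth recovery
  raster.py       # density grid container + ESRI ASCII I/O
  io.py           # CSV/GeoJSON readers and writers
  pipeline.py     # in-memory and file-based drivers
  cli.py          # click CLI
docs/methods.md   # model, assumptions, defaults, limitations
```
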