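# soccf — process-based land-use characterization factors for SOC depletion

`soccf` computes **characterization factors (CFs) for soil organic carbon
(SOC) depletion** caused by land occupation and land transformation, for use
in life cycle impact assessment (LCIA). It is aimed at LCIA method
developers and LCA practitioners who want process-based, regionalized,
management-resolved land-use CFs with quantified uncertainty, rather than
proxy/statistical factors.

## The model

SOC turnover is simulated with a five-pool first-order monthly model
(decomposable and resistant plant material, microbial biomass, humified
organic matter, plus an inert pool). Each active pool decays as

    P(t+1 month) = P · exp(−k_P · a·b·c / 12)

where *a*, *b*, *c* are temperature, moisture (topsoil moisture deficit) and
soil-cover rate modifiers; decayed carbon splits into CO₂ and
microbial/humified carbon with a clay-dependent ratio. Potential
evapotranspiration comes from the Thornthwaite equation; the inert pool from
a power-law pedotransfer on the initial stock.

Because the monthly update is affine in the pool vector, the **attainable
SOC** (ASOC) of a land-use class — the equilibrium stock under constant
climate, soil and management — is the fixed point of the composed annual
map, and every transition trajectory has a closed form. For each region the
**potential natural vegetation** (PNV) is the feasible forest/grassland
class with maximum ASOC, and

* occupation CF (t C/ha):  `CF_occ = ASOC_PNV − ASOC_LU2`
* transformation CF (t C·yr/ha):  `CF_tr = Impact_LU2 − Impact_LU1`, where
  `Impact_LU = ∫₀^∞ (ASOC_PNV − SOC_LU→PNV(t)) dt` is the accumulated
  regeneration deficit of the curve from LU back to PNV (simulated monthly
  window plus a fitted exponential tail integrated analytically).

Positive CFs are SOC depletion; `CF(A→B) = −CF(B→A)` holds exactly.
Transitions into forest run through a growth period with ramped carbon
inputs. "Background" transformation CFs (initial land use unknown) replace
`Impact_LU1` with the land-use-share-weighted mean of category impacts.
Input uncertainty is propagated by Monte Carlo: each run perturbs climate,
clay, initial SOC and plant C inputs with truncated normal draws shared by
all factors in the run; CFs are reported as means with sample standard
deviations. Region CFs aggregate to country level area-weighted and map
onto the standard land-use elementary-flow hierarchy (81 foreground classes:
63 cropland from crop × water regime × residue fate, 16 forest, 1 grassland,
1 urban).

## Worked example

```python
from soccf import SOCDepletionModel
from soccf.synthetic import WorldSpec

model = SOCDepletionModel.from_world_spec(
    WorldSpec(n_regions=6, n_countries=2, seed=5))
res = model.fit(n_runs=50, seed=7)
print(res.summary())
```

```
SOC depletion characterization
==============================================
regions:              6
land-use classes:     12
Monte Carlo runs:     50

table                            n        mean    sd(mean)
----------------------------------------------------------
occupation (t C/ha)             50      10.285      41.333
transformation (t C.yr/ha)     186    2091.498   15442.446
background transf.              50     768.400   10811.671
```

Per-region occupation CFs (one synthetic region shown):

```python
occ = res.foreground_occupation()
print(occ[occ.region_id == "R0002"])
```

```
region_id  flow_kind                                            lu2      mean     stdev  units
    R0002 occupation                        crop_grape_irrigated_na 14.510725  3.107940 t C/ha
    R0002 occupation                          crop_olive_rainfed_na 20.178589  4.327695 t C/ha
    R0002 occupation                       crop_rice_irrigated_left  0.355238  1.661195 t C/ha
    R0002 occupation                     crop_wheat_rainfed_removed 31.553330  7.002057 t C/ha
    R0002 occupation forest_needleleaf_evergreen_warm_temperate_dry  0.000000  0.000000 t C/ha
    R0002 occupation                                      grassland  3.955093  1.502604 t C/ha
    R0002 occupation                                          urban 44.954709 10.003595 t C/ha
```

Reading this: occupying this region as urban land forgoes ~45 t C/ha
relative to its natural vegetation (the needleleaf forest, whose own CF is
exactly zero); wheat with residues removed forgoes ~32 t C/ha; irrigated
rice is nearly carbon-neutral here. Negative values (e.g. irrigated maize
with residues left, in other regions) are SOC *gains*. Country aggregation,
the elementary-flow table, GeoTIFF maps and a zipped JSON impact-method
bundle come from the same results object:

```python
res.by_country()            # area-weighted country CFs
res.flow_table()            # CFs per land-use elementary flow
res.export_rasters("maps")  # one (mean, stdev) GeoTIFF per class
res.export_impact_method("soc_method.zip")
```

A CLI mirrors the pipeline for shell use:

```sh
soccf synth --n-regions 25 --seed 3 --out world
soccf cf-foreground --config demo.yml --seed 7 --out cf
soccf export --config demo.yml --seed 7 --out export
```

where `demo.yml` holds the world and perturbation settings, e.g.

```yaml
world:
  n_regions: 25
  n_countries: 5
  seed: 3
perturbation:
  n_runs: 100
```

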