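# fiscalfood

An integrated simulation framework for studying food import tariffs as a
public-health and environmental policy instrument.  A recursively-dynamic
multi-sector general-equilibrium economy is coupled to household food-demand
systems (AIDS), a fatty-acid → serum-cholesterol transmission chain, stratified
clinical cardiovascular outcomes, a cohort-component demographic projection
with mortality feedback, labour-supply and health-cost feedbacks into the
economy, and a land-use-change greenhouse-gas satellite module.

Because the original calibration data (a national social accounting matrix and
household surveys) are not public, the package ships a deterministic
synthetic-fixture generator that reproduces the published structural targets:
a balanced 49-sector social accounting matrix whose 8-sector aggregation
matches the published import/export/tariff/sales/consumption shares (average
import share 24.0%, average tariff 1.6%, beverages tariff 22.7%), nine
regional household types, seven production factors including four regional
land types, 10 cholesterol-biomarker strata on [2.0, 7.0], gender × 15
age-group × rural/urban population strata, and degree-10 polynomial clinical
rate lookups.

## Package layout

| module | contents |
|---|---|
| `fiscalfood.sam` | SAM data model, CSV dialect, RAS balancing, 49→8 aggregation |
| `fiscalfood.fixtures` | seeded synthetic fixture bundle (SAM, elasticities, nutrients, biomarkers, clinical lookups, demography, health-economics, emission coefficients) |
| `fiscalfood.cge` | benchmark calibration, within-period Newton solve, recursive dynamics and growth-trend calibration |
| `fiscalfood.demand` | AIDS calibration from elasticities and demand evaluation |
| `fiscalfood.nutrition` | fatty-acid intake shares, cholesterol response, biomarker strata |
| `fiscalfood.clinical` | polynomial outcome-rate lookups, stratified rates and levels |
| `fiscalfood.demography` | cohort-component projection, transition calibration, excess-mortality feedback |
| `fiscalfood.feedbacks` | caregiver/patient time losses, effective labour supply, lagged health costs |
| `fiscalfood.luc` | land-transition flows and GHG emission deltas |
| `fiscalfood.scenarios` | scenario orchestration, efficiency/health-pathway decompositions, cost-effectiveness |
| `fiscalfood.reporting` | tidy CSV/JSON output tables |

## Command line

```bash
# generate the fixture bundle into a directory of CSVs + manifest
fiscalfood make-fixtures --seed 20160101 --out fixtures/

# run scenarios described in YAML (policy + efficiency + health-pathway)
fiscalfood run --scenario scenario.yaml --out results/ --mode all

# re-derive summary tables from a run directory
fiscalfood report --in results/ --out tables/
```

A scenario YAML names a counterfactual (`bau` with the calibrated tariff
structure, or `nitd` with all tariffs eliminated) and one intervention
template:

```yaml
name: food30
counterfactual: nitd
intervention: uniform_food   # none | eliminate_food | eliminate_nonfood |
                             # eliminate_all | uniform_food | uniform_all | sector
rate: 0.30
# sector: beverages          # for the `sector` template
start: 2016
end: 2035
```

## Notes

- All within-period equilibria satisfy market clearing to ≤ 1e-9 with the
  omitted (Walras) market clearing to ≤ 1e-8; benchmark replication of the
  calibrating SAM is exact to ≤ 1e-8.
- Fixture generation, scenario runs and reports are pure functions of the
  seed: same-seed runs are bit-identical.
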