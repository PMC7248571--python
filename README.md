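# hbpcost

Counterfactual costing engine for essential health-benefits packages
(HBPs) in stylised country income groups. Given a registry of
interventions — each with a unit cost, a population in need, baseline
coverage and classification attributes — the engine estimates the
baseline, incremental and total annual cost of delivering the package at
a counterfactual coverage target (default 80%), disaggregates costs by
delivery platform, delivery timing, health-system objective and package,
and quantifies uncertainty with one-way (tornado) and probabilistic
(Monte Carlo) sensitivity analysis.

The model operates on two stylised 2015 income groups: low-income
countries (population 0.90 billion, GNI $0.70 trillion) and
lower-middle-income countries (population 2.7 billion, GNI $5.9
trillion). A seeded synthetic generator emulates the structure of a
218-intervention / 21-package registry with a 115-intervention
highest-priority subset, so everything is testable offline; **dollar
totals of generated registries are synthetic** — only structure and,
for the calibrated fixture, cost *shares* are meaningful.

## Model overview

1. **Standardisation** (`hbpcost.standardize`): raw study unit costs are
   converted to 2016 exchange-rate USD with a bundled deflator/FX series
   (`indices.csv`, a documented stand-in, user-overridable), transferred
   to the target group by scaling the non-traded cost component with the
   ratio of per-capita GNI, and annualised (per-episode costs × episode
   rate).
2. **Engine** (`hbpcost.engine`): per (intervention, group),
   baseline = unit cost × population in need × baseline coverage;
   total = same at max(baseline, target) coverage (negative increments
   clamped by default); incremental = total − baseline. Package totals
   intentionally double-count shared interventions; de-duplicated totals
   count each intervention once. Health-system markups (facility 0.45 +
   above-facility 0.298 of service-delivery cost by default, jointly
   calibrated so health-system costs are 42.8% of the grand total) apply
   to de-duplicated totals only.
3. **Disaggregation** (`hbpcost.disaggregate`): shares by platform,
   timing, objective (with an explicit `unallocated` pathology
   remainder) and package, over service-delivery costs, with markups
   allocated pro-rata for grand-total tables. Combined-group shares pool
   costs before dividing.
4. **Sensitivity** (`hbpcost.sensitivity`): one-way swings per parameter
   family and a seeded Monte Carlo PSA (default 10 000 draws, 95%
   credible intervals as empirical 2.5/97.5 percentiles with linear
   interpolation). Each uncertain parameter draws from its own stream
   derived from the root seed, so adding a parameter never perturbs the
   others. Default plausible ranges (±50% unit cost, ±20% coverage,
   ±25% markups, uniform) are documented stand-ins.

## CLI

```bash
# generate a seeded synthetic registry (writes registry.csv + groups.csv + packages.csv)
hbpcost synth --seed 1 --out registry.csv
# or the share-calibrated fixture
hbpcost synth --seed 0 --calibrated --out fixtures/calibrated_euhc.csv

hbpcost validate registry.csv
hbpcost cost --registry registry.csv --out reports/ [--package-set hpp]
hbpcost disaggregate --registry registry.csv --by timing --cost incremental
hbpcost oneway --registry registry.csv --out tornado.csv
hbpcost psa --registry registry.csv --n-sims 10000 --seed 7 --out psa.csv
```

Exit codes: 0 ok, 1 runtime error, 2 usage/validation error. Every
`cost` run writes a `provenance.json` (input hashes, resolved config,
version) sufficient to reproduce its outputs. Config is YAML
(`--config`); flags win over config, config over defaults. Reports round
to two significant figures at render time only.

## Registry file schemas

`registry.csv` — one row per (intervention, group); classification
columns repeat per row and must agree. Columns: `intervention_id`,
`name`, `packages` (semicolon-separated integer ids), `platform`
(`population_based|community|health_centre|first_level_hospital|referral_specialty_hospital`),
`timing` (`urgent|chronic|time_bound`), `objective`
(`under5_mortality|mortality_5_69_cmpn|mortality_5_69_ncdi|disability|non_health|unallocated`),
`hpp`, `pathology` (booleans), `group`, `unit_cost_value`,
`unit_cost_currency`, `unit_cost_price_year` (1990–2016),
`unit_cost_source_gni_pc`, `unit_cost_basis`
(`per_patient_year|per_episode`), `episodes_per_beneficiary_year`
(required iff per_episode), `traded_fraction`, `population_in_need`,
`baseline_coverage`. Proportions are decimals in [0, 1]. Sibling files:
`groups.csv` (`id,population,gni_total`) and `packages.csv` (`id,name`).
`registry.json` holds all three tables in one document.

`fixtures/calibrated_euhc.csv` is the shipped calibrated fixture
(`hbpcost synth --seed 0 --calibrated`): unit costs are iteratively
reweighted (iterative proportional fitting on the platform and timing
margins of per-intervention incremental cost) until combined-group
incremental shares match published headline shares (health centre 49.8%,
chronic 45.5%, …). Its dollar totals are not estimates of anything.

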