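# axialgrowth

Axial growth analysis for hemianamorphic arthropod ontogenies (trilobite-style
cross-sectional developmental series). The package provides:

* **`axialgrowth.data_model`** — specimen measurement schema (cephalic parts
  FAL/PGL/ORL, thoracic segment lengths LTS1–LTS13, pygidial length PYL, all
  in mm), CSV I/O, derived quantities (CEL, TRL, BOL, relative segment
  lengths RLS and boundary positions RPS), per-stage summaries, trunk growth
  rates (TRG) and average growth rates (AGR).
* **`axialgrowth.synthetic_data`** — a seeded generator of specimen-level
  ontogenies (meraspid degrees D0–D12 plus holaspides) with a decaying
  per-stage trunk growth rate, a posterior-increasing segmental growth
  gradient, constant absolute pygidial length through D0–D10, two-phase
  log–log cephalic allometries and multiplicative lognormal noise.
* **`axialgrowth.allometry`** — major-axis regression coefficient profiles,
  continuous two-phase ("hinge") threshold regression with grid
  maximum-likelihood change-point estimation, pairs-bootstrap confidence
  intervals, BOL standardization of change points and stage assignment.
* **`axialgrowth.growth_gradients`** — the SG-R/SG-A segmental-gradient and
  TG-T/TG-D trunk-gradient models, Levenberg–Marquardt fitting with
  deterministic multistart, AICc model comparison with Akaike weights and
  evidence ratios, and the pygidial-stasis OLS test.
* **`axialgrowth.pipeline` / `axialgrowth.cli`** — end-to-end report
  assembly and the `axialgrowth` command-line tool.

## CLI

```sh
# generate a synthetic specimen CSV (234 specimens with default config)
axialgrowth simulate --seed 1 --out specimens.csv

# per-stage means, TRG and relative-length vectors
axialgrowth summarize --input specimens.csv --seed 1 --out summary.csv

# threshold (change-point) models and MA coefficient profiles
axialgrowth fit-allometry --input specimens.csv --seed 1 --boot-reps 1000 --out tables/

# SG/TG gradient model fitting and AICc comparison
axialgrowth fit-gradients --input specimens.csv --response rls --out comparison.csv

# everything at once, with a JSON manifest
axialgrowth report --simulate --seed 1 --out report/
```

Simulation configs are YAML/JSON mappings of `SimulationConfig` fields, e.g.

```yaml
seed: 1
gradient_model: TG-T
gradient_params: {c0: 0.4, c1: 3.0, q0: 0.54, q1: 0.835}
pygidium_mode: gradient
sigma_part: 0.02
```

## Specimen CSV dialect

Header `specimen_id,period,degree,FAL,PGL,ORL,LTS1,…,LTS13,PYL`; one row per
specimen; empty cells mean "not measured/not present"; lengths in mm with
decimal points; UTF-8. Meraspid rows carry a degree 0–12 and exactly
`degree` thoracic segment values; holaspid rows have no degree and up to 13
segment values.
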