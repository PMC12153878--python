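# ruminbal

Whole-animal energy- and nitrogen-metabolism analysis for 2×2 crossover
dairy-cow feeding trials measured in open-circuit respiration chambers.

The package covers the full pipeline:

- **`ruminbal.synthetic_trial`** — generates complete crossover trials with
  known ground truth: balanced block/sequence designs, cow-day performance
  records with additive treatment/period/block structure and a cow random
  intercept, well-mixed chamber gas traces (exact exponential washout
  dynamics, recovery scaling, sensor noise, optional diurnal modulation),
  and excreta allocated so that digestibility and nitrogen-flow truths are
  attained exactly when noise is off (the nitrogen ledger closes by
  construction).
- **`ruminbal.calorimetry`** — inverts chamber traces into daily gas volumes
  (trapezoidal integration on the native 6-min grid, recovery correction,
  gap flagging) and derives the fermentative/metabolic CO₂ partition,
  metabolic respiratory quotient, net fat and carbohydrate oxidation and
  heat production with the fixed published stoichiometric coefficients.
- **`ruminbal.nutrient_balance`** — energy-corrected milk, milk energy, ME
  intake, energy balance, apparent digestibilities (DM, OM, energy, crude
  protein), nitrogen partition, and the energy/nitrogen use efficiencies,
  collapsed per cow-period over a collection window.
- **`ruminbal.trial_stats`** — robust-z outlier screening, the DMI/mBW
  exclusion filter, the crossover linear mixed model (profiled REML,
  random cow intercept; fixed group/period/sequence/block effects) with a
  recorded fallback ladder (log2 transform on residual non-normality →
  gamma GLMM via PQL → plain linear model on singularity), Tukey–Kramer
  pairwise contrasts, and the two design-planning calculations (exact
  log-scale TOST equivalence sample size and noncentral-t sample size).
- **`ruminbal.io_cli`** — strict CSV schemas, the pipeline driver with a
  reproducibility manifest, report rendering, and the `ruminbal` CLI.

A deliberate convention note: the energy-balance milk term defaults to
3.14 MJ/kg ECM. The alternative literal value 0.00314 MJ/kg is selectable
(`eb_factor`) but is dimensionally implausible; using it is flagged in
the balance results, the manifest and the rendered report.

## CLI

```sh
ruminbal simulate   --out out/ --seed 1          # synthetic trial CSVs
ruminbal calorimetry --trace trace.csv --recovery 0.997 --nu 93.2
ruminbal run        --out out/ --seed 1          # full pipeline + manifest
ruminbal run        --out out/ --config cfg.yaml # override any PipelineConfig key
ruminbal power      --mode tost                  # equivalence sample size
ruminbal power      --mode ttest                 # superiority sample size
ruminbal report     --fits out/model_fits.csv
```

`ruminbal run` writes `animal_days.csv`, `excreta.csv`, `feed.csv`,
`truth.csv`, `gas_exchange_daily.csv`, `balance_results.csv`,
`model_fits.csv`, `report.txt` and `manifest.json`; identical config and
seed reproduce byte-identical numeric outputs.

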