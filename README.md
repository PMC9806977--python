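# trialcea

Trial-based cost-effectiveness analysis for a two-arm randomized trial,
built as a reusable, tested pipeline: item-level outcome and cost inputs
in, QALYs, cost profiles, incremental cost-effectiveness ratios (ICERs),
bootstrap confidence intervals, willingness-to-pay threshold fractions
and a cost-effectiveness acceptability curve (CEAC) out.

The package ships a synthetic trial generator with *analytic* ground
truth (expected incremental cost, QALYs and PHQ change implied by the
configuration in closed form), so the entire pipeline is testable
end-to-end with parameter-recovery experiments and no external data.

## Components

| module | role |
|---|---|
| `trialcea.synthetic_data` | two-arm trial generator (PHQ-9/WHODAS items, gamma service use, MAR monotone dropout) + `ground_truth` |
| `trialcea.outcomes` | PHQ-9 scoring (cutoff 10), WHODAS-to-disability linear mapping, health status = 1 − disability, trapezoidal QALY AUC |
| `trialcea.costing` | service use × unit cost, amortized implementation (training/supervision) costs, Int$2020 currency conversion, per-arm cost profiles |
| `trialcea.imputation` | chained-equation multiple imputation with predictive mean matching (deterministic, donor-membership guaranteed) |
| `trialcea.cea` | incremental deltas, ICERs (program-total and per-participant approaches), CE-plane quadrants |
| `trialcea.uncertainty` | paired within-arm bootstrap, percentile ICER CIs, threshold fractions, CEAC via net monetary benefit |
| `trialcea.reporting` | pipeline orchestration, tables, CE-plane / trajectory / CEAC figures, run manifest |

## CLI

The `trialcea` entry point exposes one subcommand per stage:

```sh
trialcea simulate --seed 1 --out data/            # synthetic CSV bundle + ground_truth.json
trialcea qaly --in data/ --out qalys.csv          # scoring + disability mapping + QALYs
trialcea cost --ledger ledger.yaml --in data/ --out costs.csv
trialcea impute --in analysis.csv --out imputed/ --seed 1
trialcea cea --approach total --effects qaly --in per_participant.csv --out cea.json
trialcea bootstrap --B 1000 --seed 1 --in per_participant.csv --out boot.csv
trialcea ceac --grid 0:20000:100 --in boot.csv --out ceac.csv
trialcea report --seed 1 --B 1000 --out run/      # full pipeline, all tables + figures
```

`trialcea report` emits: `table2_cost_profile.csv` (per-arm median/mean
costs by block), `table3_incremental.csv` (arm totals, deltas, ICERs
with 95% CIs), `fig1_health_effects.svg`, `fig2_ce_plane.svg` (with 1×
and 3× GDP rays), `fig_s3_ceac.svg`, replicate CSVs and a
`manifest.json` with config hash and output digests; identical config
and seed reproduce byte-identical CSVs.

## Conventions worth knowing

- ICERs are computed on full-precision deltas; rounding happens only in
  the reporting layer.
- Percentile CIs use linear interpolation between order statistics and
  are refused (with a pointer to the CEAC) when bootstrap replicates
  straddle zero incremental effect.
- PMM imputation only ever copies observed donor values, so bounded
  scores stay in range without truncation; observed cells are returned
  bit-identical in all m completed datasets.
- The disability-mapping coefficients are configuration data
  (`MappingCoefficients.from_yaml`); the built-in set is a documented
  uniform placeholder, not a published population mapping.
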