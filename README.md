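# coendorse

Survey-weighted analysis of binary co-endorsement data: post-stratification
weighting by iterative proportional fitting, design-based prevalence
estimates with Rao–Scott adjusted-F independence tests, bivariable weighted
logistic odds ratios, pairwise overlap / odds-ratio matrices, and a
conditional-dependence (Ising) network estimated by nodewise L1-penalised
logistic regression with one-standard-error cross-validation and AND-rule
edge selection.

A synthetic cohort generator with known ground truth (pairwise binary
Markov random field on {0,1}^p, demographic threshold shifts, stratified
countries, and biased sampling) makes every stage testable by oracle
equivalence and parameter recovery.

## Package layout

| module | contents |
| --- | --- |
| `coendorse.items` | item battery encoding (yes/no items, likelihood composite) |
| `coendorse.synthetic` | Ising simulator (exact enumeration / Gibbs), cohort presets, biased sampling |
| `coendorse.weighting` | raking (`rake`, `rake_by_stratum`), margin specs and reports |
| `coendorse.prevalence` | weighted prevalence with logit CIs, second-order Rao–Scott adjusted F |
| `coendorse.correlates` | bivariable weighted logistic OR grid with sandwich CIs |
| `coendorse.coendorsement` | overlap row proportions, pairwise ORs, margin reconstruction |
| `coendorse.network` | penalised paths, one-SE CV, AND-rule, symmetrised conditional ORs |
| `coendorse.pipeline` / `coendorse.cli` | end-to-end orchestration, config, manifest |

## CLI

```bash
coendorse simulate --preset default --n 5000 --seed 1 --out-dir cohort
coendorse rake --demographics cohort/demographics.csv --margins margins.json --out weights.csv
coendorse prevalence --responses cohort/responses.csv --demographics cohort/demographics.csv \
    --weights weights.csv --by country
coendorse correlates --responses ... --demographics ... --weights ...
coendorse overlap --responses ... --demographics ... --weights ...
coendorse network --responses ... --demographics ... --weights ... --folds 10 --seed 1
coendorse run --config config.yaml        # full pipeline with manifest
```

A minimal YAML config for the full pipeline:

```yaml
preset: default      # or responses_path/demographics_path/margins_path
n: 5000
seed: 1
out_dir: out
```

## Notes

- Ising coding is {0,1}, so pairwise interaction weights are conditional
  log-odds ratios and post-selection refit ORs estimate them directly.
- Gibbs defaults: 1,000 burn-in sweeps, thinning 10, parallel chains;
  exact enumeration is available for p ≤ 20.
- Raking defaults: tolerance 1e-6 on margin proportions, 200 cycles,
  no trimming (enable with `trim_cap`).
- Predictor standardization before penalisation is ON by default and
  changes variable selection; disable with `--no-standardize`.
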