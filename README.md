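# thirdvar

Third-variable (mediation/suppression) decomposition of exposure–outcome
associations with standardized linear models, built around the classic
four-step procedure:

1. **Total effect** `c`: standardized coefficient of the exposure X in
   `Y ~ X + covariates`.
2. **Action paths** `beta1_k`: standardized coefficient of X in
   `Z_k ~ X + covariates` for each intermediate variable Z.
3. **Outcome model** `c'` and `beta2_k`: standardized coefficients from
   `Y ~ X + Z_1..Z_K + covariates`.
4. **Classification**: with `beta_Ind = beta1 * beta2`, and provided
   `|c| > |beta_Ind|`, the intermediate is a *mediator* if `|c| > |c'|`
   (effect % = `|beta_Ind|/|c| * 100`) and a *suppressor* if `|c| < |c'|`
   (effect % = `|beta_Ind|/|c'| * 100`). Indirect effects are tested with a
   first-order delta-method (Sobel-type) z-test.

All sub-models are fit on a single shared complete-case sample with shared
scaling, so the identity `c = c' + sum_k beta1_k * beta2_k` holds to
machine precision — this is enforced at run time and by the test suite.

The package targets cohort analyses of the form "serum biomarker exposure →
leukocyte telomere length, with BMI and log-CRP as intermediates", but the
model spec is generic over the bundled variable set.

## Layout

| module                 | contents |
|------------------------|----------|
| `thirdvar.datamodel`   | cohort table + model spec, CSV dialect (round-trip exact), validation report |
| `thirdvar.preprocess`  | natural-log transforms with below-LOD policies, T/S-ratio → base-pair conversion (`3274 + 2413 × T/S`), covariate coding, complete-case filtering, standardization, design matrices |
| `thirdvar.regression`  | OLS with standardized coefficients and t-based inference, ANCOVA adjusted means, chi-square descriptives |
| `thirdvar.decompose`   | the four-step decomposition, Sobel-type tests, mediation/suppression classification, effect percentages |
| `thirdvar.subgroup`    | per-path two-group interaction tests (stratified betas + pooled interaction p), predictor-swap sensitivity analysis |
| `thirdvar.synthetic`   | seeded cohort generator with linear-Gaussian structure and a closed-form oracle for the implied standardized paths |
| `thirdvar.cli`         | `simulate` / `analyze` / `subgroup` / `report` subcommands |

## CLI

Runs are driven by a YAML config with exactly one input source (a cohort
CSV or synthetic-generator parameters):

```yaml
# config.yaml
synthetic: {n: 4047}
seed: 7
model:
  predictor: cotinine
  outcome: ltl
  third_variables: [bmi, crp]
  covariates: [age, race, sex, physical_activity, alcohol_use]
lod_policy: lod_over_sqrt2
group_vars: [race, sex]
output_dir: out
```

```sh
thirdvar simulate -c config.yaml          # write out/cohort.csv (+ params log)
thirdvar analyze  -c config.yaml          # full bundle: model tables (TSV),
                                          # decomposition JSON/TSV per Z-set,
                                          # subgroup tables, descriptives, run log
thirdvar subgroup -c config.yaml -g race  # one subgroup table only
thirdvar report   -b out                  # plain-text report rendered from the
                                          # serialized JSON (no recomputation)
```

The cohort CSV dialect has a fixed lower-snake-case header
(`age,sex,race,physical_activity,alcohol_use,current_smoker,cotinine,crp,bmi,ltl_bp,ts_ratio`),
empty cells for missing values and `"<0.05"`-style entries for below-LOD
biomarker values. Either `ltl_bp` or `ts_ratio` may be given; T/S ratios
are converted to base pairs on the fly.

## Notes and documented choices

* Logs are natural logs; the log base does not affect standardized betas.
* Below-LOD values default to LOD/sqrt(2) substitution (`half_lod` and
  `strict` also available); substitutions are counted in the run log.
* SDs use the n−1 denominator; standardized betas for binary indicators are
  scaled like continuous terms.
* Alcohol use is an ordinal 0–3 score; physical activity is a single
  any-activity indicator.
* Classical (homoskedastic) SEs; no survey weights or design-based
  variance.
* No imputation: complete-case analysis only.
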