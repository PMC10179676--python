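# iuiselect

Threshold discovery, GEE significance filtering and an eligibility decision
rule for intrauterine-insemination (IUI) cycle cohorts.

Given a per-cycle table (couples as clusters, up to four cycles each, a
binary clinical-pregnancy outcome, and male/female covariates), the pipeline

1. **discovers** extreme-value cutoffs in a first recruitment period: for
   each parameter, the directional extreme beyond which no pregnancy was
   observed;
2. **validates** each cutoff for consistency against the second period's
   group extremes (boundary inclusive), with a configurable
   `cutoff_policy ∈ {discovery, validation, tighter}` for the surviving
   cutoff value;
3. **binarizes** cycles into normal/altered flags (strictly beyond the
   cutoff = altered);
4. fits a **binomial-logistic GEE** with exchangeable working correlation,
   robust sandwich covariance, per-term Wald tests and odds ratios
   (implemented from scratch; agrees with `statsmodels` to ~1e-10, which the
   test suite uses as an independent oracle);
5. applies the **decision rule** — decline IUI when any significant
   validated rule flags a cycle — and evaluates it retrospectively
   (retained-cycle breakdown, counterfactual pregnancy rate, relative gain),
   alongside per-period descriptive statistics.

A synthetic-cohort module (`iuiselect.synthetic`) generates cohorts with the
assumed statistical structure: couple-level covariates from truncated
normals, within-couple correlated outcomes via a logistic random-intercept
model, optional hard thresholds that force non-pregnancy beyond a cutoff
(with anchor records so discovery recovers the cutoffs exactly), plus
fixture builders that realise exact group extremes or exact published
counts. Bundled reference tables (`iuiselect/data/`) encode the original
cohort's parameter policies, per-period group extremes, and the eleven
validated rules.

## Command line

```sh
# full pipeline from a config file (synthetic source shown; use input:
# {cohort: ..., parameters: ...} for real data)
iuiselect run --config pipeline.yaml --seed 7 --outdir out/ \
    --cutoff-policy discovery --alpha 0.05
```

writes `rules.{json,csv}`, `gee_report.{json,csv}`, `policy_report.json`,
`descriptives.json` and a reproducibility `manifest.json` (byte-identical
outputs under a fixed seed). Individual stages are available as
`iuiselect simulate | discover | validate | fit | evaluate`, all reading and
writing the same CSV/JSON interchange formats. Example config:

```yaml
synthetic:
  couples_discovery: 93
  couples_validation: 104
  seed: 7
  outcome:
    intercept: -2.14          # ~10.5% per-cycle rate
    random_intercept_sd: 0.6  # couple-level heterogeneity
    hard_rules:
      - {parameter: male_age, direction: upper, cutoff: 41.0}
cutoff_policy: discovery
correlation: exchangeable
alpha_level: 0.05
```

Note: rules discovered and validated on the *same* data necessarily have
zero pregnancies in their altered region, so their flags quasi-separate the
outcome; `run` screens such columns out of the GEE stage (logged) and, if no
testable column remains, applies the policy with all validated rules.

## Layout

| module | contents |
| --- | --- |
| `iuiselect.cohort` | `ParameterSpec` / `CycleRecord` / `Cohort`, CSV I/O, period split |
| `iuiselect.synthetic` | generators, extreme/count fixtures, ICC estimator |
| `iuiselect.thresholds` | `ThresholdRule`, discover/validate/binarize |
| `iuiselect.gee` | exchangeable GEE, Wald report, significance filter |
| `iuiselect.policy` | recommend/evaluate_policy/describe |
| `iuiselect.cli` | `iuiselect` command group and pipeline orchestration |
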