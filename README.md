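# flip2sss

Robust tests for regression coefficients in **two-level clustered
generalized linear models** — longitudinal binary outcomes, repeated counts,
growth curves — without specifying a random-effects structure or a working
correlation.

The method is a two-stage summary-statistics procedure with sign-flipping
score inference:

1. **Stage 1** fits a small GLM inside every cluster (subject), reducing it
   to its coefficient vector `b_j` — intercept, time slope, and so on. For
   binary responses the Firth bias-reduced fit is used by default, so
   complete separation (a routine event with 4–8 observations per cluster)
   still yields finite, bias-reduced estimates.
2. **Stage 2** collects the N×h matrix `B` of these estimates and models it
   with a masked multivariate linear model `B = Z Γ + E` in the
   between-cluster covariates `Z`. Each coefficient of `Γ` is tested with a
   **standardized sign-flipping score test**: the effective score
   `S = Σ_i ν_i` is decomposed into one contribution per cluster, the signs
   of the contributions are flipped `B` times (the same flips across all h
   models), each flipped score is studentized by
   `σ_F = sqrt(Σ ν_i² − S_F²/n)`, and the p-value is the fraction of flips
   at least as extreme as the observed statistic. Per-covariate ANOVA-like
   tests combine the flipped score vectors through a Mahalanobis quadratic
   form.

Because the flip distribution is built from the data's own per-cluster
contributions, the test is robust to heteroscedasticity between clusters,
unequal cluster sizes, and misspecified (indeed, unspecified) random-effect
structure — the situations where GLMM and GEE inference is fragile.

## Worked example

A longitudinal follow-up study: a binary health indicator (`unhealth`)
recorded at several visits per child, with cluster-constant demographics
(`country`, `age`, `sex`). One formula describes both stages: terms that
vary within clusters (`time`) form the stage-1 design; cluster-constant
terms model the within-intercept column; the `sex:time` interaction lets
`sex` additionally model the time-slope column.

```sh
flip2sss run --data followups.csv \
  --formula "unhealth ~ 1 + country + age + sex + time + sex:time" \
  --cluster child --family binomial --stage1 firth --B 5000 --seed 1 \
  --out results/
```

Output on a synthetic 60-child dataset (227 visits):

```
             term within_column  estimate  score_stat  p_value
      (Intercept)   (Intercept)  0.730463    1.396094   0.1788
country[ethiopia]   (Intercept) -0.284839   -0.707772   0.4928
   country[india]   (Intercept) -0.705884   -1.483445   0.1508
              age   (Intercept) -0.159279   -1.949787   0.0594
           sex[m]   (Intercept)  0.727447    1.961975   0.0556
      (Intercept)          time -0.131679   -0.687156   0.5018
           sex[m]          time -0.110783   -0.485240   0.6166

       term  n_components  score_stat  p_value
(Intercept)             2    1.808290   0.4074
    country             2    2.066589   0.3530
        age             1    3.553552   0.0594
        sex             2    4.220452   0.1184
```

Reading it: each row of the first table is one stage-2 coefficient — e.g.
`sex[m]` on the `(Intercept)` column asks whether boys have a higher
baseline probability of health issues (estimate +0.73 on the logit scale of
the per-child intercepts; standardized flip statistic 1.96; two-sided
p = 0.0556 from 5000 sign flips). Rows `(term, time)` exist only for terms
the formula unmasks on the slope column — `country` and `age` never appear
there. The second table gives one combined test per covariate, pooling its
dummy columns across the within-columns it models: `sex` has two components
(baseline and time slope), `age` one. `results/runlog.json` records seed,
flip mode, B, the stage-1 diagnostic counts (separated / non-converged /
inestimable clusters) and the standardization formula, enough to reproduce
the run bit for bit.

The same interface is available in Python:

```python
from flip2sss import parse_model, fit_flip2sss
spec = parse_model("unhealth ~ 1 + country + age + sex + time + sex:time",
                   df, "child", B=5000, seed=1)
result = fit_flip2sss(df, spec)
result.coefficient_table; result.anova_table; result.runlog
```

## Simulation study

`flip2sss sim --scenario scenario.yaml --out report.csv [--plot report.png]`
runs replicated scenarios of the built-in generative model (random intercept
+ random slope logistic clusters, correlated within-cluster nuisance,
balanced or unbalanced sizes) and reports rejection rates with Monte-Carlo
half-widths for the method (ML or Firth first stage) and the comparators
(naive GLM Wald, GEE-independence). See `docs/methods.md` for the model and
its defaults.

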