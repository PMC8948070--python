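# lianameta

Meta-analysis of climber (liana) removal experiments in tropical
forests: how much faster do trees grow, and how much more aboveground
biomass (AGB) do they accumulate, when competing climbing plants are cut
— and what would that be worth, in carbon terms, if applied across the
world's degraded tropical forests?

The package is aimed at forest-restoration and meta-analysis
practitioners. It takes a study-level table of treatment-vs-control
comparisons (group means, SDs, plot counts, and study covariates),
computes standardized effect sizes, handles missing variance reports by
multiple imputation, fits inverse-variance-weighted mixed-effects
meta-regressions, quantifies heterogeneity and publication bias, and
extrapolates the pooled biomass effect to carbon-sequestration
scenarios. A synthetic-data generator reproduces the statistical
structure of such a literature table so the entire pipeline is testable
without any external download.

## The model

Each treatment-vs-control comparison *i* yields a Hedges-*g*
standardized mean difference and its sampling variance:

    d_i = (x̄_t − x̄_c) / s_pooled,      J = 1 − 3 / (4(n_t + n_c − 2) − 1)
    g_i = J · d_i,                       v_i = J² [ (n_t+n_c)/(n_t n_c) + d_i²/(2(n_t+n_c)) ]

Effect sizes enter a weighted linear mixed model with a random intercept
per study *s(i)* (studies contribute several comparisons — multiple
timepoints and tree size classes):

    g_i = x_iᵀ β + u_{s(i)} + e_i,    u_s ~ N(0, τ²),   e_i ~ N(0, σ² v_i)

fitted by REML with weights 1/v_i and Satterthwaite per-coefficient
degrees of freedom. Continuous covariates are mean-centred and study
quality is treatment-coded with reference level "high", so the model
intercept is the overall summary effect; it is reported as a percent
increase (100·β₀) and fold change (1+β₀). Missing sampling variances
are filled in m = 10 times by stochastic log-linear regression
imputation, and coefficients, standard errors and dfs are averaged
across the m fits. Residual heterogeneity is summarized by Cochran's
Q and I² = max(0, (Q−df)/Q)·100; publication bias by Egger's weighted
funnel-asymmetry regression, a publication-year trend, and
Rosenthal/Rosenberg/Orwin fail-safe numbers.

The carbon extrapolation converts a baseline AGB growth rate AGBg₀
(Mg C ha⁻¹ yr⁻¹), the pooled relative enhancement *E*, an eligible
area and a deduction for the removed climbers' own biomass into
additional CO₂ over a horizon:

    AGBg_CR = AGBg₀ (1 + E)
    CO₂     = (AGBg_CR − AGBg₀ − AGBg_climber) · area · years · 44/12

## Worked example

```sh
lianameta simulate --out studies.csv --seed 3
lianameta run-all studies.csv --out out --seed 1 --m 10
```

prints (abridged):

```
Pooled meta-regression over m=10 imputations (rule=average)
  mean tau2: 0.0979651   mean sigma2: 1.46044
                      estimate      se       df  ci_low  ci_high       p
intercept               1.4894  0.1497  21.2546  1.1784   1.8005  0.0000
months_since_removal    0.0086  0.0012  93.2081  0.0062   0.0110  0.0000
n_species              -0.0003  0.0071  17.3077 -0.0153   0.0147  0.9704
quality[medium]        -1.5663  0.2140  18.4071 -2.0151  -1.1175  0.0000
quality[low]           -1.3061  0.2672  20.5100 -1.8626  -0.7495  0.0001
summary effect: 148.9% (95% CI 118-180%), 2.49-fold
heterogeneity: Q=166.0 (df=98, p=2.2e-05), I2=41% [moderate]
```

The synthetic table was generated with a true summary effect of 1.56 SD
units and between-study SD 0.5; the fitted intercept 1.49 says trees in
removal plots grew about 1.5 pooled SDs (≈149%) faster than controls in
this realization, the per-month coefficient says the advantage grows
slightly with monitoring time, and the negative quality coefficients
say lower-quality studies reported weaker effects than high-quality
ones. I² = 41% indicates moderate residual heterogeneity. The run also
writes `effects.csv`, `model_summary.csv`, `heterogeneity.csv`,
`bias.csv`, `forest_plot.csv` and a JSON run manifest into `out/`.

The same objects are available as a library:

```python
from lianameta import MetaRegression, build_effect_table, read_study_table

table = read_study_table("studies.csv")
effects = build_effect_table(table, "growth")
res = MetaRegression.from_dataframe(
    effects.dropna(subset=["variance"]),
    fixed_effects=["months_since_removal", "n_species", "quality"]).fit()
print(res.summary())
```

Carbon scenarios come from a YAML file (see
`examples/scenarios_synthetic.yaml`, whose climber-deduction and cost
range are documented placeholders):

```sh
lianameta extrapolate examples/scenarios_synthetic.yaml
```

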