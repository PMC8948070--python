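# Methods

## Effect sizes

The primary effect measure is the small-sample-corrected standardized
mean difference (Hedges *g*) between climber-removal and control plots,
with the large-sample variance

    var_g = J² [ (n_t+n_c)/(n_t n_c) + d²/(2(n_t+n_c)) ],
    J = 1 − 3/(4(n_t+n_c−2) − 1),

the convention of the standard effect-size references and of the
widely used R implementations (`metafor::escalc`, `compute.es`), so an
independent cross-check against any of them is meaningful. The raw mean
difference is available as a sensitivity measure. One effect size is
computed per comparison; a study contributes several when it reports
multiple timepoints or tree size classes.

Degenerate rows (zero pooled SD, fewer than three units in total) are
excluded with a logged warning rather than aborting the run: extracted
literature tables routinely contain salvageable rows.

**Comparisons without reported dispersion.** Some studies report group
means but no SDs. Their standardized estimate is computed with the one
observed group SD if present, otherwise with the median pooled SD of
the complete rows for the same response metric, and the sampling
variance is left missing for the imputation stage. This is a
reconstruction — the original workflow's handling of such rows is
described only in supplementary material not available here — chosen so
that no estimable comparison is dropped while the extra uncertainty is
still propagated through the variance imputation.

## Imputation of missing variances

Missing sampling variances are imputed m = 10 times from an OLS
regression of log(variance) on log(n_t + n_c) and |estimate| fitted to
the complete rows, adding a fresh Normal(0, residual SD) draw per row
per imputation. The log scale guarantees positivity; the noise makes
the imputations proper, so cross-imputation spread reflects imputation
uncertainty. Predictors and noise model are likewise a documented
reconstruction (the two predictors capture the dominant structure of
the variance formula: sample size and effect magnitude). When fewer
than five complete rows exist the imputer falls back to hot-deck
resampling of observed variances rather than failing.

Random draws come from substreams keyed by (master seed, imputation
index, CRC32 of the row key), so results are reproducible and adding or
reordering rows does not perturb other rows' draws.

## The weighted mixed model

Effect sizes are analysed with an lme4-style weighted linear mixed
model: fixed covariate effects, a random intercept per study, known
prior weights 1/v_i, and a freely estimated residual scale σ² (so the
row-level residual variance is σ²·v_i). This mirrors the original
analysis — a weighted LMM fitted with lme4/lmerTest — rather than a
classical `rma`-type model, whose residual scale is fixed at 1; the two
coincide when σ̂² ≈ 1 and otherwise the LMM rescales all sampling
variances by a common factor.

Estimation is REML. The restricted likelihood is profiled analytically
over σ², leaving a one-dimensional deterministic bounded search over
log(τ²/σ²) (search interval e⁻³⁰…e³⁰, tolerance 1e−9, explicit
comparison against the τ² = 0 boundary; no random starts). Per-study
Woodbury identities keep each likelihood evaluation O(k·p²).
Per-coefficient denominator degrees of freedom use the Satterthwaite
approximation, with the variance of (τ̂², σ̂²) taken from a central
finite-difference Hessian of the restricted log-likelihood
(forward-shifted at the τ² = 0 boundary); if the Hessian is singular
the residual df k − p is used as a fallback. On a reference dataset the
full fit — coefficients, SEs, Satterthwaite dfs, τ², σ², restricted
log-likelihood — matches lme4 + lmerTest to six significant figures
(frozen in the test suite).

Continuous covariates are mean-centred and study quality is
treatment-coded with reference "high", making the intercept the summary
effect at average covariate values in a high-quality study. The percent
(100·β₀) and fold (1+β₀) presentations are display transforms only.

Named covariate sets reproduce the published model objectives: the
magnitude model (months since removal, number of species, quality) and
the driver models (removal method, repetition, disturbance context,
climate) — all the same operation with different `fixed_effects` lists.

## Pooling across imputations

The default rule averages coefficients, SEs and dfs arithmetically
across the m fits and recomputes CIs and p-values from the averages —
the convention of the original analysis, retained for fidelity even
though Rubin's rules are statistically preferable. Rubin pooling
(within + (1+1/m)·between variance, Barnard–Rubin df) is provided as a
diagnostic alternative; it widens SEs when imputations disagree.

## Heterogeneity

Q is the weighted residual sum of squares of the *fixed-effects*
(τ² = 0) fit of the same design matrix — residual (QE-style)
heterogeneity, since the reported statistics accompany covariate-bearing
models — with df = k − p and a χ² upper-tail p-value.
I² = max(0, (Q−df)/Q)·100 is read against the 25/50/75 anchors with
band edges at the midpoints (37.5, 62.5). Confidence intervals use a
nonparametric bootstrap over effect rows (default 2000 resamples,
percentile intervals, degenerate resampled designs redrawn); the
original interval construction is undocumented, and a Q-profile
analytic interval is a possible future alternative. Across imputations,
Q, I² and interval endpoints are averaged, matching the coefficient
pooling convention.

## Publication bias

Egger's test regresses effect size on its standard error with weights
1/v (the algebraically equivalent precision-regression form of the
classic intercept test); numerically exact fits (zero residual) are
reported as p = 1 when flat. The publication-year trend is an
inverse-variance-weighted regression of effect size on year. Fail-safe
numbers: Rosenthal's classic floored count from summed z-scores
(one-tailed α = 0.05 by default — conventions differ, so this is
configurable); Rosenberg's weighted analogue, defined as the smallest
number of zero-effect studies of average weight whose addition lifts
the one-tailed pooled p to ≥ α (verified against brute-force appending);
and Orwin's count with the target defaulting to half the observed mean
effect. Bias diagnostics run on the first completed imputation by
default, preceding pooling in the workflow.

## Carbon extrapolation

The enhanced growth rate is AGBg₀·(1+E). Additional sequestration is
(AGBg_CR − AGBg₀ − AGBg_climber)·area·years·44/12; the conversion to
CO₂ is applied once to the net rate — the published formula's
precedence is ambiguous as printed, and this reading follows the
accompanying prose ("the final difference in AGB" converted to CO₂).
Cost efficiency is per-ha cost × area / additional CO₂. The bundled
example scenarios ship *placeholder* values for the climber biomass
deduction and the per-ha cost range (the real numbers live in the
study's deposited additional data); nothing is back-solved from
published totals. Negative net rates are returned with a warning, not
hidden. Internally everything is kept at full precision; table views
round to 2 decimals.

## Synthetic data generator

The generator emulates an extracted climber-removal literature table:
26 studies contributing 103 growth comparisons (12/69 for the biomass
arm preset), study covariates drawn over the reported context ranges
(elevation 13–776 m, precipitation 1144–2964 mm yr⁻¹, temperature
21.2–27.7 °C, dry season 0–7 months, monitoring 12–228 months,
disturbance mix and regional imbalance matching the study counts), a
Normal(0, τ²) study effect with τ = 0.5 by default, a true summary
effect of 1.56 SD units (2.09 for the biomass preset), a 0.01/month
monitoring-time slope and quality offsets −1.18/−1.22 — the published
coefficient structure.

True effects live on the SMD scale and are back-converted to group
summaries; *observed* means and SDs are then drawn from their sampling
distributions (Normal means, χ-scaled SDs) so that the computed Hedges
g carries genuine sampling error of approximately the magnitude its
variance formula claims, and calibration (type-I error, CI coverage) is
a meaningful question. Plot counts per arm are drawn uniformly from
3–10, a typical replication level for stand-scale removal experiments.
Covariate contributions are applied as deviations from the realized
table mean, so the generator's `true_intercept` is exactly the estimand
of the fitted model's centred intercept. Missingness of SDs is MCAR by
default (an MAR option keyed to sample size exists); an optional
censoring parameter drops "nonsignificant" comparisons to emulate
publication bias.

What the generator does *not* emulate: correlated sampling errors among
comparisons sharing control plots, heterogeneous growth metrics needing
standardization, non-Normal study effects, and real missingness
mechanisms. Passing recovery tests therefore demonstrate the pipeline's
internal consistency under the stated model, not robustness to those
features of real data.

## Problem sizes and calibration results

The test suite replicates the full pipeline 200 times at the default
dimensions (m = 10) for parameter recovery, runs a 500-replicate null
simulation for the intercept's type-I error (measured at 4.8%, within
the 2–9% band), and checks coverage of the monitoring-time slope; the
acceptance script uses 100 replicates per arm. These sizes were chosen
to keep each target's Monte-Carlo standard error near one percentage
point.

**Known limitation — small-sample weighting bias.** With the row's own
d² inside its variance, inverse-variance weighting systematically
downweights comparisons that randomly drew large effects, biasing the
pooled SMD downward. At the default plot counts (3–10 per arm) and a
true effect of 1.56, the recovery simulations measure a mean bias of
about −0.12 to −0.15 SD units (≈ −8%) with intercept CI coverage just
below 90%; diagnostic runs with equal weights or true-variance weights
are unbiased, and the fit itself is verified against lme4/lmerTest, so
the bias is a property of the published estimator at small per-study
replication, not of this implementation. It shrinks quickly as group
sizes grow (the consistency test verifies monotone RMSE decrease) and
is absent for the unstandardized mean-difference sensitivity measure's
weighting structure only insofar as its variance omits the d² term.
Real syntheses with comparable replication should expect the same
order of attenuation.

## Numerical and degenerate-input conventions

CSV exports use 12-significant-digit floats (round-trip safe), UTF-8,
comma separator, empty cell = missing. Validation is total: malformed
inputs raise errors naming the offending row/column. Ties and
degenerate cases: τ̂² = 0 is accepted at the boundary (profile compared
explicitly); two-point Egger/year-trend fits report df = 0 with NaN
p-values; zero-sequestration scenarios make cost-efficiency an error
rather than ∞; empty result sets still produce a manifest.
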