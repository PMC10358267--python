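# Methods

This note documents the statistical machinery behind `pssval`: what each
metric estimates, how the synthetic cohort is calibrated, which numerical
choices were made where several were defensible, and what the synthetic
tests do and do not establish about real data.

## Horizon status and ascertainment

All metrics are evaluated at fixed month horizons. A patient's status at
horizon *t* is DEAD if death was observed at or before *t*, ALIVE if
follow-up reached *t* alive (censoring exactly at *t* counts as ALIVE: the
patient was observed through the horizon), and UNKNOWN otherwise. UNKNOWN
patients are dropped per horizon (complete-case), which matches reporting
denominators of the form deaths/ascertained. No inverse-probability-of-
censoring weighting is applied; it would be a reasonable extension but
changes the estimand away from the one the reported counts define. Time is
in months as reals; follow-up is administratively censored at 24 months.

## Metrics

**Horizon AUC (c-index).** The probability that a random survivor received
a higher predicted survival value than a random non-survivor, ties counting
½; computed from Mann–Whitney rank sums, so it is invariant under strictly
monotone transforms and applies to integer scores directly. The default CI
is a stratified bootstrap (2000 resamples, survivors and non-survivors
resampled separately, percentile interval); a Hanley–McNeil normal
approximation is available as `ci_method="hanley"`. The bootstrap was
chosen because the validation study style reports CIs without naming a
method and the bootstrap is distribution-free and reproducible under a
seed.

**Brier score.** Mean squared error of predicted survival probability
against the alive indicator. The null model predicts the prevalence p̄ for
everyone, giving null Brier p̄(1−p̄) exactly; a constant-p̄ prediction
attains it identically, which the tests assert as an algebraic check.
Model quality is read from the difference (model − null); negative is
good.

**Calibration.** Three quantities on the ascertained patients, with
predicted probabilities clamped to [ε, 1−ε], ε = 10⁻⁶, before logits:

- *Calibration-in-the-large*: the intercept of a logistic model for the
  alive indicator with `logit(p̂)` as a fixed offset. Positive values mean
  observed survival exceeds predicted — the model underestimates survival.
- *Recalibration slope* (and its intercept): the joint logistic fit
  `logit P(alive) = a' + b·logit(p̂)`. A slope below 1 indicates
  predictions that are too extreme. Both the offset-model intercept and the
  joint pair are reported, because they answer different questions: the
  offset intercept is the average miscalibration holding slope at 1, and
  it equals the joint intercept only when b = 1.
- *log(O:E)*: `ln(observed survivors / Σ p̂)`, with the delta-method CI
  `± 1.96·√((1−p̄)/O)`.

Constant predictions leave the slope undefined (flagged, not an error);
the intercept and log(O:E) are still returned. The calibration curve is
formed from deciles of p̂ (duplicate-edge bins merged).

**Decision curve.** The event is death by the horizon and predicted risk is
1 − p̂. At threshold p_t, patients with risk ≥ p_t are classified positive
and net benefit is TP/n − FP/n·p_t/(1−p_t); treat-all and treat-none are
the comparators. The death-risk orientation was chosen because thresholds
then read as "acceptable risk of dying despite surgery"; the
survival-framed curve is its mirror image and derivable from the same
output. The default grid is 0.01–0.99 in steps of 0.01.

**Model consistency (MC).** For every patient and every ordered horizon
pair t₁ < t₂ with both predictions present, the pair is reasonable iff
p̂(t₁) ≥ p̂(t₂) (survival cannot rise with horizon; ties are reasonable).
MC is the fraction of reasonable pairs, reported per horizon pair and
overall, with the violating (patient, pair) records listed for inspection.

## Synthetic cohort

The generator emulates a 356-patient surgical cohort for extremity
metastasis: horizon mortality among ascertained patients of
5/18/32/51/61/68% at 1/3/6/12/18/24 months, ascertainment counts
356/350/342/326/314/302, median age 61 (range 25–95), 52% female, BMI
median 23 (13–39), 60% with an additional Charlson comorbidity, ECOG 0–2
in 79%, primary tumors lung 33% / breast 16% / hepatocellular 10% / other
41%, and per-lab missingness of 0.3% (sodium), 2.2% (lymphocyte,
neutrophil, calcium), 5% (alkaline phosphatase), 7% (albumin), and 25%
(blood urea nitrogen). Covariates not in that list (prior therapies,
metastasis sites, fracture type, ASA, lab marginals) use documented
placeholder defaults chosen once from clinical plausibility; they do not
enter any metric's correctness.

**Survival model.** Piecewise-exponential with knots at the six horizons —
the simplest family able to match all horizon targets exactly. Loss to
follow-up is an independent piecewise-exponential dropout process plus
administrative censoring at 24 months.

**Joint hazard calibration.** The emulated targets are *conditional on
ascertainment* (deaths/ascertained), so death and dropout hazards must be
solved together: calibrating the death hazard to the raw cumulative
mortality and then adding dropout overstates conditional mortality by up
to +0.055 at 24 months. The targets pin, per horizon k, the probability of
an observed death D_k = m_k·a_k and of being alive-and-followed
A_k = (1−m_k)·a_k, which yields a closed form on each interval:
total exit hazard ρ_k = −(ln A_k − ln A_{k−1})/Δ_k, death hazard
λ_k = ΔD_k·ρ_k/(A_{k−1} − A_k), dropout μ_k = ρ_k − λ_k. With full
ascertainment this reduces to the familiar
λ_k = −(ln S_k − ln S_{k−1})/Δ_k. Infeasible targets (non-decreasing
at-risk probability, decreasing deaths, negative implied dropout) are
rejected with the offending interval.

**Risk heterogeneity.** Each patient's death hazard is scaled by
exp(η_i), where η_i is an optional covariate linear predictor plus a
normal log-frailty with SD `frailty_sd` (default 1.5). Heterogeneity is
essential: with a single shared survival curve no prediction model can
exceed AUC 0.5, so target-AUC models would be unconstructible. At the
default, the latent truth's own 12-month AUC (the information limit) is
about 0.87 — above the strongest score a validation would realistically
meet, as a truth model must be. When η is present, per-interval baseline
hazards are solved by one-dimensional root-finding so the
population-average observed-death and at-risk probabilities still match
the targets exactly; with η ≡ 0 this coincides with the closed form.

**Missingness.** MCAR at the configured per-lab rates by default. A MAR
option raises the missingness log-odds with ECOG (sicker patients get
fewer elective labs) while rescaling to preserve the marginal rate, since
forest imputation behaves differently under MAR. Lab marginals are
normal/log-normal; an optional Gaussian copula injects pairwise lab
correlations (used by the imputation benchmark: albumin–BUN ρ = 0.8).

**Synthetic prediction models.** From the latent truth p_i(t), a model is

    p̂_i(t) = expit((logit p_i(t) + ε_i − a) / b)

with one patient-level ε_i ~ N(0, σ²) shared across horizons. The
parameters are stated in the *recoverable* direction: at large n and σ = 0
the downstream recalibration returns intercept a and slope b, so a > 0
means the model underestimates survival — consistent with the calibration
sign conventions above. Because the transform is monotone per patient
(b > 0), MC is exactly 1; per-horizon noise behind `horizon_noise_sd`
deliberately breaks it for MC testing. When `target_auc` is given, σ is
solved by bisection on an auxiliary sample of 50 000 patients bootstrapped
from the true reference-horizon probabilities with Bernoulli outcomes,
stopping within ±0.002 of the target; on a censored cohort the realized
AUC differs from the target by roughly the conditioning effect of
ascertainment (~±0.005 at n = 50 000). Score mode quantile-bins the latent
predictor into `n_score_levels` integers.

**What passing tests do not show.** The generator matches marginal
covariate distributions, horizon mortality, ascertainment, and missingness
rates, but not inter-covariate dependence beyond the optional copula, not
tumor-type-specific survival, and not the messiness of real predictions
(systematic subgroup miscalibration, heaping, data-entry error). Metric
correctness established here transfers to real data; generalization claims
about any particular scoring system do not.

## Imputation

The missForest scheme: initialise gaps with column means; each sweep,
visit variables in ascending missingness (ties by column order, for
determinism) and refit a random forest (default 100 trees; tests and the
acceptance benchmark use 20–30 for speed) of the variable on all other
currently-completed columns, re-predicting the missing cells; stop when
the normalised squared difference between successive sweeps first rises,
returning the previous sweep's values, or at `max_iter` (default 10).
Only the ten labs are imputation targets — they are the only variables
with missingness in the emulated study — while every covariate serves as
a predictor (categoricals one-hot). Out-of-bag R² per variable is
converted to an error estimate. Observed cells are never modified, which
is asserted at run time. The complete-case subset (all ten labs observed,
order preserved) feeds the sensitivity analysis; at the default rates the
expected subset size is 356·Π(1−r_j) ≈ 220 under MCAR.

## Pipeline

`run_validation` imputes (unless disabled or nothing is missing), computes
every metric for every model at every available horizon, and repeats
everything on the raw cohort's complete cases. Per-metric seeds are
derived from the run seed with `numpy.random.SeedSequence`, so reruns are
byte-identical. A model may omit horizons; metrics are computed where
predictions exist and report an explicit unavailability reason otherwise
(e.g. "integer-score model without a score map"). Report tables round to
2 decimals and mark unavailable cells with an en-dash.

## Problem sizes and numerical choices

Calibration parameter recovery uses n = 20 000 with full ascertainment
(the generator's identity setting, so recovery error reflects only the
estimator); the simulator-calibration check averages 200 seeded
356-patient cohorts, where the standard error of mean mortality is about
0.001–0.003 per horizon; the imputation benchmark uses 20 seeded cohorts
with 30-tree forests. Probability clamping before logits is ε = 10⁻⁶;
AUC ties count ½; bootstrap intervals are percentile with the point
estimate forced inside. One arithmetic inconsistency in the reference
figures is handled explicitly: a 3-month null Brier given as 0.16 where
the accompanying counts (63/350) give 0.148 → 0.15; the implementation
follows the stated prevalence definition, and the 3-month cell is
excluded from the reference-value comparison for that reason.

## Known limitations

- Complete-case handling per horizon; no censoring weights.
- No CI for net benefit (descriptive curves only, as is conventional).
- No between-model significance testing; comparison is descriptive.
- Score→probability maps must be supplied; the package does not infer
  them from development publications.
- The generator's lab marginals and several covariate frequencies are
  placeholders, adequate for metric testing but not for clinical realism.
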