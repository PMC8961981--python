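# Methods

This note documents the statistical methods implemented in `dmtrank`: the
outcome models, the sampler, the ranking and reporting layer, the validation
and monitoring machinery, the propensity-weighted evaluation studies, and
the synthetic registry generator that serves as the package's study
environment. Design decisions that required a judgement call are marked as
such.

## 1. Unit of analysis: the therapy switch

The clinical question is prospective: *a patient is stopping their current
disease-modifying therapy (DMT) — which therapy should come next?* The
modelling unit is therefore the **therapy switch**: each time an eligible
patient stops one DMT and starts another, the package forms one row with

* baseline predictors frozen at the switch (index) date: age, sex, EDSS,
  the discontinued DMT and its duration, number of previous DMTs, any
  previous second-line exposure, time since diagnosis, relapses in the 12
  months before the index date, and time since the last relapse (capped at
  120 months);
* the newly assigned DMT;
* outcomes over the subsequent exposure window: the relapse count and an
  indicator of 3-month confirmed disability progression (3mCDP), with the
  exposure time in months.

3mCDP is derived from the EDSS trajectory: an increase of ≥ 1.0 point over
the index baseline (≥ 0.5 above baseline 5.5) confirmed by the first EDSS
assessment at least 90 days after the provoking one. A patient with no
follow-up assessment is censored for this outcome.

Eligibility mirrors a routine-care RRMS cohort: age 18–70, EDSS ≤ 6.5 at
the index date, an identifiable current-therapy episode, and ≥ 6 months of
registry history before the switch.

## 2. Outcome models

Both models are hierarchical Bayesian generalized linear models sharing the
design: standardized continuous predictors, 0/1 indicators for sex and
prior second-line exposure, one-hot coding for the discontinued DMT against
its most frequent level, and a partially pooled per-assigned-DMT effect.

**Relapse count** `y_i` over exposure `t_i` months:

    y_i ~ NegBin(mu_i, r),   log mu_i = b0 + x_i' beta + alpha_{d(i)} + log t_i

with dispersion `r` (variance `mu + mu^2/r`). The probability of staying
relapse-free over a horizon `h` is the negative-binomial zero probability

    P(relapse-free) = (r / (r + mu(h)))^r .

**3mCDP indicator** with a complementary-log-log link and the same exposure
offset, i.e. a discrete-time proportional-hazards form:

    P(event by t) = 1 − exp(−t · exp(b0 + x' beta + alpha_d)) .

A logistic alternative with `gamma · log t` as a free exposure coefficient
is available behind `ModelSpec(cdp_link="logit_exposure")`.

**Priors.** Normal(0, 2.5) on standardized coefficients, Normal(0, 5) on
the intercept, Normal prior on `log r`. Therapy effects are non-centred:
`alpha_d = tau * a_d`, `a_d ~ N(0,1)`, with a boundary-avoiding
Gamma(2, 1) prior on the pooling scale `tau` (its density vanishes at
`tau = 0`, so the scale — informed by only a handful of therapies — cannot
collapse and over-shrink every therapy contrast at once; parameter-recovery
studies during development showed exactly that failure mode under a
half-Normal prior). Partial pooling lets a rarely assigned or unseen DMT
borrow strength from the catalogue; predictions for a DMT absent from
training fall back to the pooling distribution and are flagged.

**Sampler.** Affine-invariant ensemble MCMC (`emcee`) with stretch moves,
at least `max(32, 2·ndim+2)` walkers, and defaults of 1600 steps with 1000
burn-in, thinned by 4. Chains are initialized at a maximum-likelihood GLM
estimate (per-DMT intercepts, so the initializer is identified without the
pooling prior) with jitter scaled by the GLM standard errors; a BFGS
optimum of the log posterior is the fallback. The move family was chosen by
calibration against a Laplace approximation of the package's own log
posterior: a differential-evolution/snooker mixture equilibrated with
posterior SDs ~15–20 % below the Laplace/MLE widths on these GLM-like
posteriors (the ensemble spread feeds back into the DE proposal scale),
which degraded parameter-recovery coverage from ~0.85 to ~0.80; stretch
moves reproduce the Laplace widths to within ~1 %.

Convergence is gated on a split R-hat comparing the first and second half
of the post-burn-in period, each flattened across walkers — individual
walkers wander slowly by design in an affine-invariant ensemble and are not
treated as independent chains. The default threshold 1.15 was calibrated so
that healthy fits (measured 1.01–1.03 across seeds, cohort sizes, chain
lengths, and both outcomes) pass while deliberately broken runs (no
burn-in, grossly overdispersed initialization; measured 1.19–1.28) fail. A
fit failing the gate is returned with `converged=False` and a warning;
downstream refit procedures may use shorter chains
(`SamplerSettings.reduced()`) with a proportionally looser gate, because
those refits only feed point estimates.

## 3. Ranking and decision support

For one patient and horizon (24–72 months), the package computes each
catalogue DMT's posterior event-free probability (posterior mean, with a
5th–95th percentile credible interval) for both endpoints and ranks by
decreasing probability; exact ties break by narrower interval, then
catalogue order. Patient preferences *shade* therapies: an excluded DMT
keeps its probability but carries no rank, so the cost of a preference
stays visible. Reports render probabilities as natural frequencies ("73 of
100 patients like you") and attach an additive per-predictor contribution
panel for the top-ranked therapy (posterior-mean coefficient × deviation
from the training reference, with the patient's percentile in the training
distribution).

## 4. Validation

* **C-index**: over all pairs whose observed outcomes differ (counts
  compared as exposure-normalized rates), the fraction where the predicted
  ordering matches; prediction ties score 0.5. The implementation is
  chunk-vectorized and is tested for exact agreement against exhaustive
  pair enumeration.
* **MSE / NLL**: squared error in outcome units and the mean negative log
  posterior-predictive mass of the observed outcomes.
* **Cross-validation**: k-fold with folds split by patient, never by row.
* **Empirical coefficient intervals**: the model is refitted ≥ 20 times
  from random initializations (the data are never resampled — variation is
  attributed to initialization only); each coefficient is summarized by the
  5th–95th percentile of the point estimates. Small spans indicate the data,
  not the initialization, determine the coefficients. Non-convergent refits
  are excluded and counted; > 20 % exclusions fails the run.
* **Growth monitoring**: on a series of accruing data cuts, each cut is
  refitted and compared with the first cut (the reference): in/out-of-sample
  C-index deltas on a fixed evaluation cohort and the median empirical
  interval span. The refit seed stream and performance-fit seed are shared
  across cuts (a paired design), so cut-to-cut changes reflect data growth
  rather than Monte-Carlo noise.

A power analysis of the monitoring statistics under a stationary generator
(documented in the test suite) found the out-of-sample C-index delta to be
signal-dominated only on the steep part of the learning curve (first cuts
of a few hundred rows), while the median-span ratio carries irreducible
percentile-estimator noise of ~15–20 % at 20 refits against a systematic
shrink of only ~5 % per 11 % data growth.

## 5. Clinical-value evaluation

* **Adherence scenarios**: each switch is labelled by whether the assigned
  DMT was in the patient's own top-1 / top-2 / bottom-2 ranking (computed
  from that patient's covariates at their index date). Followers and
  non-followers are balanced with stabilized ATE propensity-score weights
  (logistic propensity on ten baseline characteristics, Hajek-normalized to
  mean 1 per group, clipped at the 1st/99th weight percentiles), with
  standardized mean differences reported before/after. Outcomes are then
  modelled with survey-weighted GLMs — negative binomial with log-exposure
  offset for relapse counts (dispersion from a Pearson-moment auxiliary
  regression), binomial for 3mCDP — using design-robust (HC0 sandwich)
  variance and two-sided p-values. A negative slope on the adherence
  indicator means less disease activity when the recommendation was
  followed.
* **Trial-arm comparison**: for a published arm (DMT, duration, inclusion
  ranges over predictors, published event-free proportion), the package
  filters the registry to the trial-like sub-cohort, predicts each
  patient's event-free probability under the arm's DMT, and compares the
  cohort mean (with a 90 % credible interval) against the published value;
  differences of ≥ 10 percentage points are flagged, and a baseline table
  supports comparability checks. Shipped arm files are illustrative
  examples; published numbers are user-supplied configuration.

## 6. Synthetic registry generator

The generator is the package's study environment and its defaults are the
frozen study conditions: ~0.4 relapses/year at reference covariates, ~10 %
two-year 3mCDP risk, negative-binomial dispersion 1.5, treatment effects
spanning platform to high-efficacy DMTs, and *confounded* therapy
assignment (recent relapse activity and higher EDSS push patients toward
high-efficacy therapy) via a multinomial-logit assignment model whose
covariate dependence can be scaled or switched off. Patient histories
include multi-episode therapy sequences, EDSS trajectories with transient
"blips" that must not count as progression, and lognormal exposure windows.

Two named variants exist for method-calibration studies:
`null_treatment_spec()` (identical treatment effects everywhere — the
induced ranking is uninformative — with confounding retained) and
`informative_ranking_spec()` (widely separated treatment effects and a
raised progression rate, so scenario analyses have working power at
moderate cohort sizes). `sample_switch_records()` draws modelling rows
directly from the outcome models (one row per synthetic patient) for
studies that need many replicates. `recovery_targets()` maps generator
truth onto a fitted model's standardized coefficient scale for
parameter-recovery checks.

## 7. Reproducibility

All randomness flows from explicit integer seeds, forked per stage with a
hash-salted `SeedSequence`, so every CLI artifact and library result is
reproducible given config + seed. Artifacts carry a provenance block
(package version, config hash, seed).

## 8. Limitations

* The synthetic generator is a study environment, not a calibrated model of
  any real registry; absolute effect sizes are illustrative.
* Site structure, time-varying confounding, informative censoring, and
  treatment discontinuation dynamics are not modelled.
* Propensity weighting balances the ten listed baseline covariates only;
  unmeasured confounding is out of scope.
* The ensemble sampler's split R-hat on flattened walkers is an ensemble
  diagnostic, not a multi-chain one; gross non-convergence is caught, slow
  modes shared by all walkers may not be.
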