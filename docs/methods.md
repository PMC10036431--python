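# Methods

This note documents the statistical procedures `pgsrisk` implements, the
tunable parameters and their defaults, what the synthetic-data generator
does and does not emulate, and the numerical and design choices made where
more than one convention exists.

## Polygenic score construction

A polygenic score is the weighted sum of effect-allele dosages,
`PS_i = Σ_v d_iv β_v`, with weights `β_v` equal to the discovery GWAS log
odds ratio.  Before scoring:

* **Harmonization** matches summary-statistic records to the genotype file
  by (chromosome, position, unordered allele pair).  When the summary
  effect allele is the genotype file's *other* allele, the weight is
  negated and the frequency complemented (equivalent to flipping the
  dosage `d → 2−d`).  Palindromic A/T and C/G variants are strand-ambiguous;
  they are dropped when `|EAF − 0.5| < 0.08` (a conventional window,
  configurable) because allele frequency can then no longer resolve the
  strand.  Unmatched and mismatched records are logged in a
  `HarmonizationReport`.  Genome-build liftover is out of scope: records on
  another build surface as unmatched.
* **QC** removes variants with MAF < 0.01 (MAF = min(EAF, 1−EAF)) or
  imputation info < 0.5 — the usual post-imputation filters.
* **Pruning and thresholding** keeps variants with `p < 5×10⁻⁸`
  (genome-wide significance) and greedily selects them in ascending p,
  rejecting a candidate within 500 kb of an already-selected variant on
  the same chromosome whose squared dosage correlation exceeds 0.1.  The
  window and r² cap follow standard P&T practice and are configurable.
  Ties in p break on genomic position, then allele order, making the
  selection invariant to input record order.
* **Standardization** rescales the raw sum to mean 0, SD 1 over the study
  population (or a stated reference subset), so Cox coefficients are log
  hazard ratios *per SD of the score*.  Scores standardized against a
  reference will generally not have SD 1 within a sub-cohort; they are not
  re-standardized there.
* Missing dosages are mean-imputed as `2·EAF` and counted.

**Population-specific scores.**  Two cross-validated variants avoid
in-sample overfitting when weights (or the variant set itself) are
estimated from the target cohort.  `cv_weight_ps` partitions samples into
k = 10 folds; per-variant weights are estimated on the other nine folds
and applied only to the held-out fold, so no person's outcome informs
their own weights.  `cv_variant_ps` (k = 2 by default) additionally ranks
variants by association p-value within each training half and keeps the
top `n_select` (default 287).  The per-variant association model is
univariate logistic regression of event-by-horizon status on dosage
(a vectorised two-parameter Newton solver); a per-variant Cox option
(`model="cox"`) is exposed.  Persons censored before the horizon are
excluded from weight estimation but still scored.  A fold without events
raises an error instructing the caller to reduce k.

**PC residualization** (`residualize_ps`) replaces the standardized score
by its least-squares residual on supplied covariates (e.g. ten genetic
principal components) plus an intercept, re-standardized; rank-deficient
covariate matrices and scores exactly linear in the covariates raise.

## Cox model and Breslow baseline

`CoxPH` maximizes the partial likelihood with the **Breslow** tie
approximation by Newton–Raphson with step-halving (convergence when the
max |score| < 1e-8 or the relative log-likelihood change < 1e-10, at most
50 iterations).  Breslow ties are the default because they are consistent
with the Breslow baseline-hazard estimator used for prediction (and are
the convention of the major commercial survival procedures); the Efron
correction is available via `ties="efron"`.  The Wald covariance is the
inverse observed information.  Coefficients whose magnitude exceeds 15
after convergence, or 40 during iteration, are treated as evidence of a
monotone likelihood (perfect separation) and raise rather than returning a
meaningless estimate — a monotone likelihood flattens out, so separation
can masquerade as convergence.

Covariates are centred at their means before fitting; estimates and
predictions are invariant to the centring (tested), it only stabilises the
exponentials.  The baseline cumulative hazard is the Breslow step function
`H₀(t) = Σ_{t_k ≤ t} d_k / Σ_{j ∈ R(t_k)} e^{lp_j}` over unique event
times, and predicted cumulative incidence by horizon t is
`1 − exp(−H₀(t)·e^{lp})`.  Predicting beyond the last observed time is an
error unless `extrapolate=True`.

**Covariate encoding** (`ModelSpec`): age enters in decades; sex as a
female indicator (reference male); parental diabetes as two indicators per
parent (diabetic, unknown; reference non-diabetic); birthweight as two
indicators, <3000 g and >4000 g (reference 3000–4000 g), reflecting the
U-shaped birthweight–diabetes relationship; BMI (adult), modified BMI z
score (youth), FPG, HbA1c and 2hPG as-is.  Default cohort models: adult
and youth — age, sex, parental diabetes, adiposity, FPG, HbA1c; birth —
sex, parental diabetes, birthweight.  Default horizons: 10 years (adult,
youth), 30 years (birth).

## Horizon status, discrimination, reclassification

At a fixed horizon a person is an **event** (event occurred by the
horizon), **nonevent** (followed beyond the horizon event-free) or
**excluded** (censored before the horizon — status unknown).  Excluding
the censored-before-horizon group is the simplest defensible reading of
classifying events and nonevents at a fixed follow-up; it discards
information and can bias components if censoring is strongly outcome
related, which the synthetic generator's independent censoring does not
produce.

**Harrell's C** counts usable pairs under censoring (the earlier subject
had the event, or tied times with exactly one event); score ties credit
0.5.  The implementation builds ordered-pair indicator matrices once, so a
bootstrap replicate's C is a ratio of quadratic forms in the multiplicity
vector — this makes person-level bootstrap CIs and paired ΔAUC tests cheap
(matrix products instead of per-replicate pair scans).  The fast path is
tested for exact equality against O(n²) pair enumeration.  ΔAUC p-values
use a normal test on the paired-bootstrap SE of the difference by default;
a leave-one-out jackknife variance is available.

**Continuous NRI** for nested predictions is
`[P(up|event) − P(down|event)] + [P(down|nonevent) − P(up|nonevent)]`,
where "up" means the larger model assigns a strictly higher probability;
exact ties count as no reclassification.  The default excludes persons
censored before the horizon from the components; `ipcw_nri` offers an
inverse-probability-of-censoring-weighted variant for settings where the
thinning of events vs nonevents by censoring matters.  Bootstrap CIs
resample individuals, re-deriving horizon status per replicate
(`stratify_by_event=True` resamples within outcome strata); replicates
with no events or no nonevents are dropped and counted (warning above
10%).  The
per-predictor NRI table compares the full model against the model with
that predictor's whole block removed (both indicator columns of a parent,
both birthweight bins), mirroring how per-variable contributions are
reported in incidence studies.

**Decision curves.**  For threshold probability p_t, with x the proportion
with predicted risk ≥ p_t and F the Kaplan–Meier event probability by the
horizon among the selected, net benefit is
`x·F − x·(1−F)·p_t/(1−p_t)` — the survival extension of decision-curve
analysis, which keeps censored individuals in the selected group via the
KM estimate rather than discarding them.  Reference strategies: treat-all
(x = 1, whole-cohort KM) and treat-none (identically 0).  The default
grid is 0.01–0.60 in steps of 0.01.  Selecting nobody yields 0 by
convention.  Marginal benefit of one model over another is reported both
absolutely and as a percentage where the baseline's benefit is positive.

## Cross-cohort HR comparison

Cohorts drawn from one longitudinal study overlap in membership, so their
PS hazard ratios are dependent and cannot be compared with independent-
sample tests.  `bootstrap_hr_difference` resamples *persons* (n_boot =
2000 by default) — a sampled person contributes all their cohort rows, so
the dependence is preserved — refits the unadjusted per-SD Cox HR per
cohort per replicate, and tests the observed log-HR difference against the
bootstrap SD of the replicate differences with a two-sided normal test
(a percentile test is available).  The comparison is unadjusted because
covariate availability differs across cohorts and would confound the
comparison of genetic effects.  The PS keeps its original full-sample
standardization in every replicate, so "per SD" means the same thing in
every cohort and replicate; re-standardizing within replicates would mix
scale changes into the effect comparison.  Replicates in which a cohort
has fewer than two events are dropped and counted (warning above 5%).

## Synthetic-data generator

The generator emulates the *design* of a long-running longitudinal
diabetes study — three overlapping age cohorts with roughly the published
sizes (adult 2333, youth 2229, birth 2894), imputed dosages, external
discovery summary statistics — with the following generative model:

* **Genotypes**: Hardy–Weinberg counts at MAFs uniform on (0.05, 0.5),
  laid on chromosomes 1–22 at 1 Mb spacing; allele pairs uniform over
  distinct bases (so ~1/6 are palindromic, exercising harmonization);
  info scores Beta(5, 1) (median ≈ 0.87, a small tail below the 0.5
  filter). `dosage_noise > 0` perturbs counts into continuous dosages.
* **Summary statistics**: a `frac_causal` subset of variants receives
  N(0, 0.1²) true effects; reported log-ORs add noise with
  `SE = 1/√(2·N·MAF·(1−MAF))` for discovery size N, with Wald p-values.
* **Event times**: Weibull proportional hazards
  `S(t|lp) = exp(−(t/scale)^shape · e^lp)` with shape 1 (exponential) by
  default so closed-form checks exist.  The linear predictor is
  `log(true_ps_hr_per_sd)` × the standardized true PS plus clinical
  covariate terms whose effect sizes match the magnitudes reported for
  incident type 2 diabetes (e.g. FPG HR ≈ 2/mmol/l, maternal diabetes
  HR ≈ 1.5–4 depending on cohort, female HR ≈ 1.2–1.4).
* **Censoring**: an exponential dropout time truncated at an
  administrative horizon.  The real study's dropout process is unknown;
  independent censoring is a modelling choice and is flagged as such.
* **Cohort scales** (chosen once to land near the published cumulative
  incidences of ~27%/10%/15% and then left alone): baseline hazard scale
  35/130/280 years and censoring rate 0.08/0.05/0.03 per year for
  adult/youth/birth, administrative horizons 25/25/50 years.
* **Overlap**: cohorts share a person registry; a configurable fraction of
  each later cohort is drawn from already-registered persons, who keep
  their genotypes (hence PS) across cohorts while covariates and event
  times are cohort-specific.

What it deliberately does **not** emulate: the real cohorts' marginal
covariate distributions or secular trends, family/pedigree structure,
linkage disequilibrium beyond independent variants, and outcome-dependent
dropout.  Passing tests therefore validate the *estimators and their
calibration under the assumed model*, not the field data-quality problems
(relatedness, LD leakage, informative censoring) a real analysis must also
confront.

## Numerical choices and degenerate inputs

* Partial-likelihood exponentials are computed after subtracting the max
  linear predictor (invariant shift).
* Quantile group boundaries use right-closed searchsorted assignment;
  empty deciles raise a degenerate-grouping error; constant predictions
  collapse calibration to a single bin with a warning.
* Zero p-values read from summary-statistic files are clamped to the
  smallest positive float with a warning; OR columns are log-transformed
  with a notice.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configurations reproduce every
  output byte-for-byte, which the test suite asserts via checksums.

## Problem sizes used in the test suite

The simulation-based checks run at the sizes they validate: parameter
recovery uses 200 replicates of n = 2500 adult-like cohorts (true PS HR
1.30/SD); null calibration uses n = 2000 cohorts (50 repeats for NRI CI
coverage) and 100 repeats of paired n = 1500 cohorts at n_boot = 500 for
the HR-difference type-I error; oracle-equivalence checks use 100 random
censored datasets of up to n = 200.  Per-repeat bootstrap sizes inside the
repeated null-calibration loops use a few hundred replicates, which is
ample for percentile CIs at these scales.

## Known limitations

* No time-varying covariates, frailty, competing risks, left truncation,
  or proportional-hazards diagnostics.
* No LD-aware shrinkage scores (clumping + thresholding only), no liftover,
  no meta-analysis of summary statistics.
* NRI excludes persons censored before the horizon by default; the IPCW
  variant corrects for independent censoring only, not outcome-dependent
  dropout.
* The decision-curve KM extension assumes non-informative censoring within
  the selected group.
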