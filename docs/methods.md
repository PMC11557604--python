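# Methods

## The estimation problem

Trauma prevalence in a skeletal sample is the fraction of individuals
carrying at least one traumatic lesion. When remains are incomplete the
observed indicator is right-censored in an unusual way: a specimen scored
"no trauma" may simply be missing the elements that carried its fracture.
The package studies two estimators of cranial trauma prevalence under this
missingness, on a per-specimen summary record
`(sample ∈ {A, B}, completeness ∈ [0, 100]%, trauma ∈ {0, 1})`:

* **Crude frequency (CF).** Proportion of traumatized specimens among those
  with completeness at or above a threshold (default 75 %, the most common
  convention in cranial trauma studies); specimens below the threshold are
  excluded together with their trauma observations. When no specimen
  passes, the estimate is *undefined* — a real outcome the evaluation
  tracks, not an error.

* **Binomial GLM with log link.** `log E[trauma] = β₀ + β₁·[sample=B] +
  β₂·completeness`, fitted to all specimens jointly. The log link makes
  coefficients act multiplicatively on prevalence, which is the natural
  scale for a rate; completeness enters on its raw percent scale (0–100),
  uncentered, so `exp(β₀ + 100β₂)` is sample A's prevalence at full
  completeness. Prevalence per sample is *predicted*, not read off a
  single coefficient: 10,000 coefficient vectors are drawn from the
  asymptotic sampling distribution `MVN(β̂, V̂)`, the inverse link is
  evaluated on a completeness grid (75–100 % in steps of 1, aligning the
  GLM with the CF threshold), each draw's grid values are averaged, and
  the mean of those per-draw averages (×100) is the point estimate. The
  2.5th/97.5th percentiles of the per-draw averages give a 95 %
  compatibility interval. Predictions are clipped at 1 before averaging
  (`clip_predictions=True`), since the log link can exceed it.

The estimator pair is exposed statsmodels-style: `PrevalenceGLM` (model) →
`fit()` → `PrevalenceGLMResults` (coefficients, covariance, `summary()`,
`predict_prevalence()`, `diagnostics()`).

### Fitting ladder

Log-link binomial fits are fragile (the mean must stay below 1 on the
data's support). `fit()` therefore tries, in order: (1) a plain IRLS fit;
(2) an IRLS fit restarted from intercept-seeded start values
(β₀ = log ȳ, slopes 0); (3) a logit-link fallback, flagged as
`fallback_used` on the results and counted per scenario by the harness.
If all rungs fail (in practice only for an all-zero/all-one response) a
`ModelFailure` is raised; the harness records the iteration as a model
failure instead of aborting. A non-positive-definite coefficient
covariance is repaired by eigenvalue clipping before parameter drawing and
flagged (`cov_repaired`).

### Model assessment

`PrevalenceGLMResults.diagnostics()` returns randomized quantile residuals
(uniform under a well-specified binary model, with a KS p-value) and a
small posterior-predictive check of per-sample prevalence. It is a report,
not a gate: the simulation harness fits thousands of models and cannot
inspect them interactively.

## The simulation framework

### Cranial schema and trauma pool

A simulated cranium is a vector of 48 recording elements: 14 bones
(frontal, occipital, paired parietal, temporal, maxilla, zygomatic, nasal,
mandible), four regions per bone except two for each nasal and zygomatic.
Region semantics (which region is "mandibular body", "zygomatic arch",
etc.) are documented in `anatomy.py` and used consistently by the trauma
fixture.

Trauma is assigned by drawing, uniformly **with replacement**, from a pool
of 40 real-life blunt-force cranial injury cases (sports accidents, animal
encounters, falls from a height, clinical cases, arrow wounds,
interpersonal violence), each recorded as a 48-element binary vector. With
replacement matters: extensive multi-element fractures are more likely to
survive attrition, and resampling keeps their expected share constant.
Severity spans 1 to 34 injured elements (211 in total across the pool).
The shipped fixture (`data/trauma_pool.csv`) reconstructs each case's
element vector from its verbal fracture description and published
injured-element count; the counts and affected bones are exact, the choice
of region within a bone follows the documented conventions. The CSV is
editable and revalidated on load (pool size 40, per-case count match,
element names) so refined vectors can be dropped in.

A generated sample of size n with prevalence p contains **exactly** n·p/100
trauma specimens (the benchmark is a design constant, not a binomial draw);
non-integer products are rejected.

### Missingness

Each specimen independently loses
`round(clip(Normal(mean, sd), 0, 100) / 100 × 48)` elements
(half-away-from-zero rounding; elements are atomic). Scenario means are
20/40/60/80 %, sd 20. Clipping shifts the realized mean (at mean 80, sd 20
roughly 17 % of specimens clip to 100 % missing and the realized mean falls
below 80); `prob_completeness_at_least()` provides the exact clipped-normal
pass probability used by the analytic cross-checks.

Which elements vanish is decided by weighted sampling without replacement.
Weights derive from per-bone *effective sample sizes* (ESS): counts of
preserved elements per completeness category (0.25/0.5/0.75/1) weighted by
the category score — a fractional-count measure of how much each bone
typically contributes to a fragmentary assemblage. The default transform is
inverse proportionality (weight ∝ 1/ESS, shared by all elements of a bone,
normalized); `max_minus` and `rank` transforms are available since only the
monotone direction, not the functional form, is dictated by the underlying
idea. The shipped ESS fixture encodes the qualitative representation
ranking of an Upper Paleolithic cranial assemblage — mandible, frontal and
parietals well represented; nasals and zygomatics poorly — with magnitudes
chosen once to be realistic for a few dozen crania; only the ratios matter.

The without-replacement scheme is successive weighted draws with
renormalization after each draw, implemented via exponential race keys
(`key_i ~ Exp(w_i)`, remove the k smallest), which is distributionally
identical and vectorizes over a whole sample. The test suite checks it
against exhaustive enumeration of the successive-draw process on a
6-element schema and against simple random sampling for uniform weights.

Surviving elements keep their trauma state, so a multi-element fracture can
be partially preserved. A specimen that loses everything has completeness
0 % and (vacuously) trauma 0.

**0 %-complete specimens are excluded from estimation by default**
(`drop_empty_specimens=True`). An unobservable specimen contributes no
trauma observation — scoring it as a trauma-free data point at
completeness 0 injects fabricated zeros into the GLM and steepens the
completeness slope, inflating 75–100 % predictions noticeably in the 80 %
scenario. Retention is available via the flag for sensitivity analysis.
Raw-prevalence bookkeeping (below) always uses all specimens.

### The factorial experiment

`Experiment(config).run()` executes sample sizes × scenarios × iterations
(defaults: n ∈ {500, 100} run separately, scenarios 20/40/60/80, 1000
iterations). Per iteration: generate A (10 %) and B (30 %), apply
missingness, summarize, estimate with CF and GLM. Per scenario the summary
reports, over iterations:

* median and 95 % interpercentile range of each estimator × sample, over
  **defined** estimates only (linear interpolation between order
  statistics; the convention is far inside the reported tolerances);
* production: percentage of iterations yielding a defined estimate;
* zero share: percentage of estimates exactly 0, reported under both
  denominators — share of defined estimates and share of all iterations
  (the defined-denominator version is the headline number);
* correct-pattern: percentage of iterations with strictly
  estimate(A) < estimate(B), with **all iterations** as denominator;
  undefined estimates and ties count as incorrect. This is the only
  denominator consistent with the observed co-occurrence of ~29 % pattern
  maintenance and ~81 % production in the harshest large-sample scenario.

`verify_raw_pattern()` confirms that the post-missingness raw data retain
prevalence > 0 and A < B in every iteration (vacuous and flagged if the
configured benchmarks are equal) — so every CF pathology is attributable to
thresholding, not to the generated data.

### Reproducibility

All randomness flows through numpy Generators. Each (scenario, iteration)
cell gets a child `SeedSequence(entropy=seed, spawn_key=(scenario·100,
iteration))`, so any single iteration can be replayed in isolation and
iteration-level parallelism could not change results. The CLI `run`
command writes a manifest (full config echo, seed, SHA-256 fixture hashes,
package version, per-scenario fallback/failure counts) sufficient to
reproduce a run byte-for-byte.

## Problem sizes and runtime

One iteration (two n = 500 samples, GLM fit, 10,000-draw prediction) costs
≈ 15–20 ms, so every evaluation cell — including those behind the
acceptance script — runs at the full scale of 1000 iterations; the
acceptance script's three cells complete in a couple of minutes on one
CPU. The test suite runs the same scales where a published number is
checked and much smaller configurations for mechanics.

## What the generator does and does not emulate

It emulates: realistic injury topographies and severity mix; differential
bone survival; heteroscedastic per-specimen preservation; partial fracture
survival; exact known benchmarks to judge estimators against.

It does not emulate: spatially correlated breakage (adjacent elements lost
together), specimen-level taphonomic covariates, healed-versus-perimortem
distinction, post-cranial elements, or observation error in trauma scoring.
Passing results therefore speak to the effect of *amount and bone-level
pattern* of missingness on the two estimators, not to every failure mode of
real assemblages. Because the element-level trauma vectors and ESS
magnitudes are reconstructions, published summary statistics are matched
within tolerances (±1.5 percentage points for medians, ±5 for percentages)
rather than exactly.

## Known limitations

* The log-link GLM overestimates prevalence at high missingness (extrapolating
  to 75–100 % completeness from data concentrated far below); predicting over
  50–75 % (`GLMConfig(predict_range=(50, 75))`) lowers estimates while
  preserving relative patterns. Absolute predictions from largely incomplete
  samples should not be taken at face value.
* The logit fallback changes the link for the affected iteration; its rate is
  reported per scenario and is zero in the default scenarios in practice.
* CF's undefined outcome and its zero-inflation are intrinsic to thresholding;
  the framework measures them rather than patching them.
* No mixed-effects extension (repeated observations per individual) and no
  between-sample hypothesis testing: the scope is estimation performance.
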