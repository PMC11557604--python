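# traumasim

Estimating trauma prevalence from incomplete human skeletal remains, and
quantifying how badly incompleteness distorts those estimates.

Bioarchaeologists report cranial trauma prevalence as the percentage of
affected individuals in a sample, but skeletal assemblages are rarely
complete: once-present fractures can be missing along with the bone that
carried them. The conventional remedy — restricting the sample to specimens
above a minimum completeness threshold (crude frequencies, CF, typically
≥ 75 % complete) — discards data and can break down entirely in poorly
preserved samples. An alternative keeps every fragment and models trauma
presence with a binomial generalized linear model (GLM) that carries
specimen completeness as a covariate.

`traumasim` provides both estimators for real per-specimen data **and** a
Monte-Carlo framework that measures how each behaves as completeness
decays. Simulated crania are 48-element vectors (14 bones, four regions
each, two for the small nasal and zygomatic bones). Two samples with known
trauma prevalence (benchmarks 10 % and 30 %) are built by drawing injury
patterns from a pool of 40 real-life blunt-force trauma cases (falls,
animal encounters, interpersonal violence, arrow wounds). Missing data are
then introduced per specimen: a normal draw (mean 20/40/60/80 %, sd 20,
clipped to [0, 100]) fixes how many elements vanish, and weighted sampling
without replacement — weights inversely proportional to each bone's
effective sample size in a fragmentary reference assemblage — decides which
ones, so nasals and zygomatics vanish more readily than vault bones or
mandibles.

The two estimators on a per-specimen record `(sample, completeness %, trauma 0/1)`:

- **CF**: `100 · #(trauma ∧ completeness ≥ 75 %) / #(completeness ≥ 75 %)`;
  undefined if no specimen passes.
- **GLM**: trauma ~ Binomial, `log E[y] = β₀ + β₁·[sample = B] + β₂·completeness`.
  Prevalence is predicted by drawing 10,000 coefficient vectors from the
  asymptotic normal `MVN(β̂, V̂)`, evaluating `exp(η)` over the 75–100 %
  completeness grid, and averaging; the 2.5th/97.5th percentiles of the
  per-draw means give a 95 % compatibility interval.

## Worked example

Evaluate both estimators at 60 % mean missingness with small samples
(n = 100 per sample, 200 iterations):

```python
from traumasim import Experiment, ExperimentConfig, GLMConfig

cfg = ExperimentConfig(n_per_sample=100, scenarios=(60.0,), iterations=200,
                       seed=42, glm=GLMConfig(n_param_draws=2000))
results = Experiment(cfg).run()
summary = results.summary()
print(summary.estimates.round(2).to_string(index=False))
print(summary.pattern.round(1).to_string(index=False))
```

```
 scenario estimator sample  median  ipr_lo  ipr_hi  pct_produced  pct_zero_of_defined  pct_zero_of_iterations
     60.0        CF      A    0.00    0.00   50.00          99.5                61.81                    61.5
     60.0        CF      B   25.00    0.00  100.00          99.0                27.27                    27.0
     60.0       GLM      A   13.07    5.08   28.58         100.0                 0.00                     0.0
     60.0       GLM      B   37.38   16.69   71.32         100.0                 0.00                     0.0

 scenario estimator  pct_correct_pattern
     60.0        CF                 58.5
     60.0       GLM                100.0
```

Reading this: at 60 % mean missingness the CF median for sample A has
collapsed to 0 % (62 % of its defined estimates are exactly zero, even
though the generated data never are), its 95 % interpercentile range spans
half or all of the scale, and it recovers the true ordering A < B in only
58.5 % of iterations. The GLM always produces a positive estimate, its
medians (13.1 / 37.4) bracket the 10 / 30 benchmarks more tightly, and it
preserves the ordering in every iteration — at the price of a mild upward
bias that grows with missingness.

Fitting the model directly on one per-specimen table follows the
statsmodels idiom:

```python
from traumasim import PrevalenceGLM
res = PrevalenceGLM.from_dataframe(records).fit()   # columns: sample, completeness, trauma
print(res.summary())
est = res.predict_prevalence()
```

```
Binomial GLM for trauma prevalence
link: log
n specimens: 197   converged: True
                coef  std err       z   P>|z|
intercept    -2.9984   0.5431 -5.5211  0.0000
sample_B      0.8963   0.3715  2.4130  0.0158
completeness  0.0135   0.0091  1.4757  0.1400
```

`est["A"].point` / `est["B"].point` then hold the draw-averaged prevalence
predictions with their compatibility intervals.

## Command line

```sh
traumasim run --out out/ --n 100 --scenario 80 --iterations 200 --seed 7
traumasim estimate --input specimens.csv --threshold 75 --draws 10000
traumasim validate-fixtures          # check edited pool / ESS CSVs
traumasim make-pool-template --out fixtures/
```

`run` writes the summary tables (`medians.csv`, `pattern.csv`,
`production.csv`), a long per-iteration CSV for sina-style plots, a raw-data
ordering check, a log with GLM fallback counts, and a JSON manifest (config,
seed, fixture hashes) sufficient to replay the run exactly.

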