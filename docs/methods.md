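# Methods

## The question and the experimental design

An epigenetic clock is a penalized linear regression of chronological age
on CpG methylation beta values. When the calibration animals' recorded
ages carry error, that error propagates into the clock. `clocktol`
measures the propagation by a controlled simulation:

1. **Partition.** Samples are split once into 70% training / 30% test
   (the split fraction and the random seed live in `SplitSpec`). The test
   partition and its ages are frozen for the rest of the experiment; an
   invariant test asserts they are byte-identical across all error
   levels.
2. **Baseline.** A clock is calibrated on the exact training ages and
   evaluated on the test partition (Pearson r, mean absolute error in age
   units, mean relative error in percent of each individual's true age).
3. **Error sweep.** For each level x in a grid (default 1..100% step 1),
   each repetition draws fresh perturbed training ages
   `a·(1 + u), u ~ U(−x/100, x/100)` independently per sample, refits the
   clock from scratch — site selection is data-driven on every fit, never
   restricted to the baseline's sites — and evaluates on the frozen test
   partition. Default 10 repetitions per level.
4. **Detection.** Per level, the per-sample test errors pooled across
   repetitions are compared with the baseline's pool by a two-sample
   t-test (absolute and relative errors) and by Cohen's d (absolute
   errors). The report gives the first grid level at which p < 0.05 and
   at which d > 0.2, plus an OLS line of d against x and its inversion at
   any effect-size target.
5. **Aggregation.** Across several datasets sharing a grid, per-level d
   values are averaged and a single line fitted to the means.
6. **Sample-size control.** `subsample_experiment` reruns the sweep on a
   random subset of a larger cohort to ask whether the detected threshold
   depends on n.

## Model and fitting choices

- **Elastic net, α = 0.5.** Equal L1/L2 mixing; sparsity comes from the
  L1 part, stability under correlated CpGs from the L2 part. Fitting is
  delegated to scikit-learn's `ElasticNetCV`.
- **Penalty strength.** Chosen on a log-spaced path of 20 candidates by
  internal 10-fold cross-validation minimising mean squared prediction
  error (the minimum-MSE rule, not the one-SE rule). Coordinate-descent
  tolerance 1e-3, max 2000 iterations.
- **Standardisation.** Features are centred and scaled to unit variance
  before penalisation; coefficients are reported back on the beta scale.
  Zero-variance sites are dropped from fitting; if all sites are
  constant the fit degenerates to an intercept-only model (mean training
  age) with a warning.
- **Split rounding.** Train count = round(n × fraction), halves up —
  e.g. 63 samples at 0.7 give 44/19. Fixed for reproducibility.
- **Predictions** are never clamped; negative predicted ages are
  reported raw with a warning, because clamping would silently bias the
  relative-error metric.
- **Error metrics.** "Absolute error" is the MEAN of per-sample
  |pred − true| and "relative error" the mean of |pred − true|/true×100;
  medians and a range-normalised relative error are available behind
  flags, since either convention appears in the clock literature.

## Statistical choices

- **t-test.** Student's pooled-variance test by default: it shares its
  variance assumption with the pooled-SD Cohen's d it accompanies. Welch
  is available behind a flag. Degenerate zero-variance inputs resolve
  explicitly (equal constants → p = 1; distinct constants → p = 0 with a
  warning) rather than returning NaN.
- **Cohen's d sign convention.** d = (perturbed − baseline)/pooled SD,
  so degradation is positive.
- **Pooling.** t-tests and d use per-sample test errors pooled across a
  level's repetitions (higher power); a mode using the per-repetition
  mean errors exists behind `pooled_tests=False`.
- **Threshold reporting.** First grid crossing by default; a "sustained
  crossing" option requires k consecutive levels, for noisy p-value
  trajectories. Both the real-valued inversion of the effect-size line
  and its nearest-integer percent are reported.
- **No multiple-testing correction** is applied across the 100 levels;
  the per-level tests are descriptive instruments for locating a
  threshold, not a family of confirmatory hypotheses.

## Error injection

Uniform on the symmetric interval is the maximum-entropy distribution on
the stated support ("up to x%, either direction"); any other bounded
sampler can be passed via the `draw` hook. Levels above 100% are
rejected because they could produce negative ages. Noise is drawn fresh
per repetition by default (`redraw_per_repetition=False` shares one draw
per level) — each level is an independent experiment, not a cumulative
walk. A hard invariant, property-tested across levels and seeds: no draw
ever violates the ±x% bound, and E|Δa|/a = x/200.

## Synthetic data generator

The generator emulates normalised methylation matrices with known ages:

- **Profiles.** Four named profiles carry the sample sizes and age
  ranges of published calibration cohorts (human whole blood 394,
  16–88 y; zebrafish caudal fin 96, 11.9–60.1 wk; mouse multi-tissue
  153, 1–31 wk; green turtle skin 63, 1–43 y), plus a desk-scale default
  (n = 150, 16–88 y). Ages are drawn uniformly over the range — the real
  cohorts' age distributions are unpublished, and uniform is the
  simplest cover of the printed ranges.
- **Signal.** Informative site j follows
  `beta = clamp(b0_j + s_j·(age − age_min)/(age_max − age_min) + ε, 0, 1)`
  with `s_j = ±slope_magnitude` (half increasing, half decreasing with
  age by default — methylation drifts in both directions over a
  lifetime), `b0_j ~ U(0.1, 0.5)` and Gaussian beta-scale noise
  `ε ~ N(0, 0.05²)`. Defaults: 100 informative + 900 noise sites, slope
  0.4. Gaussian-with-clamping was chosen over a beta-distributed noise
  model for transparent variance control; it is swappable.
- **What it does not emulate.** Array/platform artifacts, batch effects,
  tissue heterogeneity, sex and population structure, and the empirical
  correlation structure of real CpG panels. Consequently, passing tests
  show the *pipeline* behaves correctly under a known ground truth, not
  that any particular real cohort reproduces the published real-data
  table values — those require the external datasets.
- **A known divergence.** On real data the number of selected CpGs falls
  sharply at 100% injected error; on this generator it rises. The
  CV-selected penalty does increase with label noise, but the
  generator's informative sites are strongly inter-correlated, and the
  elastic net then spreads many small nonzero coefficients instead of
  zeroing them. This is a property of the synthetic correlation
  structure, and the site-count direction is therefore not asserted.

## Problem sizes in the test suite

The shipped experiments are sized for a single-CPU desk run: unit tests
use cohorts of 60–200 samples with 200–1000 sites; the degradation and
null checks use the default cohort (n = 150, 1000 sites) with 3–20
repetitions per level depending on the check; the
sample-size-independence experiment compares an n = 394 cohort with its
n = 96 subsample on a 150-site panel over the reduced grid (levels
5..100 step 5, 5 repetitions, 10 seeds). The full 1..100 × 10 grid is a
configuration away (`SweepConfig()` defaults).

## Numerical and testing notes

- All randomness flows from a single master seed through
  `SeedSequence([master, level_index, repetition])`; levels are
  independent and individually resumable, and per-level checkpoints
  (JSON) let interrupted 100-level sweeps resume.
- Dataset TSV round-trips are exact: betas are written at 17 significant
  digits and parsed with round-trip float precision.
- Oracle tests compare every statistical primitive against independent
  brute-force implementations (element-wise loops, normal equations,
  textbook t and pooled-SD formulas, exhaustive permutation). The
  permutation comparison uses per-group sizes 6–8, where the exact
  distribution (≥ 924 atoms) is fine enough to compare against a
  continuous reference, with mid-p for ties and an agreement tolerance
  of 0.15; at sizes 3–5 the permutation distribution has as few as 10
  atoms and genuinely differs from Student's t, so no meaningful
  tolerance exists there.

## Known limitations

- Homoscedastic, unbiased age error only; no systematic bias, no
  sample-specific error models.
- Linear clocks only; no log-linear juvenile age transformation.
- The generator's uniform ages and linear signal make the synthetic
  clocks more accurate than real ones (baseline r ≈ 0.999 vs ≈ 0.97 on
  real cohorts), so absolute effect sizes at a given error level are
  larger than the published real-data curves; directional and null
  properties are the meaningful comparisons.
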