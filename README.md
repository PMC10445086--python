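# clocktol

How much error in the chronological ages of calibration samples can an
epigenetic clock tolerate before its predictions degrade measurably?

Epigenetic clocks predict age from DNA methylation: a sparse linear model
`age = b0 + Σ_j w_j β_j` over CpG beta values, fitted by elastic-net
regression (mixing parameter α = 0.5) with the penalty strength chosen by
10-fold cross-validation. For wildlife species, exactly aged calibration
animals are rare, so training ages often carry error. `clocktol`
quantifies the consequence: it injects bounded symmetric relative error
into the *training* ages only — at level x%, each age a becomes
`a·(1 + u)`, `u ~ Uniform(−x/100, +x/100)` — refits the clock at every
level from 1% to 100%, and compares test-partition errors against the
exact-age baseline with three instruments:

1. unpaired t-tests on per-sample absolute and relative errors (p < 0.05);
2. Cohen's d, `d = (mean(perturbed) − mean(baseline)) / pooled SD`, read
   against the conventional anchors d = 0.2 / 0.5 / 0.8;
3. an OLS line `d(x) = b + m·x` of mean effect size against error
   percentage, invertible to report the level at which a target effect
   size is first predicted.

Because the real calibration cohorts (human, zebrafish, mouse, green
turtle) require external downloads, the package ships a synthetic-data
generator whose named profiles reproduce their sample sizes and age
ranges (394 / 96 / 153 / 63 samples), with a minority of CpG sites whose
methylation drifts linearly with age and a majority of age-independent
sites. Everything downstream is testable on those synthetic cohorts.

Audience: researchers building or stress-testing age-prediction models
from methylation data, and anyone deciding whether an imperfectly aged
calibration population is good enough to bother with.

## Worked example

```python
from clocktol import (DEFAULT_PROFILE, DEFAULT_SIGNAL, SplitSpec, SweepConfig,
                      detect_thresholds, generate_dataset, run_error_sweep)

dataset = generate_dataset(DEFAULT_PROFILE, DEFAULT_SIGNAL, seed=1)
config = SweepConfig(levels=tuple(range(10, 101, 10)), repetitions=3,
                     split=SplitSpec(seed=1), master_seed=1)
report = detect_thresholds(run_error_sweep(dataset, config))
print(report.first_small_effect, report.effect_size_model.slope)
```

Running `python examples/02_fit_clock.py` prints

```
selected CpG sites: 98 of 1000
test-set Pearson r: 0.999
mean absolute error: 0.90 years
mean relative error: 2.0 %
```

meaning the elastic net selected 98 of the 1000 sites and, calibrated on
exact ages, recovers the planted linear age signal almost perfectly on
held-out samples. `examples/03_error_sweep.py` then shows the same clock
degrading as training-age error is injected, with the first detection
thresholds and the fitted effect-size line; `examples/04_threshold_model.py`
inverts the published line d = (1.176x − 5.493)/100, whose small-effect
crossing is 21.68% → 22%.

The same pipeline is scriptable from the shell:

```bash
clocktol simulate --profile turtle --seed 1 --out data/turtle
clocktol sweep data/turtle --out runs/turtle
clocktol report --out runs/turtle
```

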