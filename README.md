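# suvvar

Statistical technical variation of PET SUV metrics from a single
acquisition.

When an SUV changes between two PET studies, part of that change is
irreducible noise from radioactive-decay counting statistics.  `suvvar`
quantifies that component — per SUV metric and per lesion size — by
partitioning one list-mode acquisition of length T into subsets of
statistically independent shorter frames, measuring SUVMax, SUVMean and
SUVPeak in every frame, and extrapolating each subset's coefficient of
variation to the full reconstruction length with the inverse-square-root
law

    CoV% = 100 · SD / mean,        SD₂ = SD₁ · √(RL₁ / RL₂),

where RL is the reconstruction length of a frame.  The fourteen default
subsets (RL = 4…30 s of a 150 s acquisition) give fourteen independent
estimates of the full-length CoV; their mean and spread are the result.

It is aimed at medical physicists characterising a scanner/reconstruction
combination (e.g. on a six-sphere image-quality phantom) and at anyone who
needs to know whether an observed SUV change exceeds the counting-noise
floor.  A built-in phantom simulator generates frames with calibrated
Poisson count noise, so the whole pipeline runs and is testable without
scanner data; externally reconstructed NIfTI frame stacks are analysed
through the same code path.

## Worked example

```python
import suvvar

# simulate the default phantom study (150 s, 14 subsets) and fit
model = suvvar.SUVVariationModel.from_simulation(seed=1)
results = model.fit()
print(results.summary())
```

```
Estimated coefficient of variation of SUV metrics
target reconstruction length: 150 s; 14 source subsets; alpha=0.05

metric           10 mm         13 mm         17 mm         22 mm         28 mm         37 mm
Max2D       4.8 ± 1.3%    4.2 ± 1.0%    3.9 ± 1.1%    3.0 ± 0.9%    2.3 ± 0.5%    2.3 ± 0.7%
Max3D       4.1 ± 1.3%    3.9 ± 0.8%    3.3 ± 1.0%    2.4 ± 0.3%    2.0 ± 0.6%    1.6 ± 0.6%
Mean2D      4.8 ± 1.2%    3.3 ± 0.8%    2.7 ± 0.7%    1.9 ± 0.4%    1.6 ± 0.3%    1.1 ± 0.3%
Mean3D      3.9 ± 1.0%    3.0 ± 0.9%    2.2 ± 0.5%    1.3 ± 0.2%    1.1 ± 0.2%    0.6 ± 0.2%
Peak        3.4 ± 1.1%    3.5 ± 1.1%    3.4 ± 0.9%    3.1 ± 1.2%    2.3 ± 0.5%    2.3 ± 0.7%

pairwise Welch tests: 51/85 significant at alpha=0.05
```

Each cell is the mean ± SD of the fourteen per-subset extrapolations of
the CoV to 150 s.  Reading it: at a routine 150 s reconstruction the
counting-statistics noise floor of SUVMax for a 10 mm sphere is ≈ 5%,
falling to ≈ 2% for a 37 mm sphere, and volume averaging makes SUVMean3D
the quietest metric; at RL = 4 s the same CoV is √(150/4) ≈ 6 times
larger (~25–30% for the smallest sphere), which is no longer negligible
against clinical decision thresholds.  The Welch line counts which
sphere-size and metric differences in those populations are significant.

`results` also exposes `cov_table` (CoV per metric × sphere × RL),
`cross_estimates()` (13 leave-one-out estimates per target RL),
`comparisons()`, `normality_report()` and plotting helpers
(`plot_cov_vs_rl`, `plot_estimates`).

The same analysis from the shell:

```bash
suvvar run --seed 1 --out-dir run/           # simulate + analyse + report
suvvar simulate --out-dir frames/ --seed 1   # write NIfTI frames + sidecars
suvvar metrics frames/ --out metrics.csv     # measure an external frame stack
suvvar estimate metrics.csv                  # fit on an existing table
```

`suvvar run` writes tidy CSVs (metrics, CoV table, estimates,
cross-estimates, recovery curve, comparisons), a text summary and a
reproducibility manifest; identical config + seed reproduce every file
bit-for-bit.  Phantom geometry, grid, noise, schedules and analysis
options are configurable through a single YAML file (`--config`).

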