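# chronowear

Chronotype and social-jetlag analysis of wearable-device sleep records.

Consumer wearables now log sleep onset, wake time, wake after sleep onset
(WASO), daytime naps and step counts for whole populations, night after
night. `chronowear` turns such longitudinal records into the standard
chronobiology statistics used in large-cohort sleep epidemiology, and
ships a calibrated synthetic-cohort generator so every stage of the
pipeline can be exercised and validated without access to proprietary
device data.

## What it computes

For each subject, from one row per subject-night:

- **Mid-sleep point** — the clock time halfway between sleep onset and
  final awakening (e.g. onset 00:00, wake 08:00 → 4:00 am). All clock
  arithmetic happens on a *noon-anchored night axis* (hours since 12:00
  noon of the evening the night begins), which removes the midnight
  wrap-around.
- **MSW / MSF** — mean mid-sleep on work nights (Sunday–Thursday
  evenings) and free nights (Friday/Saturday evenings).
- **Social jetlag** — SJL = MSF − MSW, signed; negative SJL means
  earlier mid-sleep on free days.
- **MSFsc** — chronotype as mid-sleep on free days corrected for the
  sleep debt accumulated over the work week:

  ```
  MSFsc = MSF − 0.5 · [SDf − (5·SDw + 2·SDf) / 7]
  ```

  where SDw and SDf are mean nocturnal sleep durations (time in bed
  minus WASO) on work and free nights. MSFsc is evaluated per complete
  Sunday-anchored week (5 work + 2 free nights) and averaged over weeks
  (at least 2 by default).
- **Chronotype class** — early (MSFsc < 3:00), intermediate (3:00–5:00),
  late (> 5:00); **nap group** — zero / short (≤ 30 min) / long
  (> 30 min) mean daily nap.

At the cohort level it reproduces the canonical analysis battery:
exclusion filters (mean nocturnal sleep 3–13 h, age 10–90, BMI
10–50 kg/m², ≥ 7 consecutive nights), SJL tail fractions (P(SJL > 1 h),
P(SJL < 0)), the chronotype composition of the negative-SJL subset,
descriptive tables by sex/day-type/nap group, Pearson correlations,
Welch t tests, OLS regressions of SJL on nap and nocturnal durations,
and a random-forest model (trees 10–50, depth 2–5, 5-fold CV grid
search) reporting unit-sum relative feature importances for sex, age,
BMI, exercise (daily steps), nocturnal sleep and nap duration.

## Worked example

```python
import chronowear as cw

sim = cw.simulate(cw.SimConfig(n_subjects=2000, n_weeks=4, seed=42))
summaries = cw.build_summaries(sim.records, sim.subjects)
report = cw.summarize_cohort(summaries, sim.subjects)
print(report.tables["fractions"].to_string(index=False))
```

```
        metric  numerator  denominator    value
   p_sjl_gt_1h        189         2000 0.094500
    p_sjl_lt_0        599         2000 0.299500
      p_napper       1886         2000 0.943000
       p_early        454         1784 0.254484
p_intermediate       1005         1784 0.563341
        p_late        325         1784 0.182175
```

Reading: 9.5 % of the 2000 simulated subjects have more than one hour of
social jetlag and 30 % have negative SJL; 94 % nap. Of the 1784 subjects
with a defined chronotype (≥ 2 complete weeks and known age), 25 % are
early and 18 % late types. Comparing the pipeline estimates with the
generator's latent per-subject truth:

```python
print(cw.recover(sim.truth, summaries).round(4).to_string(index=False))
```

```
quantity    n    bias   rmse  rank_corr
   msfsc 1784 -0.0016 0.1644     0.9905
     sjl 2000 -0.0008 0.1447     0.9595
```

i.e. four weeks of nightly records estimate each subject's chronotype
with ≈ 10 minutes RMSE and essentially no bias.

The same pipeline runs from the shell:

```bash
chronowear simulate --seed 42 --n-subjects 2000 --n-weeks 4 -o data/
chronowear analyze data/ -o report/
```

`analyze` writes the per-subject `summary.csv`, the exclusion ledger,
and the cohort report tables (fractions, descriptives, schedule means,
histograms, correlations, tests, regressions, feature importances) plus
a JSON manifest that fully records the run configuration.

## Documentation

`docs/methods.md` describes the statistical model, the calendar and
time conventions, the synthetic-cohort generator and its calibration,
and the package's known limitations.
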