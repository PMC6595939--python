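# Methods

## Scope and data model

`chronowear` analyses longitudinal sleep records as produced by
consumer wearables: one row per subject-night carrying the evening's
calendar date (`anchor_date`), clock times of nocturnal sleep onset and
final awakening, minutes of wake after sleep onset (WASO), total
daytime nap minutes for that calendar day, and a daily step count; plus
a subject table with age, sex and BMI. Device-internal sleep/wake
staging is out of scope — the package starts from staged onset/wake
times.

## Time and calendar conventions

**Night axis.** Every nocturnal timestamp is mapped to decimal hours
since 12:00 noon of the anchor date. A physiologically plausible
nocturnal episode then lies in a single (0, 24) window with
onset < wake, so means of clock times are ordinary arithmetic means on
this axis and no circular statistics are needed; circular means would
differ only for degenerate schedules that the exclusion filters remove.
Conversion back to clock hours after midnight is `axis − 12 (mod 24)`.

**Work and free nights.** A night is *free* when its anchor date is a
Friday or Saturday, *work* otherwise (Sunday–Thursday evenings). Weeks
are anchored on Sunday nights, so a *complete week* is 7 consecutive
recorded nights containing exactly 5 work and 2 free nights. Any 7
consecutive anchor dates contain exactly 2 free nights.

## Per-subject statistics

- Mid-sleep of a night: `((onset + wake)/2 − 12) mod 24` on the night
  axis — WASO is ignored for mid-sleep because the mid-point is defined
  purely by onset and final awakening; WASO is subtracted only from
  durations.
- Nocturnal sleep duration of a night: time in bed minus WASO.
- MSW, MSF: means of nightly mid-sleep values over work/free nights;
  SDw, SDf: mean nocturnal durations over work/free nights (hours).
- SJL = MSF − MSW, signed. Subjects lacking either night type have no
  SJL and drop out of the SJL analyses.
- Weekly MSFsc: within each complete week,
  `MSF − 0.5·[SDf − (5·SDw + 2·SDf)/7]`, applied unconditionally (also
  when SDf < SDw; the conditional variant used in some questionnaire
  traditions is deliberately not applied — the correction is taken
  exactly as written). The formula is evaluated in the algebraically
  identical form `MSF − (5/14)(SDf − SDw)` so that SDf = SDw leaves MSF
  unchanged to machine precision. Subject MSFsc is the mean of weekly
  values, requiring ≥ 2 complete weeks by default (configurable), plus
  a known age — subjects without age stay in the SJL cohort but not in
  the chronotype cohort, mirroring the two-cohort structure typical of
  these studies.
- Chronotype cut-offs: early < 3:00, late > 5:00, intermediate
  otherwise; both boundary values (3.0 and 5.0) fall to intermediate
  because the outer classes are defined by strict inequalities. Class
  proportions near the cut-offs are sensitive to this choice.
- Nap groups: zero (mean daily nap exactly 0), long (> 30 min), short
  otherwise; 30.0 min falls to short because "long" is strict.

Clock-valued outputs (MSW, MSF, MSFsc) live on [0, 24). A chronotype
marginally before midnight therefore prints as ≈ 23.9 h; analyses that
need a linear scale (parameter recovery, age-trajectory comparisons)
unwrap onto the midnight-centred window (−12, 12], where all realistic
values are contiguous.

## Exclusion filters

Subjects are removed when: mean nocturnal sleep < 3 h or > 13 h
(applied to the per-subject mean, since the criterion describes a
subject property and per-night removal would silently fragment weeks;
a per-night variant is available behind `ExclusionRules(per_night=True)`);
age outside [10, 90] or BMI outside [10, 50] kg/m² *when present*
(missing values do not exclude); fewer than 7 consecutive recorded
nights. The filter emits a ledger counting removals per rule plus the
union; it is idempotent. Duplicate (subject, night) rows are a hard
parse error — the ambiguity is unrecoverable, so no merging is
attempted.

## Cohort analyses

Tail fractions (P(SJL > 1 h), P(SJL < 0)) are computed over subjects
with defined SJL; chronotype shares and the negative-SJL breakdown over
the chronotype cohort. Histograms use 0.5-h bins anchored at integer
hours. Pearson correlations use pairwise deletion of missing values;
group comparisons use two-sided Welch t tests (pooled-variance
available); the default significance threshold is P < .001, appropriate
for large cohorts. The SJL regressions are OLS with SJL in hours
against durations in minutes, so a slope of 0.0066 h/min reads as
0.4 min of SJL per nap minute. Correlations and tests are run on all
subjects and on the zero- and long-nap subgroups; the short-nap
subgroup is excluded from inference because its nap exposure is too
weak to carry a signal.

The feature-importance model is a `RandomForestRegressor` over the
predictors sex, age, BMI, mean daily steps (exercise proxy), mean
nocturnal sleep and mean nap duration, complete cases only; MSFsc is
never a predictor (it is itself strongly correlated with SJL). The
tree-count × depth grid (10–50 by 10; 2–5) is scored by mean 5-fold
cross-validated R² with shuffled, seeded folds; the best point is refit
on all complete cases and impurity-based importances are normalised to
unit sum (permutation importance is available as an option).
Hyperparameters beyond the grid are library defaults and are recorded
in the run manifest. A fixed seed makes the fit bit-reproducible.

## Synthetic cohort generator

The generator produces datasets in the exact CSV dialect the reader
consumes, alongside a ground-truth table the pipeline never sees.
Defaults encode the emulated population:

| parameter | default | note |
|---|---|---|
| work onset / wake | 00:15 / 7:00 | between-subject SD 70.5 / 66.3 min |
| free-night shift | +13 / +22 min | subject-level SD 41.9 / 47.0 min |
| night-to-night noise | 30 min SD | within-subject; free parameter |
| chronotype SD | 1.0 h | between subjects, around μ(age) |
| μ(age) | hinge 3.2 h @10 → 4.0 h @22 → 2.8 h @80 | biphasic trajectory |
| napper fraction | 0.94 | non-nappers nap exactly 0 min |
| nap duration | Gamma(2, 17.5 min) | mode 17.5, ~86 % under 60 min |
| WASO | 5 + 0.48·nap + N(0, 10) min | coupling gives r(nap, nocturnal) ≈ −0.22 |
| sex | 0.64 / 0.14 / 0.22 | male / female / unknown |
| age | 0.8·truncN(32, 9) + 0.2·U(10, 90) | mass at ages 20–50 |
| steps | lognormal, median 7500/day | exercise proxy |

Construction, per subject: a latent chronotype `c = μ(age) + N(0, 1 h)`
shifts both onset and wake of the work schedule; residual subject-level
onset/wake jitter is sized so the *total* between-subject SDs match the
configured 70.5/66.3 min; the cohort is centred by subtracting E[μ]
(computed by quadrature over the age distribution) so the mean work
schedule lands on the configured 00:15/7:00 regardless of the age mix.
The free schedule adds subject-level shifts (mean +13/+22 min), whose
mid-point average of 17.5 min is the cohort-mean SJL of ≈ 0.29 h. The
WASO–nap coupling (0.48 min per nap minute) is what induces the
negative nap–nocturnal-duration correlation; it was calibrated to the
−0.22 target because minute rounding and clipping dilute the analytic
value. The within-subject night-to-night SD (30 min) is a free
parameter: published cohort tables report only between-subject SDs of
means.

All schedule values, WASO and naps are quantized to whole minutes
*before* the ground truth is evaluated, so writing HH:MM CSVs is
lossless: with every noise source at zero (`SimConfig.noiseless()`) the
pipeline recovers SJL ≡ 0 and MSFsc equal to the latent truth exactly
(floating-point tolerance 1e−9 in tests). All randomness descends from
one root seed via named `SeedSequence` spawns (subjects, schedule,
nights, naps, steps, missingness), making output files byte-identical
across runs with the same configuration.

What the generator does **not** emulate: shift work and weekend
employment (all subjects share the Friday/Saturday free-day calendar),
nap timing (only durations), seasonal and latitude effects, device
staging error, and any SJL–BMI or SJL–age dependence beyond what the
chronotype trajectory induces. Passing recovery tests therefore show
that the estimators are correct under the stated generative model, not
that the model captures every feature of real device data.

## Problem sizes and numerical choices

The shared statistical checks run on one simulated cohort of 5000
subjects × 4 weeks, chosen so that binomial and correlation checks have
4σ Monte-Carlo bands of roughly ±0.013 and ±0.05; the normal-tail
oracle uses 20,000 draws; feature-importance recovery uses 2000
subjects. Degenerate inputs fail loudly: mid-sleep rejects episodes
outside the open (0, 24) axis window, Pearson requires n ≥ 3 and
non-constant inputs, t tests require n ≥ 2 per group, regressions
reject rank-deficient designs, and the forest requires at least as many
complete cases as folds. Rare extreme night-noise draws are clipped
into the open axis window (at most one minute from the boundary) so
every generated record satisfies the reader's invariants.

## Known limitations

- The free-day definition is purely calendrical; subjects working
  weekends are misclassified.
- Chronotype classes depend on fixed cut-offs whose population validity
  varies; boundary handling (3.0/5.0 → intermediate) is a convention.
- The MSFsc correction is applied unconditionally; traditions that
  correct only when SDf > SDw will differ for the minority of subjects
  sleeping longer on work days.
- Impurity-based importances are biased toward high-cardinality
  continuous predictors; the permutation option is provided for
  sensitivity analysis.
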