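# Methods

This note records the modeling assumptions, parameter choices and known
limitations of `alstrack`, in the order the pipeline runs.

## Synthetic cohort generator

The generator (`alstrack.synthetic`) emulates a small in-home monitoring
case series for ALS: a handful of participants (default 3), enrollment
lengths of 150–600 days, ALSFRS-R assessments every 30 days (day 0, the
enrollment day, is always assessed; every third visit carries a "clinic"
flag, which is metadata only — telephone and clinic assessments are treated
identically because no reliability difference is modeled), and continuous
sensor channels whose daily means load linearly on latent functional
trajectories.

**Latent trajectories.** One daily latent level per participant × subscale,
on the 0–4 subscale domain. Three profiles:

* `homogeneous` — a per-scale decline rate shared by all participants
  (drawn once per scale from 0.004–0.015 levels/day), with small
  participant-specific intercept offsets (SD 0.15);
* `heterogeneous` — the shared base rate multiplied by a fixed
  participant ladder (×1/3, ×1, ×3). The ladder is deterministic so the
  preset reliably encodes participant-specific decline speeds; with random
  iid rates the spread between three participants is occasionally
  negligible, which would make "heterogeneous" a misnomer;
* `plateau-drop` — a constant level with 2–4 sudden step decreases
  (0.5–1.2 levels), emulating stability punctuated by acute loss.

Rates are capped so a trajectory reaches its floor no earlier than the end
of enrollment: a fast progressor declines steeply to near 0 by study exit
rather than sitting at 0 for months. This keeps late-enrollment scores
informative and matches how case-series enrollment typically ends (death or
exit near functional floor). Bounded uniform jitter (±0.02) is added, so
trajectories are monotone non-increasing up to at most twice the jitter.
The rate range was chosen so that integer assessment-score variances per
subscale fall in the 0–2.5 band reported for observed ALSFRS-R case-series
data; composite latents are the sum of the 12 subscale latents.

**Assessments.** Latent value at each assessment day, rounded half-up and
clipped to [0, 4]; the composite is recomputed as the subscale sum (never
independently noised), preserving the integer variance structure and the
composite-consistency invariant.

**Sensor streams.** Per channel, the daily sample mean is exactly
`baseline + loading × latent + N(0, noise_sd)`: the day/night amplitude
modulation and the within-day noise are mean-centred per day, so the
coupling is recoverable by OLS of daily means on the latent (a property the
tests check). Default channels couple respiration→respiratory,
pulse→dyspnea, restlessness→turning, and motion counts→walking/dressing/
composite, with negative loadings for the physiological channels (breath
rate and pulse rise as function declines). Bed channels sample once per
minute, motion once per hour; the named presets (`tiny`, `homogeneous`,
`heterogeneous`, `plateau-drop`) sample bed channels every 10 minutes — the
desk-scale condition used throughout the tests and the acceptance script.
A seeded 5% whole-day dropout mask emulates the gap between enrollment
length and usable sensor days.

What the generator does **not** emulate: raw ballistocardiogram waveforms,
falls, gait, circadian drift, sensor faults correlated with disease state,
assessment-date jitter, and any nonlinear sensor–function coupling. Tests
passing on this cohort therefore show that the pipeline recovers structure
that is present by construction — linear coupling and (in)homogeneous
decline — not that it would perform comparably on real patients.

## Feature engineering

Day window 06:00–22:00 local, half-open (the convention is asserted at the
boundary). The 17 per-cell statistics use population variance, biased
standardized third/fourth moments (kurtosis as excess; both 0 for constant
cells), linear-interpolation quantiles, a mode defined as the most frequent
2-decimal rounding with ties to the smallest value, CV with a zero-mean
guard (|mean| < 1e-12 → 0), and Shannon entropy (nats) over 10 equal-width
bins with bin index `floor(10·(x−min)/range)` (max value in the last bin;
constant cells have zero entropy). Days containing non-finite samples are
excluded with a log entry.

Collinearity removal is a greedy keep-first scan in fixed column order at
|r| > 0.95; constant columns are dropped with reason "constant". Min–max
scaling maps constant columns to 0 and is applied unchanged to test rows
(values may leave [0, 1]; no clipping). Both are fit on the training
partition only; `paper_faithful=True` fits them on all rows instead, for
auditability of the original all-rows ordering. Whether collinearity is
computed before or after min–max scaling is immaterial (Pearson r is
affine-invariant).

## Pseudo-labeling

Linear and cubic interpolators are exact at the anchors; outside the anchor
span both extend the nearest anchor value (no extrapolated decline is
invented beyond the last visit). The cubic spline uses natural boundary
conditions and is clipped to the scale range.

The self-attention interpolator is a one-layer, two-head transformer
encoder (d_model 32, feed-forward 64) over daily sensor feature vectors
with a sinusoidal encoding of the normalized day index, trained full-batch
by Adam (lr 1e-3, 200 epochs, no early stopping) against observed scores on
anchor days only, with targets standardized by anchor statistics and the
output head zero-initialized so training starts from the anchor mean.
Determinism at fixed seed was preferred over training-speed tricks. It is
fit once per sensor-channel table (day + night statistics of one channel)
and the per-table daily estimates are ensembled by pointwise averaging;
outputs are clipped to the scale range. Observed scores are never model
inputs at non-anchor days, so the interpolator cannot trivially copy them.
`target_mode="delta"` regresses per-day change and integrates from the most
recent anchor instead; the default regresses the score itself, since the
score-scale curves are the quantity of interest. The implementation is pure
NumPy over a minimal reverse-mode autodiff tape, gradient-checked against
numerical differentiation in the test suite.

## Progression models

All learners are XGBoost regressors (single-threaded, `hist`,
`seed_per_iteration` on — boosting *continuation* with column subsampling
is otherwise nondeterministic, which would break the reproducibility
contract). The sequential split takes the earliest floor(0.8·N) rows for
training. Targets with zero training-label variance are not modeled at all
(static scores); variance below 0.01 additionally excludes individual batch
models.

Randomized search draws `n_draws` (default 50) configurations from the
fixed nine-parameter candidate lists via `sklearn` `ParameterSampler`,
scored by 3-fold cross-validated RMSE — chronological block folds for
participant-level tuning, shuffled folds for the cohort base. The
precision-rounding screener then keeps features whose split-frequency
importance, rounded at p = 6, 7, 8, … decimals, is non-zero (more decimals
admit more features), capped at the 200 most important; each subset is
refit and the subset with the lowest RMSE on the selection rows wins, ties
to the smaller subset. Selection rows default to the last 20% of the
training rows; the test-based selection described for the original design
is available behind `paper_faithful` but leaks the test set and is off by
default.

Transfer batch fine-tuning resumes boosting from the serialized cohort
checkpoint for one pass (default: the base model's own tree count) over the
holdout's full training set, hyperparameters unchanged. Incremental
fine-tuning is prequential: predict row t with the state before row t, then
resume k = 1 round on the trailing w = 14-day window including row t. In
the pipeline the loop continues through the test period, so the evaluated
test predictions are the prequential ones — this is the use case the
paradigm models (between-visit adaptation as data arrive) and every
prediction still precedes its own observation. Checkpoints are a pickled
booster blob plus a JSON sidecar (features, hyperparameters, provenance,
SHA-256); loading verifies the hash. Cohort-base provenance records a
participant-qualified hash of every training row id, which is what the
leave-one-participant-out integrity audit checks.

## Evaluation

Standard deviations in Taylor/bootstrap geometry are population (ddof = 0),
making the law-of-cosines identity exact against centered residuals. The
RMSE bootstrap recomputes the centered error from σ_y, σ_ŷ and |r| per
resample, exactly as specified for the original analysis, even though this
omits the mean-bias term; `residual=True` recomputes plain RMSE instead.
Zero-variance resamples take |r| = 0; |r| within 1e-12 of 1 is snapped to 1
so perfect predictions yield the exact (0, 0) interval. Percentiles are
linear-interpolation empirical quantiles. Degenerate correlations (either
side constant) are rendered as 0 with a (0, 0) interval and an explicit
flag. Cross-participant summaries are means with t-distribution CIs from
the SEM; no interval is produced from a single participant. The
"significantly better" flag in contrast tables means *disjoint 95% CIs in
the favorable direction* — an interval-overlap criterion defined by this
package, not a formal hypothesis test — and Taylor outputs store signed r
alongside |r| plus a negative-correlation flag for plotting.

## Reproducibility and problem sizes

One master seed derives every stage seed via `derive_seed(master, label)`
(CRC-32 of `"{master}:{label}"`, below 2^31), so identical config + seed
reproduces byte-identical metric tables. Tests and the acceptance script
use 3-participant, 200-day cohorts with coarse intra-day sampling, 0–3
tuning draws and 50–1000 bootstrap resamples; these sizes were chosen so a
full run completes in minutes on a single CPU while still exercising every
stage. The structure-recovery checks are directional (win fractions over 10
seeds), not reproductions of any published effect size, because the
original cohort's data are restricted.

## Known limitations

* Tree ensembles cannot extrapolate beyond the training feature range; on
  steadily declining trajectories, late-period predictions from
  participant-only models saturate. This is intrinsic to the learner and is
  exactly the regime where cohort transfer helps.
* Pseudo-labels are interpolations, not ground truth; evaluation against
  them understates error relative to true (unobserved) daily function.
* The attention interpolator is transductive (it sees all days' features
  while training on anchor targets); its pseudo-labels therefore embed
  sensor information, which is the design intent but means label noise is
  correlated with the features.
* With three participants, cross-participant t-intervals have two degrees
  of freedom and are wide; they are reported as such, never suppressed.
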