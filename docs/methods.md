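# Methods

This note records the models, conventions and numerical choices behind
`emgreact`, in the order the pipeline applies them.

## Design and units

The repeated-measures layout is 156 participants × 3 instruction
conditions (no regulation, neutralize, transform) × 15 trials × 2 muscles
(corrugator supercilii, zygomaticus major). Each trial contributes an
8,000-ms pre-stimulus baseline epoch and an 8,000-ms regulation epoch,
both reduced to 16 consecutive 500-ms bin averages; bin *i* covers the
half-open interval ((i−1)·500, i·500] ms after instruction onset, so the
bin grid is labelled 500…8,000 ms. Reactivity is expressed as
percent-of-baseline (100 = no change), which cancels the arbitrary
absolute microvolt level of surface EMG.

## Raw-signal conditioning (optional stage)

Order: 60-Hz IIR notch (Q = 30) → 4th-order Butterworth bandpass →
full-wave rectification → 10-ms running average. All filters are applied
zero-phase (`filtfilt`), so bin means are not displaced in time; the
filter realisation is recorded in `preprocess.FILTER_SPEC`. The nominal
EMG passband is 20–500 Hz at a 1,000-Hz sampling rate; since 500 Hz *is*
the Nyquist frequency, the upper edge is clamped to 499 Hz. Records
shorter than 100 samples are rejected rather than filtered with
unreliable warm-up. For a rectified zero-mean Gaussian carrier the mean
equals σ√(2/π); the raw-signal generator scales its noise by the
reciprocal so the rectified, smoothed, binned signal is an unbiased
estimate of the latent bin amplitude.

## Data reduction

Outlier censoring operates within one trial × epoch × muscle: mean and
SD (ddof = 1) over that epoch's 16 bins, and any bin with
|x − mean| > 2.5·SD becomes missing. The rule is applied in a single
pass (no re-iteration), uses a strict inequality at the boundary, and is
skipped with a warning when the SD is zero; by default it is applied to
baseline epochs too (toggle `censor_baseline`). Scoping the statistics
to a single trial keeps conditions from contaminating each other's
censoring thresholds.

Percent change divides each regulation bin by the mean of the trial's
non-missing baseline bins; trials with a non-positive baseline mean are
dropped with a logged count. Cell aggregation averages non-missing trial
scores per participant × condition × muscle × bin and records the
contributing trial count; a cell bin is missing only if every trial is.

One deliberate interaction: with *all* noise switched off a trial's bins
are exactly the condition template, whose genuine first-bin peak then
exceeds 2.5 within-trial SDs and would be censored as structure, not
noise. The noise-free calibration checks therefore disable censoring; at
realistic noise the within-trial SD (~29 percent-points) dominates and
the template shape is never flagged.

## Synthetic data generator

The generator is the test bed for every downstream stage; its defaults
are the study conditions above, and its six condition × muscle templates
are the packaged per-bin group means and SDs. Regulation activity is
generated on the percent scale as

    score(p, t, b) = template(b) + z_p · s_p(b) + u_t + e_tb

with one standard-normal deviate `z_p` per participant × muscle shared
across conditions, a trial-level shift `u_t` (SD 25 percent-points)
shared by the 16 bins of a trial, and per-bin noise `e_tb` (SD 12).
The per-bin participant scale is
`s_p(b) = sqrt(SD_template(b)² − (25² + 12²)/15)`, so the
across-participant SD of trial-averaged cell means reproduces the
template SDs. Scores are converted to microvolts against each trial's
own realised baseline mean, making the percent-change round trip exact
by construction.

Rationale for the choices that the design left open:

* **Trial-level vs bin-level noise split.** Trial-level variance is what
  creates inter-item covariance across a trial's 16 time points, hence a
  non-trivial Cronbach's α. The 25/12 split implies, via Spearman–Brown
  with k = 16 items and ρ = 25²/(25² + 12²), a per-participant α ≈ 0.99,
  the right magnitude for stable facial-EMG profiles. Baseline epochs
  use a trial-level CV of 0.12 and bin-level CV of 0.06 around a 5-μV
  resting level (the level itself is arbitrary; percent change cancels
  it).
* **Shared participant deviate across conditions.** Within-participant
  condition responses are strongly correlated in a repeated-measures
  design; independent draws would inflate paired-difference SDs by ~√2
  and leave per-bin contrasts powerless at n = 156. Sharing `z_p`
  (while scaling by each cell's own SD profile) keeps every
  per-condition SD calibrated and restores realistic paired power.
  Muscles keep independent deviates, so the channel-independence test
  sees a null correlation.
* **Additive normal effects, no truncation.** With the large zygomaticus
  SDs (~120 at means ~135) a normal model occasionally produces negative
  reactivity values that real rectified EMG cannot show. Values are not
  clipped: truncation would distort the variance calibration by ~10%,
  and the analyses are indifferent to the sign. This is the main respect
  in which the generator is idealised — real EMG percent change is
  right-skewed with heavy tails, and passing tests on this generator do
  not certify behaviour under such skew.
* **Outliers** are isolated bin spikes at ±6 generating-SDs (rate 1% by
  default), sized so the 2.5-SD rule catches them with high probability
  — they exist to exercise the censoring stage, not to model a specific
  artifact physiology.

Identical configurations (including the seed) produce bit-identical
tables; all randomness flows through one `numpy` generator seeded once.

## Reliability analyses

Cronbach's α uses the pairwise-complete covariance matrix, with
α = k/(k−1)·(1 − tr(C)/ΣC); zero total variance yields NaN rather than
an arbitrary value. Baseline stability pools all conditions' trials (45
rows in the full design) on the microvolt scale — percent change is 100
at baseline by construction, so reliability there would be vacuous; an
alternative orientation is a documented toggle only. No-regulation
response stability uses that condition's 15 trials of percent-change
scores. Participant αs (negative values retained) are averaged as
tanh(mean(atanh α)), with α clamped into (−0.999999, 0.999999) before
the transform. Channel independence averages each participant's scores
into one value per muscle across all conditions and bins, then reports
Pearson r, t with df = n − 2, and the Fisher 95% CI.

## Per-bin contrasts

Dependent-samples t-tests per bin with pairwise deletion (a participant
missing a bin is dropped for that bin only), two-sided p, df = n − 1.
Identical pairs (zero-variance differences) are reported as t = 0,
p = 1 rather than NaN. Effect size is d_z = mean(diff)/SD(diff) — the
variant consistent with the paired design — with a normal-approximation
CI using Var(d_z) ≈ 1/n + d²/(2n). The per-test level is α/m
(0.003125 at α = 0.05, m = 16 bins). Cousineau–Morey within-subject
intervals centre each score on the participant's cross-condition mean
(plus the grand mean) across the J = 3 regulation conditions and
multiply the half-width by √(J/(J−1)).

Onset is the earliest Bonferroni-significant bin (no run-length
requirement). The **peak** of a contrast is the bin with the largest
|d_z|, ties broken toward the earlier bin, with the mean difference
reported at that bin; effect size is used because per-bin SDs differ
several-fold across the course, and raw differences are not comparable
across bins. (On the packaged tables this reproduces all narrated peak
locations, which a max-|difference| rule does not.)

## Trajectory model fitting

The observed transform-condition path is the 16 per-bin group-mean
points (x = corrugator, y = zygomaticus; both axes share percent units,
so distances are unstandardised Euclidean). Anchors are the observed
points 1 and 16. The neutral model runs vertically from the start to the
corner (start.x, end.y), then horizontally to the end; the mixed model
runs horizontally to (end.x, start.y), then vertically; the valence
model is the straight segment. For vertex v, points 1..v are equally
spaced on the first segment (point v at the corner) and points v..16 on
the second; the valence path has 16 equally spaced points. MSD averages
squared point-wise deviations over the 14 interior points — the anchored
endpoints deviate by zero and carry no shape information, and this
divisor is the convention under which the packaged rounded means
reproduce the published mixed-family and valence deviations to within
0.1%. All 29 candidates (2 × 14 vertices + valence) are scored;
the argmin breaks ties by smaller MSD, then smaller vertex, then family
order neutral < mixed < valence.

Identifiability: families are cleanly separable under interior jitter up
to SD 2 percent-points, but adjacent *late* vertices of the same family
differ by fractions of a unit, so exact-vertex recovery degrades to
~92% there. The recovery tests accordingly demand family+vertex at
jitter SD 1 and family-only at SD 2.

## Pipeline and problem sizes

`run_pipeline` chains the stages under one config and seed, writing
every table as delimited text plus a manifest (config, seed, version)
that suffices to re-create the bundle byte-for-byte. The test suite runs
the full 156 × 15 design once (shared fixture) and smaller designs
elsewhere; simulation-based calibration checks use 1,000 null
replicates for the type-I rate, 500 for effect-size recovery, and 200
for trajectory recovery — sizes at which the Monte-Carlo error is well
inside each test's tolerance.

## Known limitations

* The generator's normality (and resulting negative-score tail) and its
  perfectly correlated cross-condition participant effect are idealised;
  skewed, partially correlated real data will show larger effect-size
  discrepancies than the calibration tests suggest.
* The neutral-family MSD magnitudes depend on the corner placement
  policy; only the mixed and valence deviations are anchored to external
  reference values, and the neutral family is validated through ordering
  and recovery properties.
* No mixed-effects, cluster-permutation or FDR alternatives; no
  artifact handling beyond the 2.5-SD rule; no per-participant
  trajectory fitting.
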