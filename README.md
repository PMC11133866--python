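# emgreact

Time-course analysis of facial EMG reactivity for emotion-regulation
experiments.

When people down-regulate a positive emotion, do negative affect (NA) and
positive affect (PA) change together or in sequence? Facial
electromyography gives a muscle per dimension — corrugator supercilii
(frowning, NA) and zygomaticus major (smiling, PA) — and sub-second
resolution. `emgreact` implements the full analysis chain for a
repeated-measures design in which each trial has an 8,000-ms pre-stimulus
baseline and an 8,000-ms regulation epoch, both summarised as 16 × 500-ms
bins, across three instruction conditions: *no regulation*, *neutralize*
(reappraise toward a neutral meaning) and *transform* (reappraise toward
a negative meaning). It is aimed at psychophysiologists who want a
tested, reproducible reference implementation of this pipeline, and at
methodologists who want to stress-test it on synthetic data with known
ground truth.

## What it computes

* **Preprocessing** (`emgreact.preprocess`) — optional raw-signal
  conditioning (60-Hz notch, 20–499-Hz bandpass, full-wave rectification,
  10-ms running average, all zero-phase), 500-ms bin averaging,
  within-trial outlier censoring (|x − mean| > 2.5 SD → missing, single
  pass), and percent-of-baseline scores
  `score_i = 100 · bin_i / mean(baseline bins)` averaged into
  participant × condition × muscle cells.
* **Reliability** (`emgreact.reliability`) — per-participant Cronbach's
  α with the 16 time points as items and trials as observations,
  `α = k/(k−1) · (1 − Σ s²_item / s²_total)`, averaged across
  participants via Fisher's r-to-z; plus the corrugator–zygomaticus
  channel-independence correlation (Pearson r, `t = r√((n−2)/(1−r²))`).
* **Contrasts** (`emgreact.contrasts`) — per-bin dependent-samples
  t-tests between conditions, Cohen's `d_z = mean(diff)/SD(diff)` with a
  normal-approximation 95% CI, Bonferroni-adjusted level α/m (0.05/16 =
  0.003125), Cousineau–Morey within-subject CIs (participant-mean
  centring, Morey factor √(J/(J−1))), and onset/peak summaries.
* **Trajectory fitting** (`emgreact.trajectory`) — the headline method.
  The observed transform-condition response is a 16-point path through
  the (corrugator, zygomaticus) plane. Three hypothesised trajectories
  connect its endpoints: an L-shaped *neutral* path (PA falls, then NA
  rises), an inverse-step *mixed-emotions* path (NA rises, then PA
  falls), and a straight *valence* diagonal. Piecewise families place a
  vertex at path point v ∈ 2..15 with points equally spaced per segment;
  each candidate is scored by the mean squared Euclidean deviation (MSD)
  over the 14 interior points, and the smallest MSD wins.
* **Synthetic data** (`emgreact.synth`) — a seeded generator for the
  complete design (156 participants × 3 conditions × 15 trials × 2
  muscles by default) whose condition templates are the packaged per-bin
  group means/SDs, with participant-, trial- and bin-level variance
  components and injectable bin spikes; plus an optional 1,000-Hz raw
  mode. Every analysis stage is testable against known ground truth.

## Worked example

Fit the three trajectory models to the packaged group-mean path:

```bash
python examples/trajectory_fit.py
```

```
observed path: start (112.4, 133.5) -> end (131.3, 104.7)

  family vertex       MSD
 neutral      2     96.65
 neutral      3     74.00
 neutral      4     67.16
 ...
   mixed      2    682.71
   mixed      3    691.57
 ...
 valence      -    360.30

best fit: neutral trajectory with its corner at 2000 ms (point #4), MSD = 67.16
-> positive affect fell first; negative affect rose only after a neutral
state was reached.
```

The observed path starts high on the zygomaticus axis (133.5% of
baseline — strong PA) and ends high on the corrugator axis (131.3% — NA
has taken over). The neutral family fits best by an order of magnitude
over the mixed family, i.e. the data descend the PA axis before moving
out along the NA axis; the diagonal valence path is intermediate. Other
examples (`examples/*.py`) walk through simulation, preprocessing,
reliability and the per-bin contrasts, and `emgreact run-all --out
<dir>` runs everything from a shell.

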