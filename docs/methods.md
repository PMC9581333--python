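# Methods

## The measurement being modelled

Magnet-coil scratch monitoring implants a small magnet in each hind paw of a
mouse; any hind-limb movement induces a current in a coil surrounding the
cage. Scratching is a stereotyped hind-paw oscillation at roughly 10–20 Hz,
so in the induction current a scratch appears as a short oscillation burst
in that band. The behavioural hierarchy is:

- **beat** — one paw-oscillation cycle (~50–100 ms);
- **bout** — an uninterrupted, rhythmic run of beats; rhythmicity is
  enforced as a coefficient of variation (CV) of the inter-beat intervals of
  at most 40 %;
- **event** — one or more bouts between a paw lift and paw-down.

Sessions are 30-minute recordings starting at the injection of a pruritogen
into the nape of the neck (t = 0), a site the animal can only reach with the
hind paws. Locomotion (~1–4 Hz, large amplitude) and grooming (~5–8 Hz)
are the movement artifacts the 10–20 Hz band is meant to reject.

## Signal simulator (`scratchkit.simulate`)

Because the per-animal raw recordings behind the published summaries are not
deposited anywhere, the package ships a simulator that renders sessions with
exact annotations; every downstream stage is validated against that ground
truth.

An event/bout/beat schedule is drawn first, then rendered:

- each beat is one cycle of a Hann-windowed cosine at the bout's frequency,
  centred on the beat time — a simple, band-limited, detector-agnostic
  waveform;
- bout frequencies are drawn from the interior of the band and jittered
  inter-beat intervals are clipped 1.5 samples inside [1/f_hi, 1/f_lo], and
  jitter is redrawn until the interval CV is ≤ 0.38. Both margins exist so
  that quantizing beat times to the 200 Hz sampling grid can never push a
  *rendered* bout out of band or over the 0.40 CV limit: generated bouts
  are detectable by construction at default detector settings;
- confounders are Hann-windowed tone bursts (locomotion 1–4 Hz at 2×
  bout amplitude, ~0.5/min; grooming 5–8 Hz at 1×, ~1/min);
- all items (events and confounder bursts) are placed uniformly at random
  without overlap and with a 1.5 s minimum gap, so filter transients of one
  burst cannot bridge into the next; an impossible schedule raises
  `ScheduleInfeasibleError`;
- white Gaussian noise (default SD 0.1 of the unit bout amplitude) is added.

Defaults per session: 40 events of 1–5 bouts, 4–30 beats per bout, 0.2–0.8 s
gaps inside an event, 15 % beat-interval jitter. Sampling rate defaults to
200 Hz (ten times the top of the band; the original acquisition rate is not
on record). Identical parameters and seed give bit-identical output.

What the simulator does *not* model: coil physics, amplitude calibration,
drift, movement superposition (a mouse that scratches while walking), or
broadband grooming harmonics. Passing detection tests on this generator
therefore demonstrates the correctness of the decision logic (band, CV,
grouping, scoring), not field performance on arbitrary recordings.

## Detector (`scratchkit.detect`)

1. Zero-phase 4th-order Butterworth band-pass over the scratch band.
2. Robust noise scale: 1.4826 × MAD of the band-passed trace, floored at
   2 % of the raw trace's peak absolute value (the floor keeps the
   threshold defined on noise-free input and anchored to the session's
   dynamic range). Threshold = 5 × that scale.
3. Beats: positive peaks of the band-passed signal above threshold, with
   envelope (analytic-signal magnitude) above threshold, minimum separation
   1/(2 f_hi). Within each contiguous supra-threshold burst, peaks below
   30 % of the burst's envelope maximum are discarded: these are the
   decaying filter transients at burst edges, which would otherwise extend
   or bridge runs.
4. Bouts: greedy left-to-right run construction — a run extends while the
   next inter-beat interval lies in [1/f_hi, 1/f_lo] (with a 1e-9 relative
   tolerance against rounding at the boundary). Runs shorter than 3 beats
   (the smallest run with a defined CV) are discarded. A run whose interval
   CV (sample SD / mean, n−1 denominator, threshold inclusive) exceeds 0.40
   is split at the interval most deviant from the run's median interval
   (leftmost on ties) and both halves are re-evaluated recursively.
5. Events: consecutive bouts with gaps ≤ 1.0 s merge. Paw lift/down is not
   observable in the induction signal, so the event-gap threshold is a
   configurable surrogate; ground truth carries explicit lift/down times
   for calibrating it.
6. Scratch time is Σ(bout end − bout start), with bout start/end the first/
   last beat time, no padding.

A note on thresholds as properties: split points in step 4 do not depend on
`cv_max`, so tightening `cv_max` refines the segmentation and the number of
beats retained in bouts is monotone non-increasing. The number of *bouts*
is not monotone — one retained run can split into two retained halves — so
the monotonicity property is stated (and tested) on retained beats.

### Validation

Detected bouts are matched one-to-one to true bouts greedily by midpoint
distance within a 0.5 s tolerance; unmatched detections are false
positives, unmatched truth false negatives. PPV = TP/(TP+FP), sensitivity =
TP/(TP+FN). Matching is at the bout level (the natural unit of the counting
analyses); both the unit and the tolerance are recorded in the run config.
The default validation suite is 20 sessions (seeds 1–20) at default signal
and detector parameters with both confounder kinds enabled.

## Cohort simulator (`scratchkit.cohort`)

The study design is strain (C57BL/6J, C3H/HeJ) × pruritogen (endothelin,
chloroquine, trypsin, LPA, histamine, 5-HT, SLIGRL) × dose-fold (0.3, 1, 3,
10 of a per-pruritogen reference concentration), repeated measures: each
animal receives all four doses of one pruritogen 48 h apart (3-fold on day
1, 1-fold on day 3, 10-fold on day 5, 0.3-fold last on day 8, so
sensitization would be visible at the weakest dose).

Per-cell bout counts are drawn from a negative binomial matched to the
cell's mean and SD (counts of behavioural bouts are overdispersed); when
the target variance is at or below the Poisson limit — and always under the
`lognormal_rounded` model — a moment-matched rounded lognormal is used
instead, which degenerates to `round(mean)` as the dispersion goes to zero.
A rounded lognormal is offered because most published groups screened as
approximately normal. Counts are drawn independently across animals and
doses; no within-animal dose-to-dose correlation is modelled, which is the
minimal structure consistent with reproducing every cell's published
mean ± SEM (repeated-measures F statistics on simulated cohorts are
therefore conservative relative to animals with stable individual scratch
propensities).

Scratch time and event counts derive from the bout count through per-animal
drivers (per-bout duration ~ lognormal around 0.6 s, 2.5–3.5 bouts per
event), giving the strong cross-metric correlations seen in real sessions.

The default cell means live in `data/group_means.yaml`. Cells published as
mean ± SEM are tagged `printed`; cells between two printed anchors are
log-dose linear interpolations (`interpolated`); cells outside the anchor
range hold the nearest anchor (`edge-held`); curves with a single printed
anchor get hand-chosen `synthetic-default` shapes that respect the
published peak dose and potency ordering. Unprinted SEMs default to
0.3 × mean. Only `printed` cells carry evidential weight; the per-animal SD
of a cell is SEM·√n with the published group size n, so dispersion is
reproduced regardless of the simulated group size.

## Statistics (`scratchkit.stats`)

- **Outlier fences**: one pass of Tukey fences at 2.2 × IQR per
  strain × pruritogen × dose cell (no re-fencing). Quartiles use linear
  interpolation (type 7) by default; Tukey hinges are available via
  `quantile_method="hinges"` — for the small group sizes here the two can
  fence differently, so the convention is explicit and logged.
- **Normality**: Shapiro–Wilk by default, Lilliefors-corrected
  Kolmogorov–Smirnov as the alternative; both appear in the literature this
  workflow mirrors and no reconciliation is guessed. The reporting utility
  exposes the share of normal groups both raw and truncated to two decimals
  (47/53 prints as 88.67 %).
- **RM-ANOVA**: classical univariate sums-of-squares partition
  (subject, within-factor, residual), complete cases only — subjects
  missing any dose after outlier removal are dropped entirely, the
  conservative reading of how removal interacts with the repeated-measures
  structure. No sphericity correction by default; Greenhouse–Geisser is
  available (`gg_correction=True`). With a between-subjects factor the
  split-plot partition is used (balanced groups assumed for the interaction
  term). Cross-checked in tests against an independent explicit-loop oracle
  (1e-8 relative) and against `pingouin`.
- **Tukey HSD**: studentized-range p-values (Tukey–Kramer standard error
  for unequal n) on the RM-ANOVA residual mean square and its df (the error
  term is not dictated by the workflow being mirrored; the within-subject
  residual is the standard choice). The compact letter display enumerates
  maximal cliques of the non-significant-pair graph, so sharing a letter is
  exactly equivalent to "not significantly different" at α = 0.05.
- **Wilcoxon rank-sum** (fallback for non-normal groups): exact two-sided p
  by full enumeration of rank assignments (midranks under ties, smaller
  tail doubled, capped at 1) when min(n) ≤ 8 and combined n ≤ 16; otherwise
  a normal approximation with tie and continuity corrections (within ~0.01
  of exact at n = 7 + 7).
- **Dose-response cells**: mean, SEM, n per cell; SEM is flagged undefined
  (not silently zero) for n = 1; the peak dose is the argmax of cell means
  with ties resolved toward the lower dose.
- **Peak ratios**: per pruritogen, percent = 100 × C3H peak mean / C57 peak
  mean (nearest integer), fold = the reciprocal (one decimal), matching the
  rounding conventions of the published prose; raw values are reported
  alongside and satisfy percent × fold = 100 exactly.
- **Ranking**: each animal reduced to its grand mean over doses, one-way
  ANOVA across pruritogens within a strain, Tukey letters on the
  between-groups error term. (A one-way analysis on per-animal grand means
  is one defensible reading of how the published ranking letters were
  produced; the choice is recorded here and in the config.)
- Sexes are pooled by default (`--by-sex` keeps the split); α = 0.05
  throughout.

## Problem sizes and determinism

Default test and validation workloads — 20 full 30-min sessions at 200 Hz
for the detector suite, 50 pure-noise sessions for the false-positive
floor, n = 200 animals per cell for parameter recovery, 1e4–1e5 draws for
moment checks — were chosen so the whole suite runs in a few minutes on one
CPU while leaving the statistical checks well-powered. Every random draw in
the package flows through `numpy.random.default_rng` seeded from explicit
`seed` fields; identical configuration gives byte-identical outputs.

## Known limitations

- The simulator's confounders are narrowband tones; real grooming has
  harmonics that can reach into the scratch band, so real-data PPV is
  expected to be lower than on synthetic suites.
- Event grouping uses a time-gap surrogate for paw lift/down; event counts
  on real data depend on that threshold.
- The split-plot between-factor path assumes balanced groups.
- The anchor table's non-printed cells are conventions, not data; analyses
  that depend on them (full-curve ranking, interaction terms) demonstrate
  machinery, not biology.
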