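# scratchkit

Tools for quantifying pruritogen-induced scratching in mice from
magnet-coil induction-current recordings, and for the dose–response
statistics built on top of those counts.

In this assay a mouse carries a small magnet in each hind paw; hind-limb
movement induces a current in a coil around the cage. Scratching shows up
as oscillation bursts at the paw-beat rate of 10–20 Hz, while locomotion
(1–4 Hz) and grooming (5–8 Hz) sit below the band. The package is aimed at
behavioural-phenotyping labs that need a transparent, testable version of
this analysis chain:

- **`scratchkit.simulate`** — synthetic 30-min induction-current sessions
  with exact ground-truth annotations (events → bouts → beat times, plus
  confounder intervals);
- **`scratchkit.detect`** — beat detection (zero-phase band-pass, robust
  amplitude gate, peak picking), bout segmentation under the in-band
  interval rule with inter-beat-interval CV ≤ 40 %, event grouping, and
  PPV/sensitivity scoring against ground truth;
- **`scratchkit.summarize`** — per-session scratch time, bout and event
  counts, 5-min time-courses, and metric correlations;
- **`scratchkit.cohort`** — per-animal cohort tables for the
  strain (C57BL/6J vs C3H/HeJ) × pruritogen (7) × dose-fold (0.3/1/3/10)
  repeated-measures design, parameterized from published group means;
- **`scratchkit.stats`** — 2.2 × IQR outlier fences, normality screening
  (Shapiro–Wilk / Lilliefors KS), repeated-measures ANOVA with Tukey HSD
  and compact letter displays, exact/asymptotic Wilcoxon rank-sum,
  dose–response cells, cross-strain peak ratios, potency ranking;
- **`scratchkit.cli`** — a `scratchkit` command with subcommands
  `simulate-signal`, `simulate-cohort`, `detect`, `summarize`, `analyze`,
  `validate`, `run-all`.

The core decision rule: a detected beat run is a scratch **bout** when every
inter-beat interval lies in [1/f_hi, 1/f_lo] for the 10–20 Hz band and the
interval CV = s/ x̄ (sample SD over mean) is at most 0.40; runs failing the
CV rule are split recursively at the most deviant interval. Bouts separated
by ≤ 1 s form one scratch **event**. See `docs/methods.md` for the full
model and every numerical convention.

## Worked example

```python
from scratchkit import SignalParams, simulate_session, run_detection, validate, summarize
from scratchkit.cohort import load_group_means
from scratchkit.stats import dose_response_from_anchors, peak_ratio_report

trace, truth = simulate_session(SignalParams(seed=1))
beats, bouts, events = run_detection(trace)
s = summarize(bouts, events)
r = validate(bouts, truth)
print(f"true bouts: {truth.n_bouts}   detected: {len(bouts)}   events: {len(events)}")
print(f"scratch time: {s.scratch_time_s:.1f} s   5-min bins: {s.bin_counts}")
print(f"PPV: {r.ppv:.3f}   sensitivity: {r.sensitivity:.3f}")

mt = load_group_means()["strains"]
rep = peak_ratio_report(dose_response_from_anchors(mt, "C57"),
                        dose_response_from_anchors(mt, "C3H"))
print(rep[["pruritogen", "peak_c57", "peak_c3h", "percent", "fold"]].to_string(index=False))
```

prints

```
true bouts: 94   detected: 94   events: 40
scratch time: 109.8 s   5-min bins: [13, 12, 17, 21, 17, 14]
PPV: 1.000   sensitivity: 1.000
 pruritogen  peak_c57  peak_c3h  percent  fold
       5-HT     409.0      55.0       13   7.4
        LPA     378.0      78.0       21   4.8
     SLIGRL     215.0      72.0       33   3.0
chloroquine     513.0     138.0       27   3.7
 endothelin    1633.0     405.0       25   4.0
  histamine     406.0      19.0        5  21.4
    trypsin     549.0     106.0       19   5.2
```

The first block simulates one default 30-min session (seed 1) and runs the
detector on it: all 94 annotated bouts are recovered with no false
positives, grouped into 40 events, for 109.8 s of total scratching. The
table compares each pruritogen's peak group-mean response across strains:
the scratch-resistant C3H strain reaches only 5 % (histamine) to 33 %
(SLIGRL) of the C57 peak response, i.e. C57 is 3.0- to 21.4-fold more
responsive at peak.

From the shell, the same pipeline end to end:

```sh
scratchkit run-all --seed 7 --out-dir results/
scratchkit validate --sessions 20 --seed 1
```

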