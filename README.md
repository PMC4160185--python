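# bowcoord

Analysis pipeline for coordination in fast repetitive violin-bowing
patterns, exercised end-to-end on synthetic bowing signals with known
ground truth.

The package models bow velocity and bow inclination as coupled
quasi-sinusoidal oscillations (circular patterns share one frequency; the
figure-of-eight has a 2:1 velocity/inclination frequency relation), with a
finite string-crossing band over which the total bow force cross-fades
between strings. From sampled bowing channels it estimates, per bow
change (velocity zero crossing, sub-sample interpolated):

* **relative phase** — Hilbert-based (analytic-signal phase of velocity vs.
  angular velocity, with factor-2 compensation for the figure-of-eight)
  and time-domain (`360 * (t_bc - t_c) / T`),
* **normalized string-crossing range** — amplitude-based (band width over
  peak-to-peak inclination extent) and time-domain (`sin(pi * dt / T)`),
* **inclination offset**, transition/cycle durations and context indices,

and summarizes strategies in the 2-D coordination space (phase vs. range)
with the inside-band boundary `|phase| <= arcsin(r)`, coverage ellipses and
distribution summaries. Aggregation to per-participant/condition tables is
two-step: statistics per transition first, then an unweighted average
across transitions.

## Modules

| module | role |
| --- | --- |
| `bowcoord.synthetic_data` | forward simulator, experimental-protocol grid, force cross-fade |
| `bowcoord.preprocessing` | zero-phase Butterworth filtering (velocity 30 Hz, band width 48 Hz), differentiation |
| `bowcoord.phase_estimation` | analytic-signal continuous phase, relative phase, offset referencing |
| `bowcoord.transition_features` | bow-change detection, selection trimming, per-transition features |
| `bowcoord.coordination_space` | boundary curve, inside classification, coverage ellipses, summaries, plots |
| `bowcoord.aggregation_stats` | two-step aggregation, CV, estimator comparison, tidy export |

## CLI

```sh
bowcoord simulate --pattern CW --tempo 92 --phase 15 --range 0.32 --seed 1 -o series.csv
bowcoord extract -i series.csv -o features.csv
bowcoord summarize -i features.csv --group pattern,tempo_bpm -o summary.csv
bowcoord aggregate -i features.csv --group pattern,tempo_bpm -o conditions.csv --tsv
bowcoord compare-estimators -i conditions.csv
```

Series CSVs carry a commented YAML metadata header (pattern, tempo,
ground-truth parameters, crossing-boundary levels). Feature CSVs have one
row per bow change; missing features are NaN with a reason code in
`flags`. Aggregated tables have one row per group with
`<feature>_mean` / `<feature>_sd` columns; `--tidy` melts them to one row
per feature and statistic.

## Conventions

Down-bow is positive velocity; inclination increases toward the
higher-pitched string; the crossing band is centered at 0 by default.
Relative phase is positive when the crossing of the band center precedes
the bow change. Percentiles use linear interpolation between order
statistics. Coverage ellipses are scaled by the chi-square(2) quantile so
the stated fraction of bivariate-normal data falls inside.
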