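# pbvent

Detection and quantification of exercise-induced periodic breathing (PB) in
breath-by-breath ventilation recordings from cardiopulmonary exercise tests.

The analysis chain:

1. **Pre-peak filtering** (`pbvent.mee_ve`) — select the 200 breaths before
   the global ventilation maximum, fit an AR(6) model with intercept by
   least squares, and discard every breath whose measured VE falls below
   0.8 × its one-step-ahead prediction (gasping exhalations are recorded by
   CPET hardware as runs of spuriously low breaths).
2. **Empirical mode decomposition** (`pbvent.emd_hht`) — sift the filtered
   signal into intrinsic oscillatory components plus a monotone residue;
   per-component analytic amplitude, phase and instantaneous frequency
   (cycles per breath) via the discrete analytic signal.
3. **White-noise significance screening** (`pbvent.significance`) — compare
   each component's (mean period, energy) pair against Monte-Carlo
   confidence curves simulated from unit-variance white noise decomposed by
   the same algorithm.
4. **Peak-count features and group comparison** (`pbvent.features_stats`) —
   count prominent oscillation peaks per component (topographic prominence
   ≥ 0.5 × RMS) and compare PB vs non-PB cohorts with two-sided two-sample
   Student's t-tests (pooled variance; Welch behind a flag).
5. **Synthetic CPET generator** (`pbvent.synthetic_cpet`) — labeled PB /
   non-PB breath-by-breath ventilation simulator (rate ramp 15→40
   breaths/min, rising-then-falling VE trend, multiplicative PB
   oscillation, lognormal noise, two-breath gasping artifacts) so the whole
   chain is testable offline.

A reference cohort of published per-subject peak counts (10 PB + 10 non-PB)
is bundled in `pbvent.datasets` for validating the statistics stage.

## CLI

```sh
# simulate a labeled cohort
pbvent simulate --n-pb 10 --n-npb 10 --seed 0 --outdir cohort/

# single-subject stages
pbvent filter cohort/pb0001.csv --out mee.csv --report removed.csv
pbvent decompose mee.csv --out imfs.csv --analytic-out analytic.csv
pbvent significance imfs.csv --n-null 500 --seed 0 --out sig.csv
pbvent features imfs.csv --subject-id pb0001 --label PB --out deltas.csv

# whole cohort, manifest-driven
pbvent run-all cohort/manifest.csv --out comparison.csv
```

`run-all` accepts a YAML config (`--config`) mirroring
`pbvent.pipeline.PipelineConfig` (window length `k`, AR order/threshold,
sifting and significance settings, seed).

## Layout

```
src/pbvent/
  series.py          BreathSeries record
  synthetic_cpet.py  ventilation simulator
  io_breath.py       series / manifest CSV dialect
  mee_ve.py          pre-peak window + AR filtering
  emd_hht.py         EMD and analytic-signal analysis
  significance.py    white-noise Monte-Carlo screening
  features_stats.py  peak counts and t-tests
  pipeline.py        orchestration and config
  cli.py             click-based CLI
  datasets.py        bundled reference peak counts
tests/               pytest suite (tests/test_acceptance.py holds the
                     acceptance criteria)
```
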