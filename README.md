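# patchkin

Single-channel patch-clamp analysis for mechanosensitive channels, with a
calibrated continuous-time Markov gating simulator.

`patchkin` is aimed at electrophysiologists characterising PIEZO1 variants
(wild type, familial loss-of-function mutants, a GWAS gain-of-function
mutant) from cell-attached recordings. It implements the complete
single-molecule workflow:

- **Simulation** — Gillespie (exact event time) sampling of shut ⇄ sub ⇄ open
  gating schemes, per-pressure rate matrices, Yoda1 agonist rate scaling, a
  pressure-gated inactivated state, and rendering into 10 kHz / 2 kHz
  acquisition-grade traces with Gaussian noise. Packaged variant profiles
  (`WT`, `R537C`, `R1398W`, `K2528R`, `P2536L`, `F2484L`, a WT+R1398W
  co-expression profile) are solved from target occupancies and mean
  lifetimes so their stationary behaviour equals the published group values.
- **Preprocessing** — zero-phase Butterworth low-pass filtering and
  histogram-mode shut-state baseline tracking.
- **Idealization** — all-point amplitude histograms, least-squares Gaussian
  (or two-sided exponential) peak mixtures, channel counting from stacked
  open peaks, Viterbi most-probable-path decoding under Gaussian emissions,
  and dead-time imposition.
- **Metrics** — open probability from peak areas, Po = A_o / (A_c + A_o); the
  multi-channel correction Po = (Σ_k k·f_k)/N; unitary currents; chord and
  slope conductance; per-state occupancy, mean lifetime, log-binned dwell
  histograms with exponential-mixture fits; elementary charge flux
  e/s = occupancy · |i| / e₀.
- **Ensemble kinetics** — aligned averaging of pressure-step recordings and
  single-exponential inactivation fits, I(t) = A·e^(−t/τ) + C.
- **Statistics** — group summaries (mean ± SD), unpaired two-tailed t-tests,
  one-way ANOVA with Bonferroni-adjusted pairwise comparisons, and rendered
  cohort reports.

## Worked example

```python
from patchkin import *

profile = load_profile("WT")
protocol = StimulusProtocol.constant(-30.0, 30_000.0)   # 30 s at -30 mmHg
trace, _ = simulate_recording(profile, protocol,
                              SimConfig(duration_ms=30_000.0, seed=1))
m = analyze_recording(trace)

fold, _ = pressure_fold_change(profile, n_cells=12, base_seed=1)
fit = ensemble_tau(profile, n_traces=5, base_seed=1)
```

which prints (via the obvious f-strings):

```
Po                 0.228
open current       -1.50 pA
sub current        -0.74 pA
conductance        25.0 pS
occupancy          shut 0.769, sub 0.074, open 0.157
mean lifetimes     shut 15.79 ms, sub 1.91 ms, open 5.07 ms
charge flux (e/s)  open 1.47e+06, sub 3.42e+05, total 1.82e+06
pressure fold      4.65
Ensemble inactivation fit over 5 traces
  tau       =    83.50 ms
```

Reading the numbers: at −30 mmHg the wild-type channel conducts 22.8% of the
time (Po), passing −1.5 pA when open (25 pS at −60 mV) with a ~−0.75 pA
sub-conductance level. The 4.65-fold rise in Po relative to the unpressurised
patch is the mechanosensitive response; the 83.5 ms τ is the macroscopic
inactivation time constant of the ensemble-averaged step response (distinct
from the 5 ms single-channel mean open time).

A thin CLI mirrors the workflow:

```sh
patchkin simulate --profile WT --pressure -30 --cells 12 --seed 7 --out traces/
patchkin metrics --in traces/ --out metrics.tsv
patchkin report --metrics metrics.tsv --group variant
```

## Layout

```
src/patchkin/
  scheme.py      kinetic schemes, stationary laws, rate calibration
  profiles.py    variant profiles (+ fixtures/*.yaml)
  simulate.py    Gillespie paths, trace rendering, cohorts
  preprocess.py  Butterworth filter, baseline correction
  idealize.py    amplitude mixtures, Viterbi, dead time
  metrics.py     Po, conductance, fold changes
  dwell.py       occupancy, lifetimes, dwell fits, charge flux
  ensemble.py    aligned averaging, inactivation fits
  stats.py       t-tests, ANOVA/Bonferroni, cohort reports
  pipeline.py    end-to-end workflows
  cli.py         typer CLI
docs/methods.md  model, calibration and analysis choices in detail
```
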