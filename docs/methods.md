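# Methods

## The gating model

Channel gating is a continuous-time Markov chain over a shut state, one
sub-conductance state and one open state; an inactivated state is appended
for pressure-step protocols. The generator matrix `Q` (s⁻¹) holds one rate
per ordered state pair; rows sum to zero. Conductance is attached to states
(0 pA shut/inactivated, −0.75 pA sub, −1.5 pA open at the −60 mV reference,
scaled linearly with voltage), so stimuli that act on gating never change
unitary currents.

Stimulus conditions are encoded as separate rate matrices per profile:

- **rest** (0 mmHg) and **pressure** (−30 mmHg): solved from target stationary
  occupancies and mean lifetimes (below).
- **yoda1**: the agonist multiplies the two opening rates out of the shut
  state (shut→sub, shut→open) by a factor solved numerically so the
  stationary Po rises by the profile's calibrated fold at −30 mmHg. Scaling
  opening rates models open-state stabilisation and leaves conductances
  untouched, matching the observation that the agonist changes gating only.
- **step**: a saturating fast-activation scheme (shut→open 3000 s⁻¹,
  open→shut 30 s⁻¹, small sub exchange) used for pressure-step peaks. Its
  stationary open occupancy is 0.989 and its relaxation time ≈ 0.3 ms, so
  activation is far faster than inactivation for every variant.
- Other pressures in the −10…−50 mmHg sweep interpolate each rate
  geometrically in |P| between the two calibrated anchors (an exponential
  rate-scaling model); pressures beyond −30 mmHg extrapolate the same law.

**Inactivation.** The inactivated state is entered from open at rate
1/τ_inact while pressure is applied, and recovers to shut at 1 s⁻¹ only at
rest. During a sustained step the state is therefore absorbing and the
ensemble-averaged current decays as a single exponential with rate
π_open·(1/τ_inact) ≈ 1/τ_inact (π_open = 0.989 under the step scheme, a +1%
bias). A recovery rate acting during the step would add itself to the decay
rate and bias the fitted τ downward by ~τ·k_rec (4–10% here), so recovery is
deliberately confined to rest. Steady-state cohorts are simulated without
the inactivated state: they represent the post-adaptation activity from
which open probability is measured on 15–30 s stretches, not the initial
peak response.

## Calibrating rates from measurable targets

`calibrate_rates_to_targets` solves the inverse problem: given stationary
occupancies π and mean lifetimes L (exit rate r = 1/L) for shut/sub/open,
find a nonnegative generator with exactly those margins. For the three-state
scheme the stationary conditions plus the three exit-rate constraints leave a
one-parameter family indexed by the shut→open rate; the solver takes the
midpoint of its feasible interval (the choice only reroutes flux between the
direct and the via-sub pathway and does not affect occupancies or
lifetimes). Feasibility is exactly the set of flux conditions
π_s·r_s ≤ Σ_{s'≠s} π_{s'}·r_{s'}; a violated state is named in the error.
Detailed balance is *not* imposed — several published per-variant
occupancy/lifetime combinations are only realisable by a non-reversible
chain. For two states, one lifetime may be omitted and is recovered from
flux balance.

### Variant profiles

Each fixture stores the targets, τ_inact, and the Yoda1 Po fold. The
published characterisation provides *relative* quantities (fold changes, τ values,
occupancy/lifetime orderings) but not absolute Po per condition, so absolute
levels were fixed once at values typical of cell-attached PIEZO1 work
(resting Po of a few percent; WT Po 0.23 at −30 mmHg) and the per-variant
pressure and agonist folds were then made exact by construction:

| profile | Po rest | Po −30 | fold | τ_inact (ms) | Yoda1 fold |
|---|---|---|---|---|---|
| WT      | 0.050 | 0.230 | 4.6 | 90.2 | 2.0 |
| R537C   | 0.030 | 0.105 | 3.5 | 88.0* | 1.5 |
| R1398W  | 0.025 | 0.035 | 1.4 | 58.5 | 3.0 |
| K2528R  | 0.030 | 0.051 | 1.7 | 52.5 | 4.0 |
| P2536L  | 0.035 | 0.077 | 2.2 | 85.0* | 2.5 |
| F2484L  | 0.100 | 0.320 | 3.2 | 121.6 | — |

(*inactivation was not characterised for these variants; wild-type-like
defaults are used.) Occupancy splits and lifetimes follow the reported
qualitative fingerprints: familial mutants have higher shut occupancy,
lower sub and open occupancy, and longer shut lifetimes (longest for
R1398W, which also has the shortest sub lifetime); the gain-of-function
F2484L has lower shut occupancy, higher open occupancy and a longer open
lifetime. A `WT_R1398W_coexp` profile encodes the dominant-negative
co-expression result as mutant-like activity; no heteromer stoichiometry is
modelled.

## Simulation and rendering

Paths are sampled with exact event times within each pressure segment
(piecewise-constant rates; the state carries across boundaries), starting
from the stationary law of the first segment. Rendering sums the per-channel
state currents at the sample times, adds white Gaussian noise
(σ = 0.15 pA default, chosen so the −1.5 pA open level sits ≈10 filtered-σ
from shut, matching visually clean published traces), and applies a causal
4th-order Butterworth at 2 kHz as the acquisition filter (10 kHz sampling).
The first 5/f_c seconds are flagged as filter burn-in. Path and noise
streams are seeded independently, so changing only the noise level never
changes the underlying gating path; cohorts use seeds
`base_seed … base_seed+n−1`.

What the generator does *not* emulate: open-channel excess noise, 1/f and
line noise, seal drift other than what `baseline_correct` is tested against,
capacitive transients, heteromeric channels, and tension-dependence beyond
the per-pressure rate tables. Pipeline accuracy on these traces therefore
bounds, but does not guarantee, accuracy on bench data.

## Analysis chain

1. **Filter**: zero-phase (forward–backward) Butterworth, order 4. Zero phase
   is the default because a causal pass delays transitions by the group
   delay and skews dwell durations. Presets: 2 kHz ("acquisition") used
   throughout; 20 Hz ("substate"), a heavy smoothing preset that destroys
   millisecond dwells and is never used before dwell analysis.
2. **Baseline**: the shut level is the mode of the densest amplitude-
   histogram peak in 500 ms windows (50% overlap), interpolated linearly and
   subtracted. A mode is immune to openings occupying a minority of time, so
   shut/open peak spacing is preserved (verified to <1%).
3. **Amplitude model**: least-squares Gaussian-peak mixture fitted to the
   all-point histogram (0.02 pA bins, Poisson weights). Components are
   seeded at the expected levels (0, u/2, u from the known unitary current)
   when available, else at detected peaks; a two-sided-exponential peak
   backend exists as an alternative for log-scale histograms. Areas are
   normalised; the component nearest 0 pA is shut.
4. **Channel count**: N = largest k with a fitted component at ≈ k·u
   (tolerance 25% of u). Sub-levels at u/2 match no integer multiple. A
   stacked-opening probe (samples beyond 1.5·u) widens the mixture to four
   components before counting. Patches with no conducting peak report N = 1
   with a no-openings flag.
5. **Idealization**: Viterbi decoding under Gaussian emissions with a shared
   SD taken from the shut component (open-channel noise is not modelled).
   Self-transition probability defaults to 1 − Δt/5 ms per state, remaining
   mass split uniformly; transition probabilities are fixed (single pass, no
   EM re-estimation). Dwells shorter than the dead time (0.3/f_c ≈ 0.15 ms,
   the filter rise time) are merged into their longer neighbour.
6. **Metrics**: Po = A_o/(A_c+A_o) with sub counted as conducting by default
   (configurable); for N > 1 the reported Po is (Σ_k k·f_k)/N over decoded
   summed levels. Occupancy includes censored edge dwells; mean lifetimes
   exclude them and use the truncated-exponential estimator
   mean(d | d ≥ c) − c with c = 0.8/f_c (0.4 ms at 2 kHz), which is unbiased
   for exponential dwells and rejects the sub-resolution artifact dwells
   that filtered transitions through the intermediate level leave behind.
   Charge flux is e/s = occupancy·|i|/e₀ (the conditional, occupancy-free
   variant is available); conductances are reported as magnitudes.

## Ensemble inactivation

Five step recordings (150 ms rest, 700 ms at −30 mmHg) are aligned at the
step onset and averaged; I(t) = A·e^(−t/τ) + C is fitted from the post-onset
peak (extremum within 50 ms of onset) to the step end, initialised from a
log-linear fit. Each recording is a multi-channel macro-patch of 150
channels: the averaged decay is an empirical survival curve over
5 × 150 = 750 inactivation events, putting the sampling SE of τ̂ near 4%;
with 1–3 channels per patch (the single-channel configuration) τ̂ would
carry 25–30% error and be uninterpretable at the precision the study
reports. Fits with τ > 10× the window or amplitude below 3× the local noise
are flagged "no inactivation".

## Statistics

Group data are summarised as mean ± SD. Two-group comparisons use the
pooled-variance unpaired two-tailed t-test (Welch behind a flag — the
classical test is the default to match standard practice); three or more
groups get one-way ANOVA plus pairwise t-tests with Bonferroni adjustment
min(1, m·p). Cohort fold change is the ratio of group-mean Po values rather
than the mean of per-cell ratios, which is robust to cells with near-zero
resting Po. Stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.

## Numerical choices and degenerate inputs

- Stationary laws solve the augmented least-squares system [Qᵀ; 1]π = e,
  clipped and renormalised; disconnected or all-zero schemes raise.
- Boundary-feasible calibration targets (flux equality) collapse the
  feasible interval to a point rather than failing.
- Amplitude fits fall back to the detected peak count (with a warning) when
  fewer peaks exist than requested; degenerate components (vanishing area or
  duplicated location) are flagged and excluded from conducting-area sums.
- Exponential-mixture dwell fits with fewer than 5 dwells per parameter fall
  back to the single-component closed form.
- The Viterbi kernel is an O(T·K²) numba routine; ties are broken toward the
  lower state index, identically to the brute-force oracle it is tested
  against.
- All simulations are reproducible from a single integer seed; derived
  stream keys stay below 2³¹.

## Problem sizes

Cohort analyses use 12 recordings × 30 s per condition (8 for R1398W and
K2528R, matching the study's replica counts), ensemble fits 5 × 0.85 s
macro-patch recordings, and property tests use short synthetic sequences
(T ≤ 8 for exhaustive Viterbi enumeration, 10⁴ replicates for test
calibration). These sizes give sub-minute end-to-end runs while keeping
Monte-Carlo error well inside the tolerances quoted above.

## Known limitations

- No missed-event (first-order dead-time) correction of rate constants and
  no maximum-likelihood kinetic fitting of the full scheme.
- Multi-channel idealization works on summed levels; sub-conductance levels
  of individual channels in a stack are conflated with full openings of
  another channel (one sub-level per patch is assumed dominant).
- The e/s definition (occupancy-scaled) and the NPo/N multi-channel
  correction are declared conventions; alternatives are computed but not
  primary.
- Whether the 20 Hz substate-filter figure in the source workflow is a
  typo for 2 kHz cannot be resolved; both presets exist and no intent is
  guessed.
- The Yoda1 mechanism (which rates the agonist scales) is a modelling
  choice; only its stationary Po effect is constrained by data.
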