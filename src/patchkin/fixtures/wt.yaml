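# Wild-type mouse PIEZO1 gating profile (cell-attached, -60 mV reference).
# Condition targets are stationary occupancies and mean lifetimes of the
# shut / sub-conductance / open states; transition rates are solved from them
# at load time.  Po (= sub + open occupancy) rises 4.6-fold from rest to
# -30 mmHg; Yoda1 doubles Po at -30 mmHg.
name: WT
label: wild-type PIEZO1
open_current_pA: -1.5
sub_current_pA: -0.75
reference_voltage_mV: -60.0
tau_inact_ms: 90.2
recovery_rate_per_s: 1.0
yoda1_po_fold: 2.0
conditions:
  rest:
    pressure_mmHg: 0
    occupancy: {shut: 0.950, sub: 0.020, open: 0.030}
    mean_lifetime_ms: {shut: 60.0, sub: 1.5, open: 4.0}
  pressure:
    pressure_mmHg: -30
    occupancy: {shut: 0.770, sub: 0.070, open: 0.160}
    mean_lifetime_ms: {shut: 15.0, sub: 2.0, open: 5.0}
# Saturating fast-activation scheme used for pressure-step (peak) responses:
# open occupancy ~0.99 within ~1 ms of the step, so the ensemble decay time
# constant equals tau_inact to ~1%.
step_rates_per_s:
  shut->open: 3000.0
  open->shut: 30.0
  shut->sub: 100.0
  sub->shut: 1000.0
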