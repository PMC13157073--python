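# p.K2528R familial loss-of-function profile: weak pressure response
# (1.7-fold), long shut lifetime, fast ensemble inactivation (tau 52.5 ms).
# Strongest Yoda1 rescue among the familial variants (4-fold Po increase).
name: K2528R
label: p.K2528R (familial, loss-of-function)
open_current_pA: -1.5
sub_current_pA: -0.75
reference_voltage_mV: -60.0
tau_inact_ms: 52.5
recovery_rate_per_s: 1.0
yoda1_po_fold: 4.0
conditions:
  rest:
    pressure_mmHg: 0
    occupancy: {shut: 0.970, sub: 0.012, open: 0.018}
    mean_lifetime_ms: {shut: 90.0, sub: 1.5, open: 4.0}
  pressure:
    pressure_mmHg: -30
    occupancy: {shut: 0.949, sub: 0.016, open: 0.035}
    mean_lifetime_ms: {shut: 65.0, sub: 1.8, open: 4.8}
step_rates_per_s:
  shut->open: 3000.0
  open->shut: 30.0
  shut->sub: 100.0
  sub->shut: 1000.0
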