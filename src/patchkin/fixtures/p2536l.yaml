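# p.P2536L familial loss-of-function profile: attenuated pressure response
# (2.2-fold) and longer shut lifetime.  Inactivation was not characterised for
# this variant; tau_inact defaults to a wild-type-like value.
name: P2536L
label: p.P2536L (familial, loss-of-function)
open_current_pA: -1.5
sub_current_pA: -0.75
reference_voltage_mV: -60.0
tau_inact_ms: 85.0
recovery_rate_per_s: 1.0
yoda1_po_fold: 2.5
conditions:
  rest:
    pressure_mmHg: 0
    occupancy: {shut: 0.965, sub: 0.014, open: 0.021}
    mean_lifetime_ms: {shut: 80.0, sub: 1.5, open: 4.0}
  pressure:
    pressure_mmHg: -30
    occupancy: {shut: 0.923, sub: 0.022, open: 0.055}
    mean_lifetime_ms: {shut: 45.0, sub: 1.8, open: 5.0}
step_rates_per_s:
  shut->open: 3000.0
  open->shut: 30.0
  shut->sub: 100.0
  sub->shut: 1000.0
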