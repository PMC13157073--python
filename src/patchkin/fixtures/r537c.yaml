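# p.R537C familial loss-of-function profile: reduced Po at both pressures
# (3.5-fold pressure response), longer shut lifetime, reduced sub occupancy.
# Inactivation was not characterised for this variant; tau_inact defaults to a
# wild-type-like value.
name: R537C
label: p.R537C (familial, loss-of-function)
open_current_pA: -1.5
sub_current_pA: -0.75
reference_voltage_mV: -60.0
tau_inact_ms: 88.0
recovery_rate_per_s: 1.0
yoda1_po_fold: 1.5
conditions:
  rest:
    pressure_mmHg: 0
    occupancy: {shut: 0.970, sub: 0.012, open: 0.018}
    mean_lifetime_ms: {shut: 90.0, sub: 1.5, open: 4.0}
  pressure:
    pressure_mmHg: -30
    occupancy: {shut: 0.895, sub: 0.030, open: 0.075}
    mean_lifetime_ms: {shut: 30.0, sub: 1.8, open: 5.0}
step_rates_per_s:
  shut->open: 3000.0
  open->shut: 30.0
  shut->sub: 100.0
  sub->shut: 1000.0
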