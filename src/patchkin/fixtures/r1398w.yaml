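# p.R1398W familial loss-of-function profile: the most severely impaired
# pressure response (1.4-fold), markedly longer shut lifetime, shorter sub
# lifetime, and the fastest ensemble inactivation among the familial variants
# tested (tau 58.5 ms).  Yoda1 triples Po at -30 mmHg.
name: R1398W
label: p.R1398W (familial, loss-of-function)
open_current_pA: -1.5
sub_current_pA: -0.75
reference_voltage_mV: -60.0
tau_inact_ms: 58.5
recovery_rate_per_s: 1.0
yoda1_po_fold: 3.0
conditions:
  rest:
    pressure_mmHg: 0
    occupancy: {shut: 0.975, sub: 0.010, open: 0.015}
    mean_lifetime_ms: {shut: 100.0, sub: 1.2, open: 4.0}
  pressure:
    pressure_mmHg: -30
    occupancy: {shut: 0.965, sub: 0.012, open: 0.023}
    mean_lifetime_ms: {shut: 80.0, sub: 1.2, open: 4.5}
step_rates_per_s:
  shut->open: 3000.0
  open->shut: 30.0
  shut->sub: 100.0
  sub->shut: 1000.0
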