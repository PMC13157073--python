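# p.F2484L gain-of-function profile (GWAS allele): elevated Po at rest and at
# -30 mmHg (3.2-fold pressure response), shorter shut lifetime, longer open
# lifetime, and slowed ensemble inactivation (tau 121.6 ms).  Yoda1 was not
# assayed on this gain-of-function variant (yoda1_po_fold null).
name: F2484L
label: p.F2484L (GWAS, gain-of-function)
open_current_pA: -1.5
sub_current_pA: -0.75
reference_voltage_mV: -60.0
tau_inact_ms: 121.6
recovery_rate_per_s: 1.0
yoda1_po_fold: null
conditions:
  rest:
    pressure_mmHg: 0
    occupancy: {shut: 0.900, sub: 0.030, open: 0.070}
    mean_lifetime_ms: {shut: 35.0, sub: 1.4, open: 5.0}
  pressure:
    pressure_mmHg: -30
    occupancy: {shut: 0.680, sub: 0.070, open: 0.250}
    mean_lifetime_ms: {shut: 10.0, sub: 1.4, open: 7.5}
step_rates_per_s:
  shut->open: 3000.0
  open->shut: 30.0
  shut->sub: 100.0
  sub->shut: 1000.0
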