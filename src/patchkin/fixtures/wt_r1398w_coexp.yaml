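# WT + p.R1398W co-expression profile.  Co-expressed patches behave like the
# mutant alone (dominant-negative): Po, occupancies and lifetimes are set
# mutant-like, marginally above the pure mutant to reflect the residual
# WT-homotrimer fraction.  No heteromeric stoichiometry is modelled.
name: WT_R1398W_coexp
label: WT co-expressed with p.R1398W (dominant negative)
open_current_pA: -1.5
sub_current_pA: -0.75
reference_voltage_mV: -60.0
tau_inact_ms: 62.0
recovery_rate_per_s: 1.0
yoda1_po_fold: null
conditions:
  rest:
    pressure_mmHg: 0
    occupancy: {shut: 0.972, sub: 0.011, open: 0.017}
    mean_lifetime_ms: {shut: 95.0, sub: 1.2, open: 4.0}
  pressure:
    pressure_mmHg: -30
    occupancy: {shut: 0.955, sub: 0.014, open: 0.031}
    mean_lifetime_ms: {shut: 70.0, sub: 1.3, open: 4.5}
step_rates_per_s:
  shut->open: 3000.0
  open->shut: 30.0
  shut->sub: 100.0
  sub->shut: 1000.0
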