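# HEK-293 (human embryonic kidney) whole-cell preset. Step families show
# K+ channel activity only, so the Na+ conductance is zero.
label: HEK-293 whole cell
r_seal_mohm: 1000.0
c_m_pf: 30.0
c_pipette_pf: 3.0
r_opamp_mohm: 0.0
e_k_mv: -90.0
e_na_mv: 60.0
e_other_mv: 0.0
compensate_pipette: true
gating:
  k: {g_max_us: 0.05, v_half_mv: -20.0, slope_mv: 10.0, tau_act_ms: 5.0}
  na: {g_max_us: 0.0}
  other_g_us: 0.0
injection:
  e_injection_mv: -0.3
  mean_drop_na: -11.7
  event_sd_na: 0.4
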