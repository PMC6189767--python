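# Bath (extracellular) solution, salts in mM. Glucose and HEPES do not
# dissociate; NaOH pH adjustment (to 7.4) is unquantified and ignored.
label: extracellular bath solution
temperature_k: 298.15
salts_mm:
  NaCl: 160
  KCl: 4.5
  MgCl2: 1
  CaCl2: 2
  glucose: 5
  HEPES: 10
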