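# Pipette (intracellular) solution, salts in mM. HEPES and EGTA do not
# dissociate; KOH pH adjustment (to 7.2-7.4) is unquantified and ignored.
label: intracellular pipette solution
temperature_k: 298.15
salts_mm:
  KCl: 75
  NaCl: 10
  KF: 70
  MgCl2: 2
  HEPES: 10
  EGTA: 10
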