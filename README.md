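# cytoclamp

Equivalent-circuit simulation and current-feedback analysis for the
cytoplasmic microinjection of small adherent cells (diameter < 30 µm,
e.g. SHSY-5Y neuroblastoma or HEK-293 kidney cells) under whole-cell
voltage clamp.

Pipette-based injection of such cells is hard to automate because the
moment of penetration and delivery is nearly invisible optically. An
electrical alternative: patch the cell, hold the membrane at −70 mV, and
watch the clamp current. Delivering a bolus of intracellular solution
shifts the cytoplasmic ion concentrations, which shifts the membrane
battery by an *injection potential* and produces a **permanent drop in
holding current** — a threshold on that drop (≈ −11 nA) is a success
signal a controller can act on. Afterward, a family of voltage steps
verifies the cell is still alive from its ion-channel currents.

`cytoclamp` provides, for electrophysiologists and micro-robotics
researchers prototyping such controllers:

- **ionics** — salt-recipe dissociation, Nernst potentials
  E = (RT/zF)·ln([ion]ₒ/[ion]ᵢ), the additive multi-ion membrane battery,
  conservative bolus mixing, and E_Injection = E_membrane(new) − E_membrane(old);
- **circuit** — the cell+pipette equivalent circuit (R_Seal, R_Access,
  C_M, C_Pipette, gated K⁺/Na⁺ branches with Nernst batteries, the
  injection branch) integrated exactly per piecewise-constant command,
  with the sample-wise identities
  I_m = I_Pipette + I_Seal + I_C + I_Access and
  I_Access = I_Na + I_K + I_Other + I_Injection;
- **protocol** — the five-stage patch/injection procedure as a stage
  machine plus a seeded synthetic-experiment generator with ground truth;
- **analysis** — test-pulse resistance estimation, baseline zeroing,
  permanent-step (injection-drop) detection, access-pair calibration
  R_Access = E_Injection / drop, K⁺/Na⁺ viability classification, and the
  threshold control loop;
- **traceio / cli** — a plain CSV+JSON trace format and a thin
  `cytoclamp` command-line wrapper (`nernst`, `simulate`, `detect`,
  `verify`, `calibrate`).

## Worked example

Simulate one injection episode with the SHSY-5Y preset and detect the
drop (`examples/02_simulate_injection_episode.py`):

```python
from cytoclamp import analysis, presets, protocol

preset = presets.load_circuit_preset("shsy5y")
script = protocol.injection_script(
    n_events=1, seed=1,
    noise=protocol.NoiseModel(gaussian_sd_na=0.05, event_sd_na=0.2),
)
exp = protocol.run_experiment(script, preset.params)
det = analysis.detect_injection_drops(exp.holding_trace())
```

prints

```
detected step at 99.8 ms: -11.43 nA
accumulated drop: -11.41 nA
success at the -11 nA threshold: True
```

The step is the permanent offset E_Injection/R_Access switched in at the
scripted event (99.8 vs the scripted 100 ms is half a detector window);
its size is the preset's calibrated −11.9 nA perturbed by the 0.2 nA
per-event spread, and it crosses the −11 nA success threshold. The other
scripts in `examples/` walk the recipe → injection-potential chain, seal
formation, the viability step family, and the retry/success control loop.

The same episode from the shell:

```sh
cytoclamp simulate --preset shsy5y --seed 1 --out episode.csv
cytoclamp detect episode.csv        # exit 0 on success, 2 otherwise
cytoclamp verify --preset hek293 --seed 2
```

## Layout

- `src/cytoclamp/` — the library (primary interface)
- `src/cytoclamp/presets/` — shipped solution recipes
  (`extracellular.cfg`, `intracellular.cfg`) and circuit presets
  (`shsy5y.cfg`, `hek293.cfg`)
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model, assumptions, parameters and numerical choices
- `tests/` — pytest suite (unit, property and end-to-end checks)
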