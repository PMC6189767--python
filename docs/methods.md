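# Methods

## The model

A small adherent cell held by a patch pipette in whole-cell configuration
is represented as a lumped two-node circuit. The clamp amplifier is an
ideal voltage source (series output resistance `R_OpAmp`, default 0)
driving the pipette node. From that node to bath ground run:

- the **seal path** `R_Seal` (leak around the pipette rim; default
  1000 MΩ, a gigaseal). The seal "switch" is conventionally open — the
  seal is never a deliberate conduction path — but the leak it represents
  is always simulated through the finite `R_Seal`; setting `R_Seal = ∞`
  recovers the idealized open circuit.
- the **pipette capacitance** `C_Pipette` (default 3 pF), which produces
  the edge transients `C·dV/dt`. A boolean compensation option subtracts
  this term exactly, mirroring amplifier capacitance neutralization; the
  shipped whole-cell presets compensate.
- the **access path** `R_Access` into the membrane node, which carries the
  membrane capacitance `C_M` (default 30 pF) and the ionic branches. Each
  channel branch is a conductance in series with its Nernst battery
  (E_K = −90 mV, E_Na = +60 mV by default); a fixed "other ions" leak
  conductance defaults to 0 because its current is negligible next to the
  K⁺/Na⁺ currents. A separate **injection branch** — battery `E_Injection`
  in series with the access resistance — switches in at injection events
  and carries the permanent current `E_Injection / R_Access`.

The measured current decomposes as
`I_m = I_Pipette + I_Seal + I_C + I_Access` and
`I_Access = I_K + I_Na + I_Other + I_Injection`. Both identities hold
sample-wise by construction (`I_C` is computed as the access-resistor
current minus the ionic branch currents, which is exactly the charging
current of the membrane node), so `decompose_currents` reports a residual
at floating-point level; the tests assert it.

At rest under a constant holding command the channel conductances are
essentially shut and `I_C = 0`, so the whole holding current reduces to
`E_Injection / R_Access` plus the constant seal leak — the **permanent
current drop** that signals a delivered bolus. Because the injection
branch is independent of the membrane node, the drop superposes linearly
on the holding current; the simulator preserves that superposition
exactly and a test asserts it.

### Electrochemistry

Recipes are expanded stoichiometrically into free-ion concentrations
(mM); glucose, HEPES, EGTA and the unquantified pH-adjustment bases are
skipped with a logged note. The Nernst potential uses
R = 8.314472 J K⁻¹ mol⁻¹ and F = 9.648533 × 10⁴ C mol⁻¹; the multi-ion
membrane battery is the plain additive sum of per-ion Nernst terms (not a
conductance-weighted GHK form) — callers exclude negligible ions
explicitly via the ion list. Injection mixing is instantaneous and
conservative: `c_new = (c_cyto·V_cell + c_inj·V_inj)/(V_cell + V_inj)`,
bath unchanged. Default temperature 298.15 K (room temperature),
default cell volume 2.5 pL (an ellipsoid bounded by a < 30 µm diameter
and < 10 µm thickness), both configurable.

Activity coefficients, ionic-strength corrections, buffer binding and
osmotic volume changes are out of scope.

### Gating

The model needs channel branches whose resistance falls when channels
activate; the kinetics are the package's own choice, selected to
reproduce the qualitative step-family signatures of these cell lines
(sustained outward K⁺ current at depolarized steps; a fast transient
inward Na⁺ current at intermediate steps that disappears when cytoplasmic
Na⁺ is redistributed by injection):

| gate | form | V½ (mV) | slope (mV) | τ (ms) |
|---|---|---|---|---|
| K⁺ activation n | Boltzmann | −20 | 10 | 5 |
| Na⁺ activation m | Boltzmann | −25 | 6 | 0.3 |
| Na⁺ inactivation h | Boltzmann | −60 | −7 | 3 |

K⁺ conductance is `g_max·n`, Na⁺ is `g_max·m·h`. Preset maxima are
0.05 µS (K) and 0.08 µS (Na, zero in the HEK-293 preset, whose step
families show K⁺ activity only); these give peak currents of a few nA,
typical of whole-cell recordings from such cells. All parameters are
configurable per preset file.

## Numerical integration

Units are the self-consistent electrophysiology set mV / nA / MΩ / pF /
ms (mV/MΩ = nA; MΩ·pF = µs, converted explicitly). Commands are
piecewise-constant, so the linear part of the circuit has an exact
single-exponential solution per segment: the membrane node is advanced
with the exact exponential update toward `V_∞ = (g_a·V_cmd + Σg·E)/Σg`
with `τ = C_M/Σg`, branch conductances frozen at their start-of-step
values, and the gates advanced by their own exact first-order update.
With no gated branch active the solution is exact at any dt and is
evaluated vectorized; with gating active the only resolution limit is the
gating kinetics, and the simulator refuses dt larger than half the
smallest active time constant, naming it. Defaults: dt = 0.01 ms for
single-step transients and step families, 0.1 ms (10 kHz) for full
experiments — acquisition-rate-like values chosen by the package, as no
rate is inherent to the model.

Convergence and correctness are pinned by tests: agreement with the
closed-form RC response within 1 % at every sample (independent analytic
oracle), transferred charge `C_M·ΔV` within 1 %, dt-halving changes below
0.5 % of the dynamic range, branch currents reversing exactly at their
batteries, and gates confined to [0, 1]. The capacitive plateau bound
(|I_C| < 0.1 % of the edge peak) is asserted from 10 τ after an edge —
at 5 τ a single exponential still retains e⁻⁵ ≈ 0.7 % of its peak, so a
5 τ plateau cannot meet a 0.1 % bound.

## Calibration and presets

The bench observable is the accumulated drop: −11.9 ± 0.2 nA (SHSY-5Y)
and −11.7 ± 0.4 nA (HEK-293), with an injection potential estimated near
−0.3 mV. `calibrate_access_pair` inverts drop = E_Injection/R_Access;
the pair implied by the printed values is ≈ 0.0252 MΩ, far below the
4–8 MΩ bath pipette resistance. The calibration surfaces this tension as
a logged warning rather than resolving it, and the shipped presets store
the battery and the drop, deriving the access resistance at load time —
no drop value is hard-coded in the simulator. The accumulated drop is
treated as the per-episode total; scripts make the event count explicit.

## The synthetic-experiment generator

`run_experiment` emulates the recording a rig would produce: stage
segments (bath / contact / gigaseal run the 20 mV, 10 ms test pulse
train; whole-cell stages hold at −70 mV), seeded stage resistances
(bath uniform on 4–8 MΩ; contact adds uniform 3–5 MΩ; seal 1 GΩ),
injection events as permanent offsets (optionally with a τ = 2 ms
exponential onset, reflecting the few-millisecond observed response),
baseline zeroing over the first 20 ms of the whole-cell stage (the bench
zeroes before injecting), and a noise model. Noise defaults: white
Gaussian 0.05 nA per sample and zero drift, chosen so the published
per-event spreads (0.2/0.4 nA, supplied as the per-event amplitude sd)
dominate the episode statistics; all configurable. Randomness uses one
spawned stream per purpose (stage resistances, event amplitudes, sample
noise), so consuming one stream never shifts the others, and identical
(script, seed) pairs give bit-identical traces.

What the generator does **not** emulate: capacitive-transient ringing and
amplifier filtering, line interference, slow seal degradation, biological
rundown, series-resistance voltage errors under large currents, and any
fluidics (pressure steps are just stage transitions). Tests passing on
this generator therefore validate the analysis algorithms against the
model's own assumptions — they are consistency checks of the
simulate/measure round trip, not evidence about real recordings, which
were never deposited.

## Analysis choices

- **Drop detector** (the bench never specified one; this is a defined
  surrogate): difference of trailing and leading 5 ms window means
  separated by a 1 ms gap, declared a step when it exceeds 6× the robust
  noise sd and the level change persists ≥ 10 ms; the accumulated drop is
  final minus initial steady level, and success means accumulated drop ≤
  threshold (−11 nA default; "lower than threshold" is read as
  more-negative-than, matching the downward steps). Noise sd comes from
  the MAD of the first-difference signal, which is immune to the very
  steps being detected; a small sd floor (0.005 nA) keeps the rule
  defined on noise-free traces. All window lengths are parameters.
- **Resistance estimator**: R = amplitude / ΔI with ΔI from plateau means
  (last 20 % of each pulse, excluding the capacitive transient) minus
  pre-pulse baseline means, averaged over every complete pulse in the
  trace. Below the noise floor (3× the sem of ΔI) a lower bound
  amplitude/floor is reported instead of a point estimate. Recovering a
  1 GΩ seal to 10 % at 0.2 nA noise requires averaging ≈ 3000 pulses
  (the plateau response is only 0.02 nA); the property test uses a
  3200-pulse train for that reason.
- **Viability classifier**: per step, currents are referenced to the
  pre-step holding baseline; the capacitive window after each edge
  (10·R_Access·C_M from trace metadata, else 2 ms) is excluded. K⁺ is
  active when the late-window (last 20 ms) mean is outward, exceeds 5×
  the noise sd at the most depolarized step and grows monotonically over
  the top three levels; Na⁺ when an early-window (first 5 ms) inward peak
  exceeds 5× sd at intermediate levels. The verdict is viable iff K⁺ is
  active (sustained K⁺ activity is the viability criterion). A noise-sd
  floor of 0.05 nA keeps the 5× rule meaningful on noise-free traces,
  where the ~0.2 nA seal-leak slope could otherwise masquerade as K⁺
  current. No multiple-testing correction is applied across levels — the
  read-out is deliberately the qualitative present/absent judgment an
  operator makes. Fewer than three levels is an error (monotonicity is
  untestable).
- **Control loop**: drops accumulate across attempts and the loop stops
  at the first threshold crossing; upstream positioning/patching are
  opaque pre-satisfied steps.

## Known limitations

- The additive Nernst-sum battery is not a steady-state flux model (no
  GHK); it is the model's stated form and the injection potential
  inherits its idealizations.
- The −0.3 mV / −11.9 nA calibration implies an access resistance two
  orders of magnitude below the pipette's bath resistance; the package
  exposes the inconsistency (warning) but cannot resolve it from the
  available numbers.
- Gating kinetics are plausible stand-ins, not fits to any recording;
  only the qualitative step-family signatures are meaningful.
- The detector assumes a constant holding command over the analyzed span
  and well-separated events (closer than the persistence window they
  merge).
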