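"""The five-stage microinjection procedure and a seeded experiment generator.

The wet-lab procedure is modeled as a forward-only stage machine: pipette
in the bath, approach/contact with the cell, gigaseal formation, whole-cell
holding at the holding potential, injection, and post-injection
observation. Each stage maps the base circuit to a stage-specific one
(pre-break-in stages are resistor-only as seen from the amplifier);
:func:`run_experiment` concatenates the simulated stages, applies the
seeded noise model and returns the trace together with complete ground
truth, standing in for recordings that were never deposited.

Randomness uses one named stream per purpose (stage resistances, event
amplitudes, sample noise), spawned from the script seed, so changing one
consumer never shifts the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Sequence

import numpy as np

from . import ionics
from .circuit import CircuitParameters, SimulatedTrace, simulate_voltage_clamp
from .core import CurrentTrace, VoltageProtocol

__all__ = [
    "Stage",
    "NoiseModel",
    "TestPulse",
    "InjectionEvent",
    "ExperimentScript",
    "SyntheticExperiment",
    "stage_parameters",
    "step_family",
    "run_experiment",
    "run_step_family",
    "injection_script",
]

#: Pipette resistance range measured with the tip in the bath, MOhm.
BATH_RESISTANCE_RANGE_MOHM = (4.0, 8.0)
#: Resistance increase on cell contact, MOhm.
CONTACT_INCREMENT_RANGE_MOHM = (3.0, 5.0)


class Stage(Enum):
    """Forward-only stages of the microinjection procedure."""

    BATH = 0
    APPROACH = 1
    SEALED = 2
    WHOLE_CELL_HOLDING = 3
    INJECTING = 4
    POST_INJECTION = 5


#: Stages during which injection events are admissible.
_INJECTABLE = {Stage.WHOLE_CELL_HOLDING, Stage.INJECTING, Stage.POST_INJECTION}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement/biological noise applied by the generator.

    ``gaussian_sd_na`` is per-sample white noise; ``drift_na_per_s`` a
    linear baseline drift; ``event_sd_na`` the episode-to-episode spread of
    injection-drop amplitudes (``None`` defers to the circuit preset).
    """

    gaussian_sd_na: float = 0.05
    drift_na_per_s: float = 0.0
    event_sd_na: float | None = None

    def __post_init__(self) -> None:
        if self.gaussian_sd_na < 0 or self.drift_na_per_s < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.event_sd_na is not None and self.event_sd_na < 0:
            raise ValueError("event sd must be >= 0")


@dataclass(frozen=True)
class TestPulse:
    """The seal-test pulse: amplitude above baseline, repeated periodically."""

    amplitude_mv: float = 20.0
    duration_ms: float = 10.0
    period_ms: float = 50.0
    baseline_mv: float = 0.0

    def protocol(self, total_ms: float) -> VoltageProtocol:
        if self.duration_ms >= self.period_ms:
            raise ValueError("pulse duration must be shorter than its period")
        reps = max(int(total_ms // self.period_ms), 1)
        segs = (
            (self.baseline_mv, self.period_ms - self.duration_ms),
            (self.baseline_mv + self.amplitude_mv, self.duration_ms),
        )
        return VoltageProtocol(segs, repeat=reps)


@dataclass(frozen=True)
class InjectionEvent:
    """One injection: when, and how the drop amplitude is determined.

    Amplitude resolution order: explicit ``amplitude_na``; else an
    ``injectate`` composition plus volume (the injection potential is then
    computed from the script's bath/cytoplasm compositions and divided by
    the access resistance); else the preset pair ``E_Injection/R_Access``.
    The resolved amplitude is perturbed by the per-event sd.
    """

    time_ms: float
    volume_pl: float = 19.0
    injectate: ionics.IonicComposition | None = None
    amplitude_na: float | None = None

    def __post_init__(self) -> None:
        if self.volume_pl < 0:
            raise ValueError("injected volume must be >= 0 (pL)")


@dataclass(frozen=True)
class ExperimentScript:
    """A complete scripted experiment: stages, events, noise and seed."""

    stages: tuple[tuple[Stage, float], ...]
    events: tuple[InjectionEvent, ...] = ()
    holding_mv: float = -70.0
    test_pulse: TestPulse = field(default_factory=TestPulse)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    bath: ionics.IonicComposition | None = None
    cytoplasm: ionics.IonicComposition | None = None
    cell_volume_pl: float = ionics.DEFAULT_CELL_VOLUME_PL
    baseline_window_ms: float = 20.0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("script must contain at least one stage")
        order = [s.value for s, _ in self.stages]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError("stages must advance forward in procedure order")
        for _, dur in self.stages:
            if dur <= 0:
                raise ValueError("stage durations must be positive (ms)")
        times = [e.time_ms for e in self.events]
        if times != sorted(times) or len(set(times)) != len(times):
            raise ValueError("event times must be strictly increasing")


@dataclass
class SyntheticExperiment:
    """A generated trace plus the ground truth that produced it."""

    trace: CurrentTrace
    current_noisefree_na: np.ndarray
    events_true: list[tuple[float, float]]  # (absolute time ms, amplitude nA)
    stage_bounds: list[tuple[Stage, float]]  # (stage, start time ms)
    stage_params: dict[str, CircuitParameters]
    k_channels_on: bool
    na_channels_on: bool
    script: ExperimentScript

    def stage_start_ms(self, stage: Stage) -> float:
        for s, t in self.stage_bounds:
            if s is stage:
                return t
        raise KeyError(f"stage {stage.name} not in this experiment")

    def holding_trace(self) -> CurrentTrace:
        """The whole-cell portion of the trace (holding through post-injection)."""
        start = min(
            (t for s, t in self.stage_bounds if s in _INJECTABLE),
            default=None,
        )
        if start is None:
            raise ValueError("experiment has no whole-cell stage")
        return self.trace.slice_ms(start, self.trace.duration_ms)


def stage_parameters(
    stage: Stage,
    base: CircuitParameters,
    rng: np.random.Generator | None = None,
    bath_resistance_mohm: float | None = None,
) -> CircuitParameters:
    """Circuit as seen from the amplifier at a given procedure stage.

    Pre-break-in stages present a resistor (plus pipette capacitance):
    bath 4-8 MOhm (seeded), approach adds 3-5 MOhm, gigaseal jumps to the
    seal resistance of ``base`` (1 GOhm default). From whole-cell holding
    onward the full circuit of ``base`` is active.
    """
    if stage in (Stage.BATH, Stage.APPROACH):
        if rng is None:
            rng = np.random.default_rng(0)
        r = (
            bath_resistance_mohm
            if bath_resistance_mohm is not None
            else rng.uniform(*BATH_RESISTANCE_RANGE_MOHM)
        )
        if stage is Stage.APPROACH:
            r = r + rng.uniform(*CONTACT_INCREMENT_RANGE_MOHM)
        return replace(
            base,
            r_seal_mohm=r,
            r_access_mohm=math.inf,
            c_m_pf=0.0,
            e_injection_mv=0.0,
        )
    if stage is Stage.SEALED:
        return replace(
            base, r_access_mohm=math.inf, c_m_pf=0.0, e_injection_mv=0.0
        )
    return base


def step_family(
    start_mv: float,
    stop_mv: float,
    increment_mv: float,
    epoch_ms: float = 60.0,
    holding_mv: float = -70.0,
    pre_ms: float = 20.0,
    post_ms: float = 20.0,
) -> list[VoltageProtocol]:
    """One protocol per step level: holding, step of ``epoch_ms``, holding."""
    if increment_mv <= 0:
        raise ValueError("increment must be positive (mV)")
    if stop_mv < start_mv:
        raise ValueError("stop level must not be below start level")
    n = int(math.floor((stop_mv - start_mv) / increment_mv + 1e-9)) + 1
    levels = [start_mv + k * increment_mv for k in range(n)]
    return [
        VoltageProtocol(
            ((holding_mv, pre_ms), (level, epoch_ms), (holding_mv, post_ms))
        )
        for level in levels
    ]


def run_step_family(
    params: CircuitParameters,
    protocols: Sequence[VoltageProtocol],
    dt_ms: float = 0.01,
    noise_sd_na: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, CurrentTrace]]:
    """Simulate a step family, returning (step level, trace) pairs."""
    rng = np.random.default_rng(seed)
    out: list[tuple[float, CurrentTrace]] = []
    for proto in protocols:
        level = proto.segments[1][0] if len(proto.segments) > 1 else proto.segments[0][0]
        tr = simulate_voltage_clamp(params, proto, dt_ms)
        cur = tr.current_na
        if noise_sd_na > 0:
            cur = cur + rng.normal(0.0, noise_sd_na, cur.size)
        out.append(
            (
                level,
                CurrentTrace(dt_ms, cur, tr.command_mv, tr.annotations, tr.metadata),
            )
        )
    return out


def _resolve_amplitude(
    event: InjectionEvent,
    script: ExperimentScript,
    params: CircuitParameters,
) -> tuple[float, ionics.IonicComposition | None]:
    """Base (un-perturbed) drop amplitude for one event, nA."""
    if event.amplitude_na is not None:
        return event.amplitude_na, None
    if event.injectate is not None:
        if script.bath is None or script.cytoplasm is None:
            raise ValueError(
                "injectate-driven events need bath and cytoplasm compositions"
            )
        new_inside = ionics.mix_injection(
            script.cytoplasm, script.cell_volume_pl, event.injectate, event.volume_pl
        )
        e_inj = ionics.injection_potential(
            script.bath,
            script.cytoplasm,
            new_inside,
            (ionics.SODIUM, ionics.POTASSIUM),
        )
        return e_inj / params.r_access_mohm, new_inside
    return params.e_injection_mv / params.r_access_mohm, None


def run_experiment(
    script: ExperimentScript,
    base: CircuitParameters,
    dt_ms: float = 0.1,
    event_onset_tau_ms: float = 0.0,
) -> SyntheticExperiment:
    """Simulate a scripted experiment and return trace plus ground truth.

    Pre-break-in stages run the seal-test pulse train around 0 mV;
    whole-cell stages hold at ``script.holding_mv``. The baseline of the
    whole-cell current is zeroed over the start of the whole-cell stage
    (first ``baseline_window_ms``), mirroring the bench practice of
    zeroing before injecting, so drops are measured from zero. Injection
    drops are instantaneous by default; ``event_onset_tau_ms`` > 0 applies
    an exponential onset instead.
    """
    rngs = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(script.seed).spawn(3)
    ]
    stage_rng, event_rng, noise_rng = rngs

    stage_list = list(script.stages)
    stage_names = [s.name for s, _ in stage_list]
    if len(set(stage_names)) != len(stage_names):
        raise ValueError("each stage may appear at most once")

    # One bath draw shared by BATH and APPROACH so contact is an increment.
    bath_r: float | None = None
    if any(s in (Stage.BATH, Stage.APPROACH) for s, _ in stage_list):
        bath_r = stage_rng.uniform(*BATH_RESISTANCE_RANGE_MOHM)

    # Event admissibility and resolved amplitudes.
    wc_start: float | None = None
    t_cursor = 0.0
    bounds: list[tuple[Stage, float]] = []
    for stage, dur in stage_list:
        bounds.append((stage, t_cursor))
        if stage in _INJECTABLE and wc_start is None:
            wc_start = t_cursor
        t_cursor += dur
    total_ms = t_cursor

    events_true: list[tuple[float, float]] = []
    if script.events:
        if wc_start is None:
            raise ValueError("injection scheduled but no whole-cell stage in script")
        first_ok = wc_start + script.baseline_window_ms
        for ev in script.events:
            if ev.time_ms < first_ok:
                raise ValueError(
                    f"injection at {ev.time_ms} ms precedes whole-cell baseline "
                    f"window (allowed from {first_ok} ms)"
                )
            if ev.time_ms >= total_ms:
                raise ValueError(f"injection at {ev.time_ms} ms beyond experiment end")
            base_amp, _ = _resolve_amplitude(ev, script, base)
            sd = (
                script.noise.event_sd_na
                if script.noise.event_sd_na is not None
                else 0.0
            )
            amp = base_amp + (event_rng.normal(0.0, sd) if sd > 0 else 0.0)
            events_true.append((ev.time_ms, amp))

    # Simulate stage by stage.
    chunks_cur: list[np.ndarray] = []
    chunks_cmd: list[np.ndarray] = []
    stage_params_used: dict[str, CircuitParameters] = {}
    for stage, dur in stage_list:
        sp = stage_parameters(stage, base, stage_rng, bath_resistance_mohm=bath_r)
        stage_params_used[stage.name] = sp
        t0 = dict((s.name, t) for s, t in bounds)[stage.name]
        if stage in (Stage.BATH, Stage.APPROACH, Stage.SEALED):
            proto = script.test_pulse.protocol(dur)
            tr = simulate_voltage_clamp(sp, proto, dt_ms)
        else:
            proto = VoltageProtocol(((script.holding_mv, dur),))
            inj = [
                (t - t0, amp * sp.r_access_mohm)
                for t, amp in events_true
                if t0 <= t < t0 + dur
            ]
            tr = simulate_voltage_clamp(sp, proto, dt_ms, injections=inj)
        chunks_cur.append(tr.current_na)
        chunks_cmd.append(tr.command_mv)

    current = np.concatenate(chunks_cur)
    command = np.concatenate(chunks_cmd)
    n = current.size

    # Optional exponential onset replaces the instantaneous steps.
    if event_onset_tau_ms > 0 and events_true:
        steps = np.zeros(n)
        smooth = np.zeros(n)
        t = np.arange(n) * dt_ms
        for t_ev, amp in events_true:
            idx = int(round(t_ev / dt_ms))
            steps[idx:] += amp
            smooth[idx:] += amp * (1.0 - np.exp(-(t[idx:] - t[idx]) / event_onset_tau_ms))
        current = current - steps + smooth

    # Baseline zeroing over the start of the whole-cell stage.
    if wc_start is not None:
        i0 = int(round(wc_start / dt_ms))
        i1 = int(round((wc_start + script.baseline_window_ms) / dt_ms))
        i1 = min(max(i1, i0 + 1), n)
        baseline = float(np.mean(current[i0:i1]))
        current = current.copy()
        current[i0:] -= baseline

    noisefree = current.copy()
    if script.noise.gaussian_sd_na > 0:
        current = current + noise_rng.normal(0.0, script.noise.gaussian_sd_na, n)
    if script.noise.drift_na_per_s > 0:
        current = current + script.noise.drift_na_per_s * (np.arange(n) * dt_ms * 1e-3)

    trace = CurrentTrace(
        dt_ms,
        current,
        command,
        annotations=[
            {"time_ms": t, "amplitude_na": a} for t, a in events_true
        ],
        metadata={
            "units": {"time": "ms", "current": "nA", "command": "mV"},
            "dt_ms": dt_ms,
            "seed": script.seed,
            "holding_mv": script.holding_mv,
            "r_access_mohm": base.r_access_mohm,
            "c_m_pf": base.c_m_pf,
            "stage_timeline": [(s.name, t) for s, t in bounds],
        },
    )
    return SyntheticExperiment(
        trace=trace,
        current_noisefree_na=noisefree,
        events_true=events_true,
        stage_bounds=bounds,
        stage_params=stage_params_used,
        k_channels_on=base.switches.s_k and base.gating.k.g_max_us > 0,
        na_channels_on=base.switches.s_na and base.gating.na.g_max_us > 0,
        script=script,
    )


def injection_script(
    n_events: int,
    start_ms: float = 100.0,
    spacing_ms: float = 150.0,
    tail_ms: float = 100.0,
    holding_mv: float = -70.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    amplitude_na: float | None = None,
) -> ExperimentScript:
    """Convenience script: whole-cell holding, then n evenly spaced injections."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    events = tuple(
        InjectionEvent(start_ms + k * spacing_ms, amplitude_na=amplitude_na)
        for k in range(n_events)
    )
    inj_dur = max(n_events, 1) * spacing_ms + tail_ms
    return ExperimentScript(
        stages=(
            (Stage.WHOLE_CELL_HOLDING, start_ms),
            (Stage.INJECTING, inj_dur),
        ),
        events=events,
        holding_mv=holding_mv,
        noise=noise if noise is not None else NoiseModel(),
        seed=seed,
    )
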