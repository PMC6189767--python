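"""The equivalent circuit of a patched, injected cell under voltage clamp.

Topology: an ideal voltage source (the clamp amplifier, optionally with a
series output resistance) drives the pipette node. From that node three
paths go to bath ground:

* the seal path through ``R_Seal`` (the leak around the pipette rim),
* the pipette capacitance ``C_Pipette`` (transients at command edges,
  optionally compensated exactly, mirroring amplifier neutralization),
* the access path through ``R_Access`` into the membrane node, which
  carries the membrane capacitance ``C_M`` and the ionic branches: K+ and
  Na+ channels as gated conductances in series with their Nernst
  batteries, plus a fixed small "other ions" leak. A separate injection
  branch (battery ``E_Injection`` in series with the access resistance)
  switches in at injection events and carries the permanent current drop
  E_Injection / R_Access.

The measured membrane current decomposes as
``I_m = I_Pipette + I_Seal + I_C + I_Access`` with
``I_Access = I_Na + I_K + I_Other + I_Injection``; both identities hold
sample-wise by construction and are exposed by :func:`decompose_currents`.

Gating is a Boltzmann steady state with first-order kinetics: a single
activation gate n for K+ (delayed-rectifier-like) and m*h (fast
activation, slower inactivation) for Na+. The membrane node is advanced
with the exact exponential update for the linear circuit over each step,
with branch conductances held at their start-of-step values; the gates are
advanced with their own exact first-order update. Resolution is therefore
limited by the gating time constants, not by R_Access*C_M.

Units are the self-consistent electrophysiology set mV / nA / MOhm / pF /
ms (mV/MOhm = nA; MOhm*pF = us, converted explicitly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import CurrentTrace, VoltageProtocol

__all__ = [
    "SwitchState",
    "BranchGating",
    "NaGating",
    "GatingParameters",
    "GatingState",
    "CircuitParameters",
    "SimulatedTrace",
    "channel_current",
    "injection_current",
    "boltzmann",
    "gating_steady_state",
    "advance_gating",
    "simulate_voltage_clamp",
    "decompose_currents",
]


@dataclass(frozen=True)
class SwitchState:
    """Switch positions; ``True`` means closed (branch conducting).

    The seal switch is open by convention (the seal is never a deliberate
    low-resistance path); the seal *leak* is nevertheless always simulated
    through the finite ``R_Seal``, and setting ``R_Seal = inf`` recovers
    the idealized open circuit. ``s_injection`` is managed by the
    simulator: it closes at the first injection event.
    """

    s_seal: bool = False
    s_injection: bool = False
    s_k: bool = True
    s_na: bool = True
    s_other: bool = True


@dataclass(frozen=True)
class BranchGating:
    """One gated conductance branch: Boltzmann activation, 1st-order kinetics."""

    g_max_us: float = 0.0
    v_half_mv: float = -20.0
    slope_mv: float = 10.0
    tau_act_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.g_max_us < 0:
            raise ValueError("g_max must be >= 0 (uS)")
        if self.slope_mv == 0:
            raise ValueError("Boltzmann slope must be nonzero (mV)")
        if self.tau_act_ms <= 0:
            raise ValueError("activation time constant must be positive (ms)")


@dataclass(frozen=True)
class NaGating(BranchGating):
    """Na+ branch: m activation plus h inactivation (negative slope)."""

    v_half_mv: float = -25.0
    slope_mv: float = 6.0
    tau_act_ms: float = 0.3
    h_v_half_mv: float = -60.0
    h_slope_mv: float = -7.0
    tau_inact_ms: float = 3.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.h_slope_mv == 0:
            raise ValueError("inactivation slope must be nonzero (mV)")
        if self.tau_inact_ms <= 0:
            raise ValueError("inactivation time constant must be positive (ms)")


@dataclass(frozen=True)
class GatingParameters:
    k: BranchGating = field(default_factory=BranchGating)
    na: NaGating = field(default_factory=NaGating)
    #: Fixed "other ions" leak conductance, uS (no gating; default 0).
    other_g_us: float = 0.0

    def __post_init__(self) -> None:
        if self.other_g_us < 0:
            raise ValueError("other-ion leak conductance must be >= 0 (uS)")


@dataclass(frozen=True)
class GatingState:
    """Gate occupancies, each in [0, 1]."""

    n: float = 0.0
    m: float = 0.0
    h: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n", "m", "h"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"gate {name}={x} outside [0, 1]")


@dataclass(frozen=True)
class CircuitParameters:
    """All passive elements, batteries and switches of the cell+pipette circuit."""

    r_seal_mohm: float = 1000.0
    r_access_mohm: float = 10.0
    c_m_pf: float = 30.0
    c_pipette_pf: float = 3.0
    r_opamp_mohm: float = 0.0  # ideal clamp source by default
    e_k_mv: float = -90.0
    e_na_mv: float = 60.0
    e_other_mv: float = 0.0
    e_injection_mv: float = 0.0
    switches: SwitchState = field(default_factory=SwitchState)
    gating: GatingParameters = field(default_factory=GatingParameters)
    compensate_pipette: bool = False

    def __post_init__(self) -> None:
        if self.r_seal_mohm <= 0:
            raise ValueError("R_Seal must be positive (MOhm; use inf to remove)")
        if self.r_access_mohm <= 0:
            raise ValueError("R_Access must be positive (MOhm; use inf to detach)")
        if self.c_m_pf < 0 or self.c_pipette_pf < 0:
            raise ValueError("capacitances must be >= 0 (pF)")
        if self.r_opamp_mohm < 0:
            raise ValueError("R_OpAmp must be >= 0 (MOhm)")

    def membrane_tau_ms(self) -> float:
        """Access charging time constant R_Access * C_M, in ms."""
        if math.isinf(self.r_access_mohm):
            return math.inf
        return self.r_access_mohm * self.c_m_pf * 1e-3


@dataclass
class SimulatedTrace(CurrentTrace):
    """A simulated recording with the hidden state and branch currents."""

    v_mem_mv: np.ndarray = None  # type: ignore[assignment]
    branches: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.v_mem_mv is None:
            raise ValueError("simulated trace requires a membrane-voltage channel")
        self.v_mem_mv = np.asarray(self.v_mem_mv, dtype=float)
        if self.v_mem_mv.shape != self.current_na.shape:
            raise ValueError("membrane-voltage channel length mismatch")


def channel_current(v_m_mv: float, e_ion_mv: float, r_ion_mohm: float) -> float:
    """Ohmic branch current (V_m - E_ion) / R_ion, in nA."""
    if r_ion_mohm <= 0:
        raise ValueError("channel resistance must be positive (MOhm)")
    return (v_m_mv - e_ion_mv) / r_ion_mohm


def injection_current(e_injection_mv: float, r_access_mohm: float) -> float:
    """Permanent injection current E_Injection / R_Access, in nA.

    With all channel switches open and the command held constant this is
    the whole membrane current at rest: the current drop the feedback
    strategy watches for.
    """
    if r_access_mohm <= 0:
        raise ValueError("access resistance must be positive (MOhm)")
    return e_injection_mv / r_access_mohm


def boltzmann(v_mv: float, v_half_mv: float, slope_mv: float) -> float:
    """Boltzmann occupancy 1 / (1 + exp(-(V - V_half)/slope))."""
    x = -(v_mv - v_half_mv) / slope_mv
    if x > 700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


def gating_steady_state(v_mv: float, params: GatingParameters) -> GatingState:
    """Steady-state gate occupancies at a fixed voltage."""
    return GatingState(
        n=boltzmann(v_mv, params.k.v_half_mv, params.k.slope_mv),
        m=boltzmann(v_mv, params.na.v_half_mv, params.na.slope_mv),
        h=boltzmann(v_mv, params.na.h_v_half_mv, params.na.h_slope_mv),
    )


def advance_gating(
    state: GatingState, v_mv: float, dt_ms: float, params: GatingParameters
) -> GatingState:
    """Exact first-order relaxation toward steady state over one step."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive (ms)")
    inf = gating_steady_state(v_mv, params)

    def relax(x: float, x_inf: float, tau: float) -> float:
        return x_inf + (x - x_inf) * math.exp(-dt_ms / tau)

    return GatingState(
        n=relax(state.n, inf.n, params.k.tau_act_ms),
        m=relax(state.m, inf.m, params.na.tau_act_ms),
        h=relax(state.h, inf.h, params.na.tau_inact_ms),
    )


def _active_gated(params: CircuitParameters) -> list[str]:
    names = []
    if params.switches.s_k and params.gating.k.g_max_us > 0:
        names.append("k")
    if params.switches.s_na and params.gating.na.g_max_us > 0:
        names.append("na")
    return names


def _check_dt(params: CircuitParameters, dt_ms: float) -> None:
    taus: list[tuple[float, str]] = []
    active = _active_gated(params)
    if "k" in active:
        taus.append((params.gating.k.tau_act_ms, "K activation tau"))
    if "na" in active:
        taus.append((params.gating.na.tau_act_ms, "Na activation tau"))
        taus.append((params.gating.na.tau_inact_ms, "Na inactivation tau"))
    if taus:
        tau_min, name = min(taus)
        if dt_ms > tau_min / 2.0:
            raise ValueError(
                f"dt={dt_ms} ms too coarse for gating kinetics: limiting "
                f"time constant is {name} = {tau_min} ms (need dt <= {tau_min / 2.0} ms)"
            )


def _initial_state(
    params: CircuitParameters, v_cmd: float
) -> tuple[float, GatingState]:
    """Self-consistent resting state at a constant command level."""
    if math.isinf(params.r_access_mohm):
        # Membrane detached from the pipette: it rests at the reversal of
        # its own branches (or at the command if no branch conducts).
        v = v_cmd
        for _ in range(200):
            gates = gating_steady_state(v, params.gating)
            g, ge = _branch_conductances(params, gates)
            v_new = ge / g if g > 0 else v_cmd
            if abs(v_new - v) < 1e-12:
                v = v_new
                break
            v = v_new
        return v, gating_steady_state(v, params.gating)
    v = v_cmd
    g_a = 1.0 / params.r_access_mohm
    for _ in range(200):
        gates = gating_steady_state(v, params.gating)
        g, ge = _branch_conductances(params, gates)
        v_new = (g_a * v_cmd + ge) / (g_a + g)
        if abs(v_new - v) < 1e-12:
            v = v_new
            break
        v = v_new
    return v, gating_steady_state(v, params.gating)


def _branch_conductances(
    params: CircuitParameters, gates: GatingState
) -> tuple[float, float]:
    """Total branch conductance g (uS) and battery-weighted sum g*E (uS*mV)."""
    g = 0.0
    ge = 0.0
    if params.switches.s_k and params.gating.k.g_max_us > 0:
        gk = params.gating.k.g_max_us * gates.n
        g += gk
        ge += gk * params.e_k_mv
    if params.switches.s_na and params.gating.na.g_max_us > 0:
        gna = params.gating.na.g_max_us * gates.m * gates.h
        g += gna
        ge += gna * params.e_na_mv
    if params.switches.s_other and params.gating.other_g_us > 0:
        g += params.gating.other_g_us
        ge += params.gating.other_g_us * params.e_other_mv
    return g, ge


def simulate_voltage_clamp(
    params: CircuitParameters,
    protocol: VoltageProtocol,
    dt_ms: float = 0.01,
    injections: Sequence[tuple[float, float]] = (),
) -> SimulatedTrace:
    """Forward-simulate the whole-cell current under a voltage command.

    Parameters
    ----------
    params
        Circuit elements, batteries, switches and gating.
    protocol
        Piecewise-constant command in mV.
    dt_ms
        Sample interval. Must resolve the gating kinetics when gated
        branches are active; the linear RC part is integrated exactly at
        any dt (exponential update per step).
    injections
        ``(time_ms, e_injection_mv)`` activations. Injection battery
        contributions accumulate; the injection switch closes at the first
        event and the branch then carries ``sum(E_k) / R_Access``.

    Returns
    -------
    SimulatedTrace
        With membrane voltage and per-branch currents (``i_pipette``,
        ``i_seal``, ``i_c``, ``i_k``, ``i_na``, ``i_other``,
        ``i_injection``, ``i_access``).
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive (ms)")
    _check_dt(params, dt_ms)
    cmd = protocol.command_samples(dt_ms)
    n = cmd.size

    if injections and math.isinf(params.r_access_mohm):
        raise ValueError("injection events require a finite access resistance")
    inj_e_cum = np.zeros(n)
    for t_ev, e_ev in injections:
        idx = int(round(t_ev / dt_ms))
        if not (0 <= idx < n):
            raise ValueError(f"injection at {t_ev} ms outside the protocol")
        inj_e_cum[idx:] += e_ev

    r_a = params.r_access_mohm
    g_a = 0.0 if math.isinf(r_a) else 1.0 / r_a
    i_injection = inj_e_cum * g_a

    i_seal = (
        np.zeros(n)
        if math.isinf(params.r_seal_mohm)
        else cmd / params.r_seal_mohm
    )

    i_pipette = np.zeros(n)
    if not params.compensate_pipette and params.c_pipette_pf > 0:
        dcmd = np.diff(cmd)
        # pF * mV / ms = pA; convert to nA
        i_pipette[1:] = params.c_pipette_pf * dcmd / dt_ms * 1e-3

    v0, gates = _initial_state(params, cmd[0])
    active = _active_gated(params)

    v_mem = np.empty(n)
    i_k = np.zeros(n)
    i_na = np.zeros(n)
    i_other = np.zeros(n)
    i_acc_r = np.zeros(n)

    g_other = params.gating.other_g_us if params.switches.s_other else 0.0
    if not active:
        # Linear circuit: exact piecewise-exponential membrane voltage,
        # vectorized over runs of constant command.
        g_tot = g_a + g_other
        ge = g_other * params.e_other_mv
        edges = np.flatnonzero(np.diff(cmd)) + 1
        starts = np.concatenate(([0], edges, [n]))
        v = v0
        for s, e in zip(starts[:-1], starts[1:]):
            vc = cmd[s]
            if g_tot == 0:
                v_mem[s:e] = v
                continue
            v_inf = (g_a * vc + ge) / g_tot
            if params.c_m_pf == 0:
                # capacitance-free node follows instantaneously
                v_mem[s:e] = v_inf
                v = v_inf
            else:
                tau = params.c_m_pf / g_tot * 1e-3  # pF/uS = us -> ms
                k = np.arange(e - s)
                v_mem[s:e] = v_inf + (v - v_inf) * np.exp(-k * dt_ms / tau)
                v = v_inf + (v - v_inf) * math.exp(-(e - s) * dt_ms / tau)
        if g_other > 0:
            i_other = g_other * (v_mem - params.e_other_mv) * 1.0
        i_acc_r = g_a * (cmd - v_mem)
    else:
        gp = params.gating
        v = v0
        nn, mm, hh = gates.n, gates.m, gates.h
        use_k = "k" in active
        use_na = "na" in active
        gk_max = gp.k.g_max_us
        gna_max = gp.na.g_max_us
        for i in range(n):
            vc = cmd[i]
            gk = gk_max * nn if use_k else 0.0
            gna = gna_max * mm * hh if use_na else 0.0
            v_mem[i] = v
            i_k[i] = gk * (v - params.e_k_mv)
            i_na[i] = gna * (v - params.e_na_mv)
            if g_other > 0:
                i_other[i] = g_other * (v - params.e_other_mv)
            i_acc_r[i] = g_a * (vc - v)
            # advance membrane voltage (exponential, conductances frozen)
            g_tot = g_a + gk + gna + g_other
            if g_tot > 0:
                ge = (
                    g_a * vc
                    + gk * params.e_k_mv
                    + gna * params.e_na_mv
                    + g_other * params.e_other_mv
                )
                v_inf = ge / g_tot
                if params.c_m_pf == 0:
                    v = v_inf
                else:
                    tau = params.c_m_pf / g_tot * 1e-3
                    v = v_inf + (v - v_inf) * math.exp(-dt_ms / tau)
            # advance gates at the start-of-step membrane voltage
            vg = v_mem[i]
            if use_k:
                ninf = boltzmann(vg, gp.k.v_half_mv, gp.k.slope_mv)
                nn = ninf + (nn - ninf) * math.exp(-dt_ms / gp.k.tau_act_ms)
            if use_na:
                minf = boltzmann(vg, gp.na.v_half_mv, gp.na.slope_mv)
                hinf = boltzmann(vg, gp.na.h_v_half_mv, gp.na.h_slope_mv)
                mm = minf + (mm - minf) * math.exp(-dt_ms / gp.na.tau_act_ms)
                hh = hinf + (hh - hinf) * math.exp(-dt_ms / gp.na.tau_inact_ms)

    i_ionic = i_k + i_na + i_other
    i_c = i_acc_r - i_ionic
    i_access = i_ionic + i_injection
    i_m = i_pipette + i_seal + i_c + i_access

    return SimulatedTrace(
        dt_ms=dt_ms,
        current_na=i_m,
        command_mv=cmd.copy(),
        annotations=[
            {"time_ms": t, "e_injection_mv": e} for t, e in injections
        ],
        metadata={
            "units": {"time": "ms", "current": "nA", "command": "mV"},
            "r_access_mohm": params.r_access_mohm,
            "r_seal_mohm": params.r_seal_mohm,
            "c_m_pf": params.c_m_pf,
            "dt_ms": dt_ms,
        },
        v_mem_mv=v_mem,
        branches={
            "i_pipette": i_pipette,
            "i_seal": i_seal,
            "i_c": i_c,
            "i_k": i_k,
            "i_na": i_na,
            "i_other": i_other,
            "i_injection": i_injection,
            "i_access": i_access,
        },
    )


def decompose_currents(trace: SimulatedTrace) -> dict[str, np.ndarray | float]:
    """Branch currents plus the residual of the current-balance identity.

    Returns the branch arrays and ``residual_na``, the maximum absolute
    violation of I_m = I_Pipette + I_Seal + I_C + I_Access over the trace.
    """
    b = trace.branches
    recomposed = b["i_pipette"] + b["i_seal"] + b["i_c"] + b["i_access"]
    residual = float(np.max(np.abs(trace.current_na - recomposed))) if trace.n_samples else 0.0
    out: dict[str, np.ndarray | float] = dict(b)
    out["residual_na"] = residual
    return out
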