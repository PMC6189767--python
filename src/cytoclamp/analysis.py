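"""Current-feedback analysis: resistance, injection drops, viability, control.

These are the measurement-side counterparts of the circuit model: test
pulse resistance estimation during seal formation, baseline zeroing,
detection of the permanent current drops that signal a delivered bolus,
inversion of the drop/battery relation to calibrate the access pair,
classification of K+/Na+ channel activity from step-family recordings, and
the threshold control loop that declares an injection episode successful.

The drop detector is a defined surrogate for what an operator reads off
the screen: the bench procedure never specified a computation, so the
windowed two-sided mean comparison here is the package's own algorithm,
with every window length exposed as a parameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import CurrentTrace

logger = logging.getLogger(__name__)

__all__ = [
    "ResistanceEstimate",
    "InjectionDetection",
    "ViabilityReport",
    "ControlDecision",
    "zero_baseline",
    "robust_noise_sd",
    "estimate_resistance",
    "detect_injection_drops",
    "calibrate_access_pair",
    "classify_viability",
    "control_loop",
]

#: Default success threshold for the accumulated injection drop, nA.
DEFAULT_DROP_THRESHOLD_NA = -11.0
#: Pipette resistance range measured in the bath; a calibrated access pair
#: falling outside it triggers a logged warning.
PIPETTE_RANGE_MOHM = (4.0, 8.0)


@dataclass(frozen=True)
class ResistanceEstimate:
    """A resistance estimate in MOhm; ``lower_bound`` marks a noise-limited
    result (the true value is at least ``megaohms``)."""

    megaohms: float
    lower_bound: bool = False
    n_pulses: int = 1

    @property
    def gigaohms(self) -> float:
        return self.megaohms / 1e3


@dataclass(frozen=True)
class DetectedEvent:
    time_ms: float
    amplitude_na: float


@dataclass(frozen=True)
class InjectionDetection:
    """Detected permanent current steps and the episode verdict."""

    events: tuple[DetectedEvent, ...]
    accumulated_drop_na: float
    threshold_na: float
    success: bool
    noise_sd_na: float


@dataclass(frozen=True)
class ViabilityReport:
    """Per-channel-type activity verdict from a step family."""

    k_active: bool
    na_active: bool
    peak_outward_na: float
    peak_inward_na: float
    noise_sd_na: float
    verdict: str  # "viable" | "non-viable"


@dataclass(frozen=True)
class ControlDecision:
    segment_index: int
    segment_drop_na: float
    cumulative_drop_na: float
    decision: str  # "success" | "retry"


def zero_baseline(
    trace: CurrentTrace, window_ms: float, start_ms: float = 0.0
) -> CurrentTrace:
    """Subtract the mean current over a command-quiet window from all samples."""
    i0 = int(round(start_ms / trace.dt_ms))
    i1 = int(round((start_ms + window_ms) / trace.dt_ms))
    if not (0 <= i0 < i1 <= trace.n_samples):
        raise ValueError("baseline window outside the trace")
    cmd = trace.command_mv[i0:i1]
    if np.ptp(cmd) != 0:
        raise ValueError("baseline window overlaps a command step")
    offset = float(np.mean(trace.current_na[i0:i1]))
    return CurrentTrace(
        trace.dt_ms,
        trace.current_na - offset,
        trace.command_mv,
        list(trace.annotations),
        {**trace.metadata, "baseline_offset_na": offset},
    )


def robust_noise_sd(current_na: np.ndarray) -> float:
    """Noise sd from the MAD of the first-difference signal.

    Differencing removes steps and slow structure, so the estimate is not
    inflated by the very events being detected; the MAD resists the few
    large step samples that remain.
    """
    d = np.diff(np.asarray(current_na, dtype=float))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


def _pulse_regions(command: np.ndarray) -> tuple[float, list[tuple[int, int, float]]]:
    """Baseline level and (start, stop, level) of each command excursion."""
    baseline = float(command[0])
    off = command != baseline
    if not off.any():
        return baseline, []
    edges = np.flatnonzero(np.diff(off.astype(np.int8)))
    starts = list(edges[command[edges + 1] != baseline] + 1)
    stops = list(edges[command[edges + 1] == baseline] + 1)
    if off[-1]:
        stops.append(command.size)
    regions = []
    for s, e in zip(starts, stops):
        level = command[s:e]
        if np.ptp(level) != 0:
            continue  # multi-level excursion; not a simple test pulse
        regions.append((s, e, float(level[0])))
    return baseline, regions


def estimate_resistance(
    trace: CurrentTrace,
    pulse_amplitude_mv: float | None = None,
    plateau_fraction: float = 0.2,
    settle_ms: float = 2.0,
) -> ResistanceEstimate:
    """Total resistance from the steady response to test pulses, in MOhm.

    For each pulse found in the command channel: R = amplitude / dI, where
    dI is the plateau mean (last ``plateau_fraction`` of the pulse, which
    excludes the capacitive transient) minus the pre-pulse baseline mean.
    All complete pulses are averaged. When dI is below the noise floor a
    lower bound (amplitude / noise floor) is reported instead of a point
    estimate.
    """
    if pulse_amplitude_mv == 0:
        raise ValueError("test pulse amplitude must be nonzero")
    baseline_level, regions = _pulse_regions(trace.command_mv)
    if not regions:
        raise ValueError("no test pulse found in the command channel")
    dt = trace.dt_ms
    settle = int(round(settle_ms / dt))
    cur = trace.current_na

    deltas = []
    n_plateau_total = 0
    n_base_total = 0
    base_samples = []
    prev_stop = 0
    amp_used = None
    for s, e, level in regions:
        amp = level - baseline_level
        if pulse_amplitude_mv is not None and not math.isclose(
            amp, pulse_amplitude_mv, rel_tol=1e-9, abs_tol=1e-9
        ):
            continue
        if amp == 0:
            continue
        amp_used = amp
        n_pl = max(int(round((e - s) * plateau_fraction)), 1)
        plateau = cur[e - n_pl : e]
        b0 = min(prev_stop + settle, s)
        base = cur[b0:s]
        prev_stop = e
        if base.size == 0:
            continue
        deltas.append(float(np.mean(plateau)) - float(np.mean(base)))
        base_samples.append(base)
        n_plateau_total += plateau.size
        n_base_total += base.size
    if not deltas:
        raise ValueError("no usable test pulse (check pulse_amplitude_mv)")
    assert amp_used is not None
    delta_i = float(np.mean(deltas))
    sd = robust_noise_sd(np.concatenate(base_samples))
    noise_floor = 3.0 * sd * math.sqrt(
        1.0 / n_plateau_total + 1.0 / n_base_total
    )
    if abs(delta_i) <= noise_floor and noise_floor > 0:
        return ResistanceEstimate(
            abs(amp_used) / noise_floor, lower_bound=True, n_pulses=len(deltas)
        )
    return ResistanceEstimate(amp_used / delta_i, n_pulses=len(deltas))


def detect_injection_drops(
    trace: CurrentTrace,
    threshold_na: float = DEFAULT_DROP_THRESHOLD_NA,
    window_ms: float = 5.0,
    gap_ms: float = 1.0,
    persist_ms: float = 10.0,
    sd_floor_na: float = 0.005,
) -> InjectionDetection:
    """Detect permanent current steps and judge the episode.

    A step is declared where the trailing-window mean minus the
    leading-window mean (windows of ``window_ms`` separated by ``gap_ms``)
    exceeds six times the robust noise sd and the level change persists
    for at least ``persist_ms``. The accumulated drop is the final minus
    the initial steady level; the episode succeeds when it is at or below
    (more negative than) ``threshold_na``.
    """
    if np.ptp(trace.command_mv) != 0:
        raise ValueError(
            "injection detection requires a constant holding command over the span"
        )
    x = trace.current_na
    dt = trace.dt_ms
    nw = max(int(round(window_ms / dt)), 1)
    half_gap = max(int(round(gap_ms / dt)) // 2, 0)
    np_persist = max(int(round(persist_ms / dt)), 1)
    n = x.size
    if n < 2 * (nw + half_gap) + 2:
        raise ValueError("trace too short for the detection windows")

    sd = max(robust_noise_sd(x), sd_floor_na)
    thr = 6.0 * sd

    csum = np.concatenate(([0.0], np.cumsum(x)))

    def win_mean(starts: np.ndarray) -> np.ndarray:
        return (csum[starts + nw] - csum[starts]) / nw

    centers = np.arange(nw + half_gap, n - nw - half_gap)
    pre = win_mean(centers - half_gap - nw)
    post = win_mean(centers + half_gap)
    d = post - pre

    above = np.abs(d) > thr
    events: list[DetectedEvent] = []
    if above.any():
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = list(edges[~above[edges]] + 1)
        stops = list(edges[above[edges]] + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            stops.append(above.size)
        for s, e in zip(starts, stops):
            k = s + int(np.argmax(np.abs(d[s:e])))
            i = centers[k]
            amp = float(d[k])
            # persistence: the new level must hold persist_ms later
            ps = min(i + np_persist, n - nw)
            late = float(np.mean(x[ps : ps + nw]))
            persistent = abs(late - pre[k]) > thr / 2.0 and np.sign(
                late - pre[k]
            ) == np.sign(amp)
            if persistent:
                events.append(DetectedEvent(time_ms=i * dt, amplitude_na=amp))

    accumulated = float(np.mean(x[-nw:]) - np.mean(x[:nw]))
    success = accumulated <= threshold_na
    return InjectionDetection(
        events=tuple(events),
        accumulated_drop_na=accumulated,
        threshold_na=threshold_na,
        success=success,
        noise_sd_na=sd,
    )


def calibrate_access_pair(
    mean_drop_na: float,
    e_injection_mv: float,
    pipette_range_mohm: tuple[float, float] = PIPETTE_RANGE_MOHM,
) -> float:
    """Access resistance implied by a measured drop and injection battery.

    Inverts drop = E_Injection / R_Access. The printed drop (~ -12 nA)
    together with the ~ -0.3 mV battery implies tens of kOhm, far below
    the bath pipette resistance; that tension is surfaced as a warning,
    not resolved.
    """
    if mean_drop_na == 0 or e_injection_mv == 0:
        raise ValueError("drop and injection battery must both be nonzero")
    if mean_drop_na * e_injection_mv < 0:
        raise ValueError(
            "drop and injection battery must share a sign (Ohm's law)"
        )
    r = e_injection_mv / mean_drop_na
    lo, hi = pipette_range_mohm
    if not (lo <= r <= hi):
        logger.warning(
            "calibrated access resistance %.5f MOhm lies outside the "
            "bath pipette range %g-%g MOhm",
            r, lo, hi,
        )
    return r


def _step_window_metrics(
    level: float,
    trace: CurrentTrace,
    early_ms: float,
    late_ms: float,
    exclude_ms: float,
) -> tuple[float, float, float]:
    """(late mean, early extreme inward, pre-step noise sd), baseline-corrected."""
    cmd = trace.command_mv
    dt = trace.dt_ms
    onstep = np.flatnonzero(cmd == level)
    if onstep.size == 0:
        raise ValueError(f"step level {level} mV not present in command")
    s, e = int(onstep[0]), int(onstep[-1]) + 1
    if s == 0:
        raise ValueError("step family traces need a pre-step holding segment")
    pre = trace.current_na[: s - 1]
    base = float(np.mean(pre[max(0, s - 1 - int(round(10.0 / dt))) :]))
    sd = robust_noise_sd(pre)
    k_ex = int(round(exclude_ms / dt))
    k_early = int(round(early_ms / dt))
    k_late = int(round(late_ms / dt))
    early = trace.current_na[s + k_ex : min(s + k_ex + k_early, e)]
    late = trace.current_na[max(e - k_late, s + k_ex) : e]
    if early.size == 0 or late.size == 0:
        raise ValueError("step epoch too short for the analysis windows")
    return (
        float(np.mean(late)) - base,
        float(np.min(early)) - base,
        sd,
    )


def classify_viability(
    step_traces: Sequence[tuple[float, CurrentTrace]],
    early_ms: float = 5.0,
    late_ms: float = 20.0,
    transient_exclude_ms: float | None = None,
    sd_floor_na: float = 0.05,
    na_band_mv: tuple[float, float] = (-60.0, 60.0),
) -> ViabilityReport:
    """Classify K+ and Na+ channel activity from a step family.

    K+ channels are active when the late-window (last ``late_ms`` of the
    epoch) mean current is outward, exceeds five times the noise sd at the
    most depolarized step, and grows monotonically over the top three
    levels. Na+ channels are active when an early-window inward peak
    exceeding five times the noise sd appears at intermediate depolarized
    steps (``na_band_mv``). Sustained K+ activity is the viability
    criterion, so the verdict is viable iff K+ is active.
    """
    if len(step_traces) < 3:
        raise ValueError(
            "viability classification needs at least 3 step levels "
            "(monotonicity is untestable below that)"
        )
    pairs = sorted(step_traces, key=lambda lt: lt[0])
    if transient_exclude_ms is None:
        meta = pairs[0][1].metadata
        try:
            tau = meta["r_access_mohm"] * meta["c_m_pf"] * 1e-3
            transient_exclude_ms = max(10.0 * tau, 0.2)
        except (KeyError, TypeError):
            transient_exclude_ms = 2.0

    late_means: dict[float, float] = {}
    early_peaks: dict[float, float] = {}
    sds: list[float] = []
    for level, trace in pairs:
        late, early, sd = _step_window_metrics(
            level, trace, early_ms, late_ms, transient_exclude_ms
        )
        late_means[level] = late
        early_peaks[level] = early
        sds.append(sd)
    sd = max(float(np.median(sds)), sd_floor_na)

    levels = [lv for lv, _ in pairs]
    top3 = levels[-3:]
    top_late = [late_means[lv] for lv in top3]
    k_active = (
        top_late[-1] > 5.0 * sd
        and all(v > 0 for v in top_late)
        and top_late[0] < top_late[1] < top_late[2]
    )

    lo, hi = na_band_mv
    band = [lv for lv in levels[:-1] if lo <= lv <= hi]
    na_active = any(early_peaks[lv] < -5.0 * sd for lv in band)

    return ViabilityReport(
        k_active=k_active,
        na_active=na_active,
        peak_outward_na=max(late_means.values()),
        peak_inward_na=min(early_peaks.values()),
        noise_sd_na=sd,
        verdict="viable" if k_active else "non-viable",
    )


def control_loop(
    segments: Iterable[CurrentTrace],
    threshold_na: float = DEFAULT_DROP_THRESHOLD_NA,
    **detect_kwargs,
) -> list[ControlDecision]:
    """Threshold feedback over successive injection attempts.

    After each segment the detector measures the accumulated drop; drops
    accumulate across attempts, and the loop terminates on the first
    crossing of the success threshold (positioning and patching upstream
    of injection are taken as already satisfied). Remaining segments are
    not consumed after success.
    """
    log: list[ControlDecision] = []
    cumulative = 0.0
    for k, seg in enumerate(segments):
        det = detect_injection_drops(seg, threshold_na=threshold_na, **detect_kwargs)
        cumulative += det.accumulated_drop_na
        decision = "success" if cumulative <= threshold_na else "retry"
        log.append(
            ControlDecision(
                segment_index=k,
                segment_drop_na=det.accumulated_drop_na,
                cumulative_drop_na=cumulative,
                decision=decision,
            )
        )
        if decision == "success":
            break
    return log
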