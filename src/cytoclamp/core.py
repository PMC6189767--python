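"""Shared containers: voltage-command protocols and current traces."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant voltage command: (level mV, duration ms) segments."""

    segments: tuple[tuple[float, float], ...]
    repeat: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "segments",
            tuple((float(v), float(d)) for v, d in self.segments),
        )
        if not self.segments:
            raise ValueError("protocol must contain at least one segment")
        for level, dur in self.segments:
            if dur <= 0:
                raise ValueError(f"segment duration must be positive, got {dur}")
        if self.repeat < 1:
            raise ValueError("repeat count must be >= 1")

    @property
    def expanded_segments(self) -> tuple[tuple[float, float], ...]:
        return self.segments * self.repeat

    @property
    def total_duration_ms(self) -> float:
        return sum(d for _, d in self.expanded_segments)

    def command_samples(self, dt_ms: float) -> np.ndarray:
        """Sampled command, one level per sample at t = i*dt.

        Segment durations are quantized to the sample grid (nearest
        multiple of dt); a sample on a boundary belongs to the new segment.
        """
        if dt_ms <= 0:
            raise ValueError("dt must be positive (ms)")
        levels = []
        counts = []
        for level, dur in self.expanded_segments:
            n = int(round(dur / dt_ms))
            if n < 1:
                raise ValueError(
                    f"segment of {dur} ms shorter than one sample at dt={dt_ms} ms"
                )
            levels.append(level)
            counts.append(n)
        return np.repeat(np.asarray(levels, dtype=float), counts)


@dataclass
class CurrentTrace:
    """A uniformly sampled membrane-current recording.

    ``current_na`` is the measured membrane current in nA, ``command_mv``
    the voltage command in mV, both sampled every ``dt_ms`` milliseconds.
    ``annotations`` carries event annotations (dicts with at least
    ``time_ms`` and, for injection events, ``amplitude_na``); ``metadata``
    carries units, seed and provenance.
    """

    dt_ms: float
    current_na: np.ndarray
    command_mv: np.ndarray
    annotations: list[dict[str, Any]] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current_na = np.asarray(self.current_na, dtype=float)
        self.command_mv = np.asarray(self.command_mv, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive (ms)")
        if self.current_na.shape != self.command_mv.shape:
            raise ValueError("current and command channels differ in length")
        if self.current_na.ndim != 1:
            raise ValueError("trace channels must be one-dimensional")
        if not np.all(np.isfinite(self.current_na)):
            raise ValueError("trace contains non-finite current samples")

    @property
    def n_samples(self) -> int:
        return self.current_na.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def slice_ms(self, start_ms: float, stop_ms: float) -> "CurrentTrace":
        """Sub-trace over [start, stop) in ms (annotations re-timed)."""
        i0 = int(round(start_ms / self.dt_ms))
        i1 = int(round(stop_ms / self.dt_ms))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        anns = [
            {**a, "time_ms": a["time_ms"] - start_ms}
            for a in self.annotations
            if start_ms <= a.get("time_ms", -1) < stop_ms
        ]
        return CurrentTrace(
            self.dt_ms,
            self.current_na[i0:i1].copy(),
            self.command_mv[i0:i1].copy(),
            anns,
            dict(self.metadata),
        )
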