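"""Pressure protocols: piecewise suction profiles applied at the nozzle.

Pressure is expressed as *suction magnitude* (positive draws the sample
into the pipette), matching the sign convention of the aspiration model.
Presets reproduce the measurement protocols used on the instrument:

* ``trapezoid``  — 100 Pa/s ramp to 1 kPa, 10 s hold, symmetric release
  (quasi-static test on alginate microbeads);
* ``triangle``   — 1500 Pa peak at 150 Pa/s, symmetric, repeated 5x
  (hysteresis curves on flying fish roe);
* ``dma``        — ramp to a 1500 Pa preload, 10 s wait, then 5 periods of a
  60 Pa sinusoid at 0.05/0.1/0.35/0.75/1 Hz separated by 2 s rests;
* ``oocyte``     — ~50 Pa capture, 50 Pa load ramp, 4 s wait, then the same
  oscillation set at reduced (~40 Pa) amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Ramp", "Hold", "Sine", "Rest", "PressureProtocol", "SegmentSpan",
    "trapezoid_protocol", "triangle_protocol", "dma_protocol", "oocyte_protocol",
    "DMA_FREQUENCIES",
]

#: test frequencies of the oscillatory (DMA) protocol, Hz
DMA_FREQUENCIES = (0.05, 0.1, 0.35, 0.75, 1.0)


@dataclass(frozen=True)
class Ramp:
    """Linear ramp toward ``target`` Pa at ``rate`` Pa/s (rate > 0)."""
    rate: float
    target: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("ramp rate must be positive")


@dataclass(frozen=True)
class Hold:
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("hold duration must be positive")


@dataclass(frozen=True)
class Sine:
    """``n_periods`` of ``amplitude * sin(2 pi f t)`` about the current level."""
    amplitude: float
    frequency: float
    n_periods: int = 5

    def __post_init__(self):
        if self.frequency <= 0 or self.amplitude < 0 or self.n_periods < 1:
            raise ValueError("invalid sine segment")


@dataclass(frozen=True)
class Rest:
    """Constant pressure; semantically a pause between oscillation bursts."""
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("rest duration must be positive")


@dataclass(frozen=True)
class SegmentSpan:
    """Resolved time span of one protocol segment."""
    kind: str            # ramp | hold | sine | rest
    t_start: float
    t_end: float
    base_pressure: float          # pressure at segment start (and end, for sine)
    frequency: float | None = None
    amplitude: float | None = None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "t_start": self.t_start, "t_end": self.t_end,
                "base_pressure_Pa": self.base_pressure,
                "frequency_Hz": self.frequency, "amplitude_Pa": self.amplitude}


class PressureProtocol:
    """Ordered, piecewise-continuous suction profile.

    The instantaneous pressure is defined for every t in [0, duration];
    each segment starts from the pressure the previous one ended at, so
    the profile is continuous by construction.
    """

    def __init__(self, segments, start_pressure: float = 0.0):
        self.segments = tuple(segments)
        self.start_pressure = float(start_pressure)
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        self._spans: list[SegmentSpan] = []
        t, p = 0.0, self.start_pressure
        for seg in self.segments:
            if isinstance(seg, Ramp):
                dt = abs(seg.target - p) / seg.rate
                self._spans.append(SegmentSpan("ramp", t, t + dt, p))
                t, p = t + dt, seg.target
            elif isinstance(seg, (Hold, Rest)):
                kind = "hold" if isinstance(seg, Hold) else "rest"
                self._spans.append(SegmentSpan(kind, t, t + seg.duration, p))
                t += seg.duration
            elif isinstance(seg, Sine):
                dt = seg.n_periods / seg.frequency
                self._spans.append(SegmentSpan("sine", t, t + dt, p,
                                               frequency=seg.frequency,
                                               amplitude=seg.amplitude))
                t += dt
            else:
                raise TypeError(f"unknown segment type {type(seg).__name__}")
        self.duration = t

    def segment_spans(self) -> list[SegmentSpan]:
        return list(self._spans)

    def pressure(self, t) -> np.ndarray:
        """Vectorized instantaneous pressure (Pa) at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.start_pressure)
        for seg, span in zip(self.segments, self._spans):
            # include the final instant of the last segment
            last = span is self._spans[-1]
            mask = (t >= span.t_start) & ((t <= span.t_end) if last
                                          else (t < span.t_end))
            if not np.any(mask):
                continue
            tloc = t[mask] - span.t_start
            if span.kind == "ramp":
                sign = math.copysign(1.0, seg.target - span.base_pressure)
                out[mask] = span.base_pressure + sign * seg.rate * tloc
            elif span.kind in ("hold", "rest"):
                out[mask] = span.base_pressure
            else:  # sine
                out[mask] = span.base_pressure + seg.amplitude * np.sin(
                    2.0 * math.pi * seg.frequency * tloc)
            out[t > span.t_end] = _end_pressure(span, seg)
        return out

    def to_descriptor(self) -> dict:
        """JSON-serializable description of the resolved segment timing."""
        return {"duration_s": self.duration,
                "start_pressure_Pa": self.start_pressure,
                "segments": [s.to_dict() for s in self._spans]}


def _end_pressure(span: SegmentSpan, seg) -> float:
    if span.kind == "ramp":
        return seg.target
    return span.base_pressure


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def trapezoid_protocol(peak: float = 1000.0, rate: float = 100.0,
                       hold: float = 10.0) -> PressureProtocol:
    """Trapezoidal suction: ramp up, hold at peak, symmetric release."""
    return PressureProtocol([Ramp(rate, peak), Hold(hold), Ramp(rate, 0.0)])


def triangle_protocol(peak: float = 1500.0, rate: float = 150.0,
                      n_cycles: int = 5) -> PressureProtocol:
    """Triangular loading/unloading repeated ``n_cycles`` times."""
    segs: list = []
    for _ in range(n_cycles):
        segs += [Ramp(rate, peak), Ramp(rate, 0.0)]
    return PressureProtocol(segs)


def dma_protocol(frequencies=DMA_FREQUENCIES, amplitude: float = 60.0,
                 preload: float = 1500.0, preload_rate: float = 150.0,
                 wait: float = 10.0, rest: float = 2.0,
                 n_periods: int = 5) -> PressureProtocol:
    """Oscillatory protocol: preload, wait, then one sine burst per frequency."""
    segs: list = [Ramp(preload_rate, preload), Hold(wait)]
    for i, f in enumerate(frequencies):
        segs.append(Sine(amplitude, f, n_periods))
        if i < len(frequencies) - 1:
            segs.append(Rest(rest))
    return PressureProtocol(segs)


def oocyte_protocol(frequencies=DMA_FREQUENCIES, amplitude: float = 40.0,
                    capture: float = 50.0, load: float = 50.0,
                    wait: float = 4.0, rest: float = 2.0,
                    n_periods: int = 5) -> PressureProtocol:
    """Oocyte test: gentle capture, small load ramp, wait, oscillation set.

    Amplitude defaults to 40 Pa, the middle of the 30-50 Pa range used on
    the zona pellucida.
    """
    segs: list = [Ramp(50.0, capture), Hold(2.0),
                  Ramp(50.0, capture + load), Hold(wait)]
    for i, f in enumerate(frequencies):
        segs.append(Sine(amplitude, f, n_periods))
        if i < len(frequencies) - 1:
            segs.append(Rest(rest))
    return PressureProtocol(segs)
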