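"""Noise filtering of demodulated traces.

Soft biological bodies are overdamped, so their frequency-specific
response is set by the external excitation alone; high-frequency content
of the demodulated phases is detector noise and is removed with a
third-order low-pass Butterworth filter (maximally flat passband).  The
filter is applied forward-backward by default so DMA phase lags are
untouched.  The cutoff can be chosen from the periodogram of the pressure
channel as the frequency where the peak-normalised power density falls
below -40 dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["FilterSpec", "lowpass", "select_cutoff"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter settings (defaults: order 3, 25 Hz)."""

    order: int = 3
    cutoff_hz: float = 25.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")


def lowpass(values: np.ndarray, sampling_rate: float,
            spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Butterworth low-pass of a uniformly sampled trace.

    Zero-phase mode filters forward and backward (squared magnitude
    response, no phase distortion); single-pass mode applies the causal
    filter once.
    """
    values = np.asarray(values, float)
    nyquist = sampling_rate / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz is at or above Nyquist {nyquist} Hz")
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low",
                        fs=sampling_rate, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, values)
    return signal.sosfilt(sos, values)


def select_cutoff(values: np.ndarray, sampling_rate: float,
                  threshold_db: float = -40.0,
                  run_length_hz: float = 5.0,
                  default_hz: float = 25.0,
                  min_duration_s: float = 10.0) -> float:
    """Cutoff frequency from the trace's power spectral density.

    Returns the lowest frequency at which the peak-normalised PSD first
    drops below ``threshold_db`` and stays below for ``run_length_hz``;
    falls back to ``default_hz`` when no such crossing exists (e.g. a flat
    white-noise spectrum).  The PSD is normalised to its maximum so the
    criterion is scale-invariant.
    """
    values = np.asarray(values, float)
    duration = values.size / sampling_rate
    if duration < min_duration_s:
        raise ValueError(
            f"trace of {duration:.1f} s too short for a stable periodogram "
            f"(need >= {min_duration_s:.0f} s)")
    nperseg = min(values.size, int(4 * sampling_rate))
    freqs, psd = signal.welch(values - values.mean(), fs=sampling_rate,
                              nperseg=nperseg)
    psd = psd / psd.max()
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(psd)
    below = db < threshold_db
    df = freqs[1] - freqs[0]
    run = max(1, int(round(run_length_hz / df)))
    # lowest start of a run of `run` consecutive below-threshold bins
    csum = np.cumsum(below.astype(int))
    for i in range(1, below.size - run):
        if csum[i + run - 1] - csum[i - 1] == run:
            return float(freqs[i])
    return float(default_hz)
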