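"""Spectral-domain phase demodulation of interferogram stacks.

Because the spectrometer samples evenly in wavenumber, the Fourier
transform of a frame yields a *cavity space* in which each low-finesse
cavity appears as a peak at its optical path length (OPL = n*d).  The
complex value at a fixed peak bin carries the interferometric phase; its
unwrapped variation over time converts to an OPL variation through

    dOPL_i(t) = phi_i(t) * lambda_bar / (4 pi) = n_i * d_i(t)

and from there to the aspirated length (divide by the medium index, sign
flipped because suction shortens the cavity) or to pressure (sealed air
cavity: dOPL = membrane travel, times the MEMS sensitivity in Pa/nm).

Implementation notes: frames are mean-subtracted and Hann-windowed before
the transform to suppress envelope leakage; the phase is read at a fixed,
non-interpolated bin (only phase variation is meaningful); the effective
``lambda_bar`` is taken as the amplitude-weighted centre of the recorded
spectrum, which makes the phase-to-OPL scale exact for motion small
compared to the cavity-space bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft
from scipy.signal.windows import hann

from .spectral_forward import InterferogramStack, SpectrometerSpec, wavenumber_grid

__all__ = [
    "CavitySpace",
    "PhaseTrace",
    "PeakNotFoundError",
    "AliasedMotionWarning",
    "cavity_space",
    "select_peak",
    "track_phase",
    "phase_to_opl",
    "opl_to_displacement",
    "opl_to_pressure",
    "effective_wavelength",
    "resample_to_k",
    "demodulate_stack",
]

FOUR_PI = 4.0 * math.pi

#: cavity-space bins around DC excluded from peak search (source envelope)
DC_GUARD_BINS = 6

_TRACK_CHUNK = 65536


class PeakNotFoundError(ValueError):
    """No cavity peak of sufficient prominence in the requested OPL window."""


class AliasedMotionWarning(UserWarning):
    """Inter-frame phase step reached pi: motion too fast to unwrap reliably."""


@dataclass
class CavitySpace:
    """One frame transformed to the OPL (cavity) domain."""

    opl: np.ndarray             # m, uniform, starts at 0
    values: np.ndarray          # complex spectrum per bin
    magnitude: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.magnitude = np.abs(self.values)


@dataclass
class PhaseTrace:
    """Unwrapped differential phase of one cavity, zeroed at the first frame."""

    time: np.ndarray
    phi: np.ndarray             # rad
    bin_index: int
    cavity_label: str = ""
    aliased: bool = False


def _window(n: int) -> np.ndarray:
    return hann(n, sym=False)


def _opl_axis(spec: SpectrometerSpec, n_bins: int) -> np.ndarray:
    k = wavenumber_grid(spec)
    dk = k[1] - k[0]
    n = spec.n_pixels
    # fringe cos(2 k L) has cyclic frequency L/pi per unit k
    return math.pi * np.arange(n_bins) / (n * dk)


def cavity_space(frame: np.ndarray, spec: SpectrometerSpec) -> CavitySpace:
    """Transform one mean-subtracted, Hann-windowed frame to cavity space."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape[-1] != spec.n_pixels:
        raise ValueError(
            f"frame has {frame.shape[-1]} pixels, spectrometer expects {spec.n_pixels}")
    w = _window(spec.n_pixels)
    y = (frame - frame.mean()) * w
    values = rfft(y)
    return CavitySpace(opl=_opl_axis(spec, values.shape[-1]), values=values)


def select_peak(space: CavitySpace, window: tuple[float, float],
                dc_guard_bins: int = DC_GUARD_BINS,
                min_prominence: float = 3.0) -> int:
    """Index of the strongest cavity peak inside an OPL window (m).

    The peak must stand ``min_prominence`` times above the median
    magnitude within the window, otherwise no cavity is considered
    present.  Bins inside the DC guard band are never returned.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("empty OPL window")
    if hi > space.opl[-1]:
        raise ValueError(
            f"window reaches {hi * 1e3:.2f} mm, beyond the Nyquist OPL bound "
            f"{space.opl[-1] * 1e3:.2f} mm")
    mask = (space.opl >= lo) & (space.opl <= hi)
    mask[:dc_guard_bins] = False
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("OPL window contains no usable bins")
    mags = space.magnitude[idx]
    best = idx[int(np.argmax(mags))]
    # background excludes the candidate's main lobe (window may be narrow)
    local = idx[np.abs(idx - best) > 3]
    if local.size >= 3:
        background = float(np.median(space.magnitude[local]))
    else:
        background = float(np.median(space.magnitude[dc_guard_bins:]))
    if space.magnitude[best] == 0 or (
            background > 0
            and space.magnitude[best] < min_prominence * background):
        ratio = space.magnitude[best] / background if background > 0 else 0.0
        raise PeakNotFoundError(
            f"no cavity peak found in [{lo * 1e6:.0f}, {hi * 1e6:.0f}] um "
            f"(peak/background = {ratio:.2f})")
    return int(best)


def track_phase(stack: InterferogramStack, bin_index: int,
                cavity_label: str = "") -> PhaseTrace:
    """Unwrapped phase of one cavity bin across all frames.

    The complex cavity-space value at the fixed bin is evaluated with a
    single-bin DFT (identical to the corresponding FFT bin), chunked over
    frames to bound memory.  Phase is unwrapped and zeroed at t = 0; an
    inter-frame step reaching pi is flagged as aliased motion rather than
    silently unwrapped.
    """
    n = stack.spec.n_pixels
    if not 0 <= bin_index <= n // 2:
        raise ValueError("bin index outside cavity space")
    w = _window(n)
    kernel = w * np.exp(-2j * math.pi * bin_index * np.arange(n) / n)
    ksum = kernel.sum()

    T = stack.frames.shape[0]
    z = np.empty(T, dtype=complex)
    for lo in range(0, T, _TRACK_CHUNK):
        hi = min(lo + _TRACK_CHUNK, T)
        block = stack.frames[lo:hi]
        z[lo:hi] = block @ kernel - block.mean(axis=1) * ksum

    raw = np.angle(z)
    steps = np.diff(raw)
    wrapped = (steps + math.pi) % (2.0 * math.pi) - math.pi
    # steps within 5% of +/-pi cannot be distinguished from wrap-around;
    # faster motion aliases silently, so the guard band is deliberately wide
    aliased = bool(np.any(np.abs(wrapped) >= 0.95 * math.pi))
    if aliased:
        warnings.warn(
            "inter-frame phase step approached pi; motion is aliased and the "
            "unwrapped trace is unreliable", AliasedMotionWarning, stacklevel=2)
    phi = np.concatenate(([0.0], np.cumsum(wrapped)))
    return PhaseTrace(time=stack.time, phi=phi, bin_index=bin_index,
                      cavity_label=cavity_label, aliased=aliased)


def phase_to_opl(phase: PhaseTrace | np.ndarray, lambda_bar: float) -> np.ndarray:
    """OPL variation dOPL = phi * lambda_bar / (4 pi), in metres."""
    if lambda_bar <= 0:
        raise ValueError("lambda_bar must be positive")
    phi = phase.phi if isinstance(phase, PhaseTrace) else np.asarray(phase, float)
    return phi * lambda_bar / FOUR_PI


def opl_to_displacement(dopl: np.ndarray, n_medium: float) -> np.ndarray:
    """Aspirated length from the sample-cavity OPL variation.

    Suction shortens the fibre-to-sample cavity, so the aspirated length
    is reported positive into the pipette: ``L_p = -dOPL / n_medium``.
    """
    if n_medium < 1.0:
        raise ValueError("medium refractive index must be >= 1")
    return -np.asarray(dopl, float) / n_medium


def opl_to_pressure(dopl: np.ndarray, sensitivity: float) -> np.ndarray:
    """Pressure from the sealed MEMS cavity OPL variation.

    The pressure cavity is air-filled (n = 1), so dOPL equals the membrane
    travel; ``sensitivity`` is in Pa per nm.  Suction is positive when the
    cavity lengthens.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    return np.asarray(dopl, float) * 1e9 * sensitivity


def effective_wavelength(mean_frame: np.ndarray, spec: SpectrometerSpec,
                         guard_bins: int = DC_GUARD_BINS) -> float:
    """Amplitude-weighted mean wavelength of the recorded spectrum (m).

    The phase of a windowed cavity peak advances as
    ``2 * k_eff * dOPL`` with ``k_eff`` the centroid of the wavenumber grid
    weighted by window times source envelope.  The envelope is estimated
    from the mean frame with the fringes removed (cavity-space bins beyond
    the DC guard zeroed), which makes the phase-to-OPL conversion
    self-calibrating.
    """
    mean_frame = np.asarray(mean_frame, dtype=float)
    n = spec.n_pixels
    if mean_frame.shape[-1] != n:
        raise ValueError("mean frame length does not match the spectrometer")
    spectrum = rfft(mean_frame)
    spectrum[guard_bins:] = 0.0
    envelope = np.clip(irfft(spectrum, n=n), 0.0, None)
    weight = _window(n) * envelope
    total = weight.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: cannot estimate lambda_bar")
    k = wavenumber_grid(spec)
    k_eff = float((weight * k).sum() / total)
    return 2.0 * math.pi / k_eff


def resample_to_k(wavelengths_nm: np.ndarray, intensities: np.ndarray,
                  spec: SpectrometerSpec) -> np.ndarray:
    """Resample a spectrum given on a wavelength grid onto the uniform k grid.

    Helper for data from spectrometers sampled evenly in wavelength; the
    native pipeline assumes k-even sampling and never calls this.
    """
    lam = np.asarray(wavelengths_nm, float)
    inten = np.asarray(intensities, float)
    order = np.argsort(lam)
    k_native = 2.0 * math.pi / (lam[order] * 1e-9)
    return np.interp(wavenumber_grid(spec), k_native[::-1], inten[order][::-1])


# ---------------------------------------------------------------------------
# high-level chain
# ---------------------------------------------------------------------------

@dataclass
class DemodulationResult:
    """Calibrated time series recovered from one interferogram stack."""

    time: np.ndarray
    pressure: np.ndarray          # Pa
    displacement: np.ndarray      # m, aspirated length
    sample_bin: int
    pressure_bin: int
    lambda_bar: float             # m, effective conversion wavelength
    n_medium: float
    sensitivity: float
    aliased: bool = False

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_s": self.time, "pressure_Pa": self.pressure,
                             "Lp_m": self.displacement})

    def metadata(self) -> dict:
        return {"sample_bin": self.sample_bin, "pressure_bin": self.pressure_bin,
                "lambda_bar_m": self.lambda_bar, "n_medium": self.n_medium,
                "sensitivity_Pa_per_nm": self.sensitivity, "aliased": self.aliased}


def demodulate_stack(stack: InterferogramStack,
                     sample_window: tuple[float, float],
                     pressure_window: tuple[float, float],
                     n_medium: float = 1.331,
                     sensitivity: float = 76.59,
                     lambda_bar: float | None = None) -> DemodulationResult:
    """Full readout: stack -> calibrated pressure and displacement traces.

    ``sample_window``/``pressure_window`` are OPL intervals (m) bracketing
    the two cavity peaks.  ``lambda_bar`` defaults to the effective mean
    wavelength estimated from the data (see :func:`effective_wavelength`).
    """
    mean_frame = stack.frames.mean(axis=0)
    space = cavity_space(mean_frame, stack.spec)
    sample_bin = select_peak(space, sample_window)
    pressure_bin = select_peak(space, pressure_window)
    if sample_bin == pressure_bin:
        raise ValueError("sample and pressure windows select the same peak")

    if lambda_bar is None:
        lambda_bar = effective_wavelength(mean_frame, stack.spec)

    sample_phase = track_phase(stack, sample_bin, "sample")
    pressure_phase = track_phase(stack, pressure_bin, "pressure")

    displacement = opl_to_displacement(phase_to_opl(sample_phase, lambda_bar),
                                       n_medium)
    pressure = opl_to_pressure(phase_to_opl(pressure_phase, lambda_bar),
                               sensitivity)
    return DemodulationResult(
        time=stack.time, pressure=pressure, displacement=displacement,
        sample_bin=sample_bin, pressure_bin=pressure_bin,
        lambda_bar=float(lambda_bar), n_medium=n_medium,
        sensitivity=sensitivity,
        aliased=sample_phase.aliased or pressure_phase.aliased)
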