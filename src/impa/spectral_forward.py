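"""Physics-forward model of the two-cavity fibre-optic aspiration probe.

The probe multiplexes two low-finesse extrinsic Fabry-Perot cavities onto a
single broadband source read by a spectrometer that samples evenly in
wavenumber ``k``:

* the *sample* cavity — fibre end-facet to the aspirated sample surface,
  filled with the working medium (water, n = 1.331).  Suction draws the
  sample toward the fibre, so this cavity shortens by the aspirated length
  ``L_p(t)``.
* the *pressure* cavity — fibre to the MEMS membrane of the sealed
  pressure sensor (air, n = 1).  The membrane deflects linearly with
  pressure, ``d(t) = d_rest + P(t)/S`` with ``S`` the membrane sensitivity
  in Pa/nm.

Each cavity contributes a single cosine fringe to the recorded spectrum
(two-beam approximation, valid at low finesse):

    I(k) = E0(k) * [1 + sum_i V_i cos(2 k n_i d_i + phi_i)] + noise

with ``E0`` the Gaussian source envelope.  The simulator renders whole
experiments (pressure protocol + sample mechanics) into interferogram
stacks together with the ground-truth kinematics, and doubles as the test
fixture generator for the demodulation and analysis chain.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .quasistatic import BETA1, BETA3, GeometryParams, geometry_factor

__all__ = [
    "SpectrometerSpec",
    "OpticalCavity",
    "ProbeConfig",
    "SampleModel",
    "AcquisitionConfig",
    "GroundTruth",
    "InterferogramStack",
    "wavenumber_grid",
    "source_envelope",
    "simulate_frame",
    "sample_response",
    "simulate_experiment",
]

TWO_PI = 2.0 * math.pi

#: refractive index of water at 1550 nm, the default working medium
WATER_RI = 1.331

#: frames rendered per block to bound peak memory on long acquisitions
_RENDER_CHUNK = 32768


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrometerSpec:
    """Spectrometer and source geometry.

    Defaults reproduce the instrument's transmission-grating spectrometer
    (1510-1595 nm range, 166 pm pixel pitch) and a superluminescent diode
    source centred at 1550 nm with 50 nm FWHM.
    """

    lambda_min_nm: float = 1510.0
    lambda_max_nm: float = 1595.0
    pixel_pitch_nm: float = 0.166
    center_wavelength_nm: float = 1550.0
    source_fwhm_nm: float = 50.0

    def __post_init__(self) -> None:
        if not self.lambda_min_nm < self.center_wavelength_nm < self.lambda_max_nm:
            raise ValueError("center wavelength must lie inside the span")
        if self.pixel_pitch_nm <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.n_pixels < 2:
            raise ValueError("degenerate wavelength span")
        if self.source_fwhm_nm <= 0:
            raise ValueError("source FWHM must be positive")

    @property
    def n_pixels(self) -> int:
        return int((self.lambda_max_nm - self.lambda_min_nm) / self.pixel_pitch_nm)

    @property
    def wavenumber_span(self) -> float:
        """Span of the k grid, ``2 pi (1/lambda_min - 1/lambda_max)`` in rad/m."""
        return TWO_PI * (1.0 / (self.lambda_min_nm * 1e-9)
                         - 1.0 / (self.lambda_max_nm * 1e-9))

    @property
    def max_opl(self) -> float:
        """Nyquist bound on recoverable optical path length (m).

        A fringe ``cos(2 k L)`` is sampled at the pixel pitch; aliasing sets
        in at ``L = lambda_bar^2 / (4 * pitch)`` (~3.6 mm at the defaults).
        """
        lam = self.center_wavelength_nm * 1e-9
        return lam * lam / (4.0 * self.pixel_pitch_nm * 1e-9)


def wavenumber_grid(spec: SpectrometerSpec) -> np.ndarray:
    """Uniform wavenumber grid (rad/m), strictly increasing.

    The spectrometer is even in k-space; the grid spans
    ``[2 pi / lambda_max, 2 pi / lambda_min]`` with one point per pixel.
    """
    if spec.lambda_min_nm >= spec.lambda_max_nm:
        raise ValueError("degenerate wavelength span")
    k_lo = TWO_PI / (spec.lambda_max_nm * 1e-9)
    k_hi = TWO_PI / (spec.lambda_min_nm * 1e-9)
    return np.linspace(k_lo, k_hi, spec.n_pixels)


def source_envelope(spec: SpectrometerSpec, k: np.ndarray | None = None) -> np.ndarray:
    """Gaussian source spectrum evaluated on the wavenumber grid.

    The source is specified by its FWHM in wavelength; the envelope is a
    Gaussian in lambda mapped onto the k grid (peak normalised to 1).
    """
    if k is None:
        k = wavenumber_grid(spec)
    lam_nm = TWO_PI / k * 1e9
    x = (lam_nm - spec.center_wavelength_nm) / spec.source_fwhm_nm
    return np.exp(-4.0 * math.log(2.0) * x * x)


@dataclass(frozen=True)
class OpticalCavity:
    """One low-finesse Fabry-Perot cavity: a single cosine fringe."""

    label: str
    geometric_length: float  # m
    refractive_index: float = 1.0
    visibility: float = 0.3
    phase_offset: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.geometric_length <= 0:
            raise ValueError("cavity length must be positive")
        if not 1.0 <= self.refractive_index <= 3.0:
            raise ValueError("refractive index out of physical range [1, 3]")
        if not 0.0 <= self.visibility <= 1.0:
            raise ValueError("visibility must lie in [0, 1]")

    @property
    def opl(self) -> float:
        """Optical path length n*d (m); sets the cavity-space peak position."""
        return self.refractive_index * self.geometric_length


@dataclass(frozen=True)
class ProbeConfig:
    """Probe-level geometry and transduction constants.

    The two working cavities must differ in optical path length by more
    than the cavity-space resolution so their peaks separate after the
    Fourier transform ("of different lengths by design").
    """

    sample_cavity_rest_length: float = 500e-6     # m, fibre to sample surface
    medium_ri: float = WATER_RI
    pressure_cavity_rest_length: float = 300e-6   # m, fibre to MEMS membrane
    mems_sensitivity: float = 76.59               # Pa per nm of membrane travel
    pipette_radius: float = 45e-6                 # m
    sample_visibility: float = 0.30
    pressure_visibility: float = 0.40
    extra_cavities: tuple[OpticalCavity, ...] = ()

    def __post_init__(self) -> None:
        if self.mems_sensitivity <= 0:
            raise ValueError("MEMS sensitivity must be positive")
        if self.pipette_radius <= 0:
            raise ValueError("pipette radius must be positive")
        if self.sample_cavity_rest_length <= 0 or self.pressure_cavity_rest_length <= 0:
            raise ValueError("cavity rest lengths must be positive")
        if self.medium_ri < 1.0:
            raise ValueError("medium refractive index must be >= 1")

    def sample_opl(self) -> float:
        return self.medium_ri * self.sample_cavity_rest_length

    def pressure_opl(self) -> float:
        return self.pressure_cavity_rest_length  # air, n = 1

    def validate_separation(self, spec: SpectrometerSpec) -> None:
        """Require peak separation larger than one cavity-space bin."""
        bin_m = math.pi / spec.wavenumber_span
        if abs(self.sample_opl() - self.pressure_opl()) <= bin_m:
            raise ValueError(
                "sample and pressure cavity OPLs are not separable "
                f"(need > {bin_m * 1e6:.1f} um apart)")


# ---------------------------------------------------------------------------
# sample mechanics
# ---------------------------------------------------------------------------

#: Poisson ratio of the aspirated body; the linearized aspiration model is
#: derived for incompressible media and the constant is not user-settable.
POISSON_RATIO = 0.5


@dataclass(frozen=True)
class SampleModel:
    """Ground-truth constitutive behaviour of the aspirated body.

    Variants
    --------
    ``elastic``
        single Young's modulus ``E`` (Pa); response is instantaneous and
        exactly proportional to pressure.
    ``fixed_complex``
        a table ``{frequency_Hz: (E', E'')}``; steady-state sinusoidal
        response at the tabulated frequencies only.
    ``power_law``
        two-term rheology ``E*(w) = A (i w)^alpha + B (i w)^(3/4)``.
    """

    variant: str
    E: float | None = None
    complex_table: tuple[tuple[float, tuple[float, float]], ...] = ()
    A: float | None = None
    alpha: float | None = None
    B: float | None = None
    sample_radius: float | None = None  # m; None = infinite half-space
    frequency_convention: str = "rad_s"

    def __post_init__(self) -> None:
        if self.variant not in ("elastic", "fixed_complex", "power_law"):
            raise ValueError(f"unknown sample variant {self.variant!r}")
        if self.variant == "elastic" and (self.E is None or self.E <= 0):
            raise ValueError("elastic model requires E > 0")
        if self.variant == "fixed_complex":
            if not self.complex_table:
                raise ValueError("fixed_complex model requires a frequency table")
            for f, (ep, epp) in self.complex_table:
                if f <= 0 or ep <= 0 or epp < 0:
                    raise ValueError("fixed_complex table requires f, E' > 0 and E'' >= 0")
        if self.variant == "power_law":
            if self.A is None or self.alpha is None or self.B is None:
                raise ValueError("power_law model requires A, alpha, B")
            if self.A < 0 or self.B < 0 or not 0.0 <= self.alpha <= 1.0:
                raise ValueError("power_law requires A, B >= 0 and alpha in [0, 1]")
        if self.sample_radius is not None and self.sample_radius <= 0:
            raise ValueError("sample radius must be positive or None (half-space)")

    # -- constructors -------------------------------------------------------

    @classmethod
    def elastic(cls, E: float, sample_radius: float | None = None) -> "SampleModel":
        return cls(variant="elastic", E=E, sample_radius=sample_radius)

    @classmethod
    def fixed_complex(cls, table: dict[float, tuple[float, float]],
                      sample_radius: float | None = None) -> "SampleModel":
        items = tuple(sorted((float(f), (float(ep), float(epp)))
                             for f, (ep, epp) in table.items()))
        return cls(variant="fixed_complex", complex_table=items,
                   sample_radius=sample_radius)

    @classmethod
    def power_law(cls, A: float, alpha: float, B: float,
                  sample_radius: float | None = None,
                  frequency_convention: str = "rad_s") -> "SampleModel":
        return cls(variant="power_law", A=A, alpha=alpha, B=B,
                   sample_radius=sample_radius,
                   frequency_convention=frequency_convention)

    # -- constitutive evaluation -------------------------------------------

    def complex_modulus(self, frequency_hz: float) -> complex:
        """E*(f) as a complex number (Pa) at a drive frequency in Hz."""
        if self.variant == "elastic":
            return complex(self.E, 0.0)
        if self.variant == "fixed_complex":
            for f, (ep, epp) in self.complex_table:
                if math.isclose(f, frequency_hz, rel_tol=1e-9, abs_tol=1e-12):
                    return complex(ep, epp)
            raise KeyError(
                f"frequency {frequency_hz} Hz not in fixed_complex table "
                f"{[f for f, _ in self.complex_table]}")
        from .dma import power_law_eval
        return power_law_eval(frequency_hz, self.A, self.alpha, self.B,
                              convention=self.frequency_convention)

    def quasistatic_modulus(self, lowest_frequency_hz: float | None = None) -> float:
        """|E*| used for ramps and holds.

        For the elastic variant this is ``E``.  For frequency-dependent
        variants the magnitude at the lowest defined (or lowest protocol)
        frequency stands in for the quasi-static stiffness.
        """
        if self.variant == "elastic":
            return float(self.E)
        if self.variant == "fixed_complex":
            f0 = self.complex_table[0][0]
            return abs(self.complex_modulus(f0))
        if lowest_frequency_hz is None:
            lowest_frequency_hz = 0.05
        return abs(self.complex_modulus(lowest_frequency_hz))


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

def simulate_frame(cavities: list[OpticalCavity] | tuple[OpticalCavity, ...],
                   spec: SpectrometerSpec,
                   noise_sd: float = 0.0,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one spectrometer frame from a set of cavities.

    Implements the two-beam model
    ``I(k) = E0(k) [1 + sum V_i cos(2 k n_i d_i + phi_i)] + noise``.
    """
    if len(cavities) == 0:
        raise ValueError("cavity list must be non-empty")
    vis_sum = sum(c.visibility for c in cavities)
    if vis_sum > 1.0:
        warnings.warn(f"total fringe visibility {vis_sum:.2f} > 1 is unphysical",
                      stacklevel=2)
    k = wavenumber_grid(spec)
    env = source_envelope(spec, k)
    fringes = np.zeros_like(k)
    for cav in cavities:
        fringes += cav.visibility * np.cos(2.0 * k * cav.opl + cav.phase_offset)
    frame = env * (1.0 + fringes)
    if noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
    return frame


# ---------------------------------------------------------------------------
# acquisition, ground truth, stack
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition settings.  The instrument records interferograms at 1 kHz.

    ``intensity_noise_sd`` is additive white Gaussian noise per pixel in
    units of the peak source envelope; the default of 1% leaves the
    demodulated displacement noise floor a few Angstrom at 1 kHz,
    i.e. comfortably sub-nanometer.
    """

    sampling_rate: float = 1000.0
    intensity_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.intensity_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class GroundTruth:
    """True kinematics on the shared acquisition clock (suction positive)."""

    time: np.ndarray                  # s
    pressure: np.ndarray              # Pa
    aspirated_length: np.ndarray      # m, positive into the pipette
    sample_cavity_length: np.ndarray  # m
    mems_cavity_length: np.ndarray    # m

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_s": self.time,
                             "pressure_Pa": self.pressure,
                             "Lp_m": self.aspirated_length})


@dataclass
class InterferogramStack:
    """Time-ordered spectrometer frames plus acquisition metadata."""

    time: np.ndarray        # s, shape (T,)
    frames: np.ndarray      # shape (T, n_pixels)
    spec: SpectrometerSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.shape[0] != self.time.shape[0]:
            raise ValueError("one frame per time point required")

    @property
    def sampling_rate(self) -> float:
        if len(self.time) < 2:
            return float("nan")
        return 1.0 / float(self.time[1] - self.time[0])


def _config_digest(*objs) -> str:
    blob = json.dumps([repr(o) for o in objs], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# mechanics: protocol pressure -> aspirated length
# ---------------------------------------------------------------------------

def sample_response(model: SampleModel, protocol, pipette_radius: float,
                    time: np.ndarray,
                    sample_radius: float | None = None) -> np.ndarray:
    """Aspirated length L_p(t) for a pressure protocol and sample model.

    The quasi-static (elastic) branch inverts the linearized aspiration
    relation ``dP/E = beta1 [1 - (Rp/Rc)^beta3] / 3 * Lp/Rp``; sinusoidal
    segments of viscoelastic samples respond at steady state with
    amplitude ``L0 = Rp/G* * P0/|E*(w)|`` and phase lag ``delta = arg E*``.
    Ramp/hold creep of viscoelastic samples is not modelled: those
    segments use the quasi-static modulus magnitude.
    """
    if sample_radius is None:
        sample_radius = model.sample_radius
    geom = GeometryParams(pipette_radius=pipette_radius, sample_radius=sample_radius)
    gstar = geometry_factor(geom)
    time = np.asarray(time, dtype=float)
    pressure = protocol.pressure(time)

    if model.variant == "elastic":
        return pressure * pipette_radius / (gstar * model.E)

    sine_freqs = [s.frequency for s in protocol.segment_spans() if s.kind == "sine"]
    e_qs = model.quasistatic_modulus(min(sine_freqs) if sine_freqs else None)
    if e_qs == 0:
        raise ValueError("quasi-static |E*| is zero")
    lp = pressure * pipette_radius / (gstar * e_qs)
    for span in protocol.segment_spans():
        if span.kind != "sine":
            continue
        estar = model.complex_modulus(span.frequency)
        if abs(estar) == 0:
            raise ValueError(f"|E*| = 0 at {span.frequency} Hz")
        delta = math.atan2(estar.imag, estar.real)
        mask = (time >= span.t_start) & (time < span.t_end)
        tloc = time[mask] - span.t_start
        l_base = span.base_pressure * pipette_radius / (gstar * e_qs)
        l0 = span.amplitude * pipette_radius / (gstar * abs(estar))
        lp[mask] = l_base + l0 * np.sin(TWO_PI * span.frequency * tloc - delta)
    return lp


# ---------------------------------------------------------------------------
# whole-instrument forward model
# ---------------------------------------------------------------------------

def simulate_experiment(probe: ProbeConfig, sample: SampleModel, protocol,
                        acq: AcquisitionConfig,
                        spec: SpectrometerSpec | None = None,
                        ) -> tuple[InterferogramStack, GroundTruth]:
    """Render a full experiment: protocol -> kinematics -> interferograms.

    The sample cavity shortens by the aspirated length (suction pulls the
    surface toward the fibre); the sealed MEMS cavity lengthens by
    ``P/S``.  Static parasitic cavities from ``probe.extra_cavities`` are
    added unchanged to every frame.  Reproducible bit-for-bit from
    ``acq.seed``.
    """
    if spec is None:
        spec = SpectrometerSpec()
    probe.validate_separation(spec)

    sine_freqs = [s.frequency for s in protocol.segment_spans() if s.kind == "sine"]
    if sine_freqs and acq.sampling_rate <= 2.0 * max(sine_freqs):
        raise ValueError("sampling rate violates Nyquist for the protocol")

    n_frames = max(2, int(round(protocol.duration * acq.sampling_rate)))
    time = np.arange(n_frames) / acq.sampling_rate
    pressure = protocol.pressure(time)
    lp = sample_response(sample, protocol, probe.pipette_radius, time)

    d_sample = probe.sample_cavity_rest_length - lp
    # sensitivity is Pa per nm of membrane travel
    d_mems = probe.pressure_cavity_rest_length + pressure / probe.mems_sensitivity * 1e-9
    if np.any(d_sample <= 0):
        raise ValueError("aspirated length exceeds the sample cavity rest length")

    rng = np.random.default_rng(acq.seed)
    # one static phase origin per cavity; only phase *variation* carries signal
    phi_sample, phi_mems = rng.uniform(0.0, TWO_PI, size=2)

    k = wavenumber_grid(spec)
    env = source_envelope(spec, k)
    static = np.zeros_like(k)
    for cav in probe.extra_cavities:
        static += cav.visibility * np.cos(2.0 * k * cav.opl + cav.phase_offset)

    frames = np.empty((n_frames, spec.n_pixels))
    n_med = probe.medium_ri
    for lo in range(0, n_frames, _RENDER_CHUNK):
        hi = min(lo + _RENDER_CHUNK, n_frames)
        block = np.cos(2.0 * np.outer(n_med * d_sample[lo:hi], k) + phi_sample)
        block *= probe.sample_visibility
        block += probe.pressure_visibility * np.cos(
            2.0 * np.outer(d_mems[lo:hi], k) + phi_mems)
        block += 1.0 + static
        block *= env
        if acq.intensity_noise_sd > 0:
            block += rng.normal(0.0, acq.intensity_noise_sd, size=block.shape)
        frames[lo:hi] = block

    stack = InterferogramStack(
        time=time, frames=frames, spec=spec,
        provenance={"seed": acq.seed,
                    "config_digest": _config_digest(probe, sample, protocol, acq, spec)})
    truth = GroundTruth(time=time, pressure=pressure, aspirated_length=lp,
                        sample_cavity_length=d_sample, mems_cavity_length=d_mems)
    return stack, truth
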