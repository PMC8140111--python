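"""Dynamic mechanical analysis of aspiration records.

A sinusoidal suction ``P(t) = P0 sin(wt + d_P)`` drives a steady-state
aspirated-length response ``L_p(t) = L0 sin(wt + d_L)`` that lags the
drive by ``delta = d_P - d_L`` in a viscoelastic body.  Amplitudes and
phases are extracted per frequency by linear least squares on the basis
{sin wt, cos wt, 1, t} (the {1, t} terms absorb offsets and residual
creep drift), and the complex modulus follows from the aspiration
geometry factor:

    E* = R_p / G* * P0/L0 * exp(i delta),   E' = |E*| cos d,  E'' = |E*| sin d

A two-term power law, ``E*(w) = A (i w)^alpha + B (i w)^(3/4)``, is fitted
across frequencies to summarise the dispersion.  The frequency-unit
convention for the power law (rad/s vs Hz) is an explicit flag recorded in
every result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .quasistatic import GeometryParams, geometry_factor

__all__ = [
    "OscillationFit",
    "ComplexModulusResult",
    "PowerLawFit",
    "fit_oscillation",
    "phase_lag",
    "complex_modulus",
    "power_law_eval",
    "power_law_fit",
    "analyze_dma",
]

TWO_PI = 2.0 * math.pi

#: small negative phase lags are measurement noise and clamp to zero
PHASE_CLAMP_TOL = 0.01  # rad


@dataclass(frozen=True)
class OscillationFit:
    """Single-frequency sinusoid fit of one channel."""

    frequency: float       # Hz
    omega: float           # rad/s
    amplitude: float       # signal units, >= 0
    phase: float           # rad, in (-pi, pi]
    offset: float
    drift_slope: float     # units/s
    residual_rms: float


@dataclass(frozen=True)
class ComplexModulusResult:
    """Per-frequency viscoelastic moduli from a pressure/length pair."""

    frequency: float       # Hz
    e_star: float          # |E*|, Pa
    delta: float           # rad, in [0, pi/2]
    e_prime: float         # storage modulus, Pa
    e_doubleprime: float   # loss modulus, Pa
    tan_delta: float

    def to_dict(self) -> dict:
        return {"frequency_Hz": self.frequency, "E_star_Pa": self.e_star,
                "delta_rad": self.delta, "E_prime_Pa": self.e_prime,
                "E_doubleprime_Pa": self.e_doubleprime,
                "tan_delta": self.tan_delta}


@dataclass(frozen=True)
class PowerLawFit:
    """Two-term power-law rheology parameters."""

    A: float               # Pa
    alpha: float
    B: float               # Pa
    residual: float        # Pa, rms over stacked real/imag residuals
    convention: str        # 'rad_s' or 'hz'

    def to_dict(self) -> dict:
        return {"A_Pa": self.A, "alpha": self.alpha, "B_Pa": self.B,
                "residual_Pa": self.residual,
                "frequency_unit_convention": self.convention}


def fit_oscillation(values: np.ndarray, time: np.ndarray,
                    frequency: float) -> OscillationFit:
    """Least-squares sinusoid + linear-drift fit at a known frequency.

    The trace must cover at least two full periods.  With the model
    ``a sin(wt) + b cos(wt) + c + d t`` the amplitude is ``sqrt(a^2+b^2)``
    and the phase ``atan2(b, a)``, so a pure ``A sin(wt + p)`` returns
    amplitude A and phase p exactly; over an integer number of periods the
    drift basis is orthogonal to the sinusoid and leaves it untouched.
    """
    values = np.asarray(values, float)
    time = np.asarray(time, float)
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    span = time[-1] - time[0]
    if span * frequency < 2.0:
        raise ValueError(
            f"trace covers {span * frequency:.2f} periods; need >= 2")
    w = TWO_PI * frequency
    t0 = time[0]
    design = np.column_stack([np.sin(w * (time - t0)), np.cos(w * (time - t0)),
                              np.ones_like(time), time - t0])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    a, b, c, d = coef
    resid = values - design @ coef
    phase = math.atan2(b, a)
    return OscillationFit(frequency=frequency, omega=w,
                          amplitude=float(np.hypot(a, b)), phase=float(phase),
                          offset=float(c), drift_slope=float(d),
                          residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def phase_lag(delta_p: float, delta_l: float,
              tol: float = PHASE_CLAMP_TOL) -> float:
    """Phase lag delta = delta_P - delta_L, wrapped and validated.

    Physically the response lags the drive: delta must lie in [0, pi/2].
    Values in [-tol, 0) are clamped to zero (numerically elastic); values
    outside the physical range raise.
    """
    d = (delta_p - delta_l + math.pi) % TWO_PI - math.pi
    if -tol <= d < 0.0:
        warnings.warn(f"phase lag {d:.4f} rad slightly negative; clamped to 0",
                      stacklevel=2)
        d = 0.0
    if not 0.0 <= d <= math.pi / 2:
        raise ValueError(
            f"unphysical phase lag {d:.3f} rad (response leading the drive "
            "or anti-phased)")
    return d


def complex_modulus(p0: float, l0: float, delta: float,
                    geom: GeometryParams) -> ComplexModulusResult:
    """Complex modulus from oscillation amplitudes and phase lag.

    ``|E*| = R_p/G* * P0/L0`` with the aspiration geometry factor G*;
    storage and loss moduli are the in-phase and quadrature parts.
    """
    if l0 <= 0:
        raise ValueError("length amplitude must be positive")
    if not 0.0 <= delta <= math.pi / 2:
        raise ValueError("delta must lie in [0, pi/2]; apply phase_lag first")
    gstar = geometry_factor(geom)
    mag = geom.pipette_radius / gstar * p0 / l0
    ep = mag * math.cos(delta)
    epp = mag * math.sin(delta)
    return ComplexModulusResult(frequency=float("nan"), e_star=float(mag),
                                delta=float(delta), e_prime=float(ep),
                                e_doubleprime=float(epp),
                                tan_delta=float(math.tan(delta)))


def _omega(frequency_hz, convention: str):
    if convention == "rad_s":
        return TWO_PI * np.asarray(frequency_hz, float)
    if convention == "hz":
        return np.asarray(frequency_hz, float)
    raise ValueError("convention must be 'rad_s' or 'hz'")


def power_law_eval(frequency_hz, A: float, alpha: float, B: float,
                   convention: str = "rad_s"):
    """Two-term power law E*(w) = A (i w)^alpha + B (i w)^(3/4).

    ``(i w)^x = w^x exp(i pi x / 2)`` for w > 0.  ``frequency_hz`` is the
    drive frequency in Hz; ``convention`` selects whether w enters the
    power law as angular frequency (rad/s, default) or plain Hz.
    """
    w = _omega(frequency_hz, convention)
    if np.any(w <= 0):
        raise ValueError("frequency must be positive")
    term_a = A * w ** alpha * np.exp(1j * math.pi * alpha / 2.0)
    term_b = B * w ** 0.75 * np.exp(1j * 3.0 * math.pi / 8.0)
    out = term_a + term_b
    return complex(out) if np.isscalar(frequency_hz) else out


def power_law_fit(frequencies_hz, e_prime, e_doubleprime,
                  convention: str = "rad_s") -> PowerLawFit:
    """Fit (A, alpha, B) to measured storage/loss moduli across frequency.

    Nonlinear least squares on the stacked real and imaginary residuals
    with bounds A, B >= 0 and alpha in [0, 1]; several alpha starting
    points guard against the shallow valley in alpha.
    """
    f = np.asarray(frequencies_hz, float)
    ep = np.asarray(e_prime, float)
    epp = np.asarray(e_doubleprime, float)
    if f.size < 3:
        raise ValueError("need at least 3 frequencies to fit 3 parameters")
    if f.size != ep.size or f.size != epp.size:
        raise ValueError("frequency and modulus arrays must align")

    w = _omega(f, convention)

    def residuals(theta):
        a, al, b = theta
        model = power_law_eval(f, a, al, b, convention)
        return np.concatenate([model.real - ep, model.imag - epp])

    w_hi = float(w.max())
    best = None
    for alpha0 in (0.05, 0.1, 0.2, 0.5):
        a0 = max(float(np.median(ep)), 1e-12)
        # seed B from what the A-term leaves unexplained at the top frequency
        resid_hi = float(ep[np.argmax(w)]) - a0 * w_hi ** alpha0 * math.cos(
            math.pi * alpha0 / 2.0)
        b0 = max(resid_hi / (w_hi ** 0.75 * math.cos(3.0 * math.pi / 8.0)), 0.0)
        try:
            sol = least_squares(residuals, x0=[a0, alpha0, b0],
                                bounds=([0.0, 0.0, 0.0], [np.inf, 1.0, np.inf]),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("power-law fit failed to converge from any start")
    a, al, b = best.x
    rms = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return PowerLawFit(A=float(a), alpha=float(al), B=float(b),
                       residual=rms, convention=convention)


def analyze_dma(time: np.ndarray, pressure: np.ndarray,
                displacement: np.ndarray, segments,
                geom: GeometryParams) -> list[ComplexModulusResult]:
    """Per-frequency complex moduli from demodulated channels.

    ``segments`` is an iterable of protocol segment spans (see
    ``protocols.SegmentSpan``); each ``sine`` span is fitted independently
    over its full (integer-period) extent.
    """
    time = np.asarray(time, float)
    results = []
    for span in segments:
        kind = span.kind if hasattr(span, "kind") else span["kind"]
        if kind != "sine":
            continue
        t0 = span.t_start if hasattr(span, "t_start") else span["t_start"]
        t1 = span.t_end if hasattr(span, "t_end") else span["t_end"]
        freq = span.frequency if hasattr(span, "frequency") else span["frequency_Hz"]
        mask = (time >= t0) & (time < t1)
        fit_p = fit_oscillation(pressure[mask], time[mask], freq)
        fit_l = fit_oscillation(displacement[mask], time[mask], freq)
        delta = phase_lag(fit_p.phase, fit_l.phase)
        res = complex_modulus(fit_p.amplitude, fit_l.amplitude, delta, geom)
        results.append(ComplexModulusResult(
            frequency=float(freq), e_star=res.e_star, delta=res.delta,
            e_prime=res.e_prime, e_doubleprime=res.e_doubleprime,
            tan_delta=res.tan_delta))
    return results
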