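"""Quasi-static elastic analysis of aspiration curves.

The aspirated length of an incompressible body drawn into a pipette of
radius ``R_p`` follows, in the small-strain (linearized Zhou/Plaza) regime,

    dP / E = beta1 [1 - (R_p/R_c)^beta3] / 3 * L_p / R_p

where ``R_c`` is the radius of the aspirated body and the beta constants
come from the finite-element calibration of the model (beta1 = 2.0142,
beta3 = 2.1187 for nu = 0.5).  Fitting the slope of L_p against P over the
loading ramp therefore yields the Young's modulus E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BETA1",
    "BETA3",
    "GeometryParams",
    "QuasiStaticResult",
    "geometry_factor",
    "fit_elastic_modulus",
    "radial_strain",
    "hydrostatic_pressure",
]

BETA1 = 2.0142
BETA3 = 2.1187


@dataclass(frozen=True)
class GeometryParams:
    """Pipette/sample geometry for the linearized aspiration model.

    ``sample_radius=None`` selects the infinite half-space limit
    (appropriate when the deformed layer is much thicker than the
    deformation, e.g. the zona pellucida of an oocyte).
    """

    pipette_radius: float                 # m
    sample_radius: float | None = None    # m; None = half-space
    beta1: float = BETA1
    beta3: float = BETA3

    def __post_init__(self) -> None:
        if self.pipette_radius <= 0:
            raise ValueError("pipette radius must be positive")
        if self.sample_radius is not None and np.isinf(self.sample_radius):
            object.__setattr__(self, "sample_radius", None)
        if self.sample_radius is not None and self.sample_radius <= self.pipette_radius:
            raise ValueError("sample radius must exceed the pipette radius")


def geometry_factor(geom: GeometryParams) -> float:
    """Dimensionless factor G* = beta1 [1 - (R_p/R_c)^beta3] / 3.

    Relates modulus and compliance: ``L_p = R_p P / (G* E)``.  In the
    half-space limit G* = beta1/3; it decreases toward zero as the pipette
    fills the whole body (R_p -> R_c), where the model loses validity.
    """
    if geom.sample_radius is None:
        return geom.beta1 / 3.0
    ratio = geom.pipette_radius / geom.sample_radius
    if ratio >= 1.0:
        raise ValueError("R_p >= R_c: aspiration model invalid")
    return geom.beta1 * (1.0 - ratio ** geom.beta3) / 3.0


@dataclass(frozen=True)
class QuasiStaticResult:
    """Elastic modulus fitted from an aspiration ramp."""

    E: float            # Pa
    slope: float        # m/Pa, d(L_p)/dP
    intercept: float    # m
    fit_r2: float
    segment: tuple[float, float]
    n_points: int


def fit_elastic_modulus(time: np.ndarray, pressure: np.ndarray,
                        aspirated_length: np.ndarray, geom: GeometryParams,
                        segment: tuple[float, float] | None = None,
                        ) -> QuasiStaticResult:
    """Fit E from the loading portion of a pressure-aspiration record.

    Ordinary least squares of ``L_p`` on ``P`` with an intercept (which
    absorbs any capture offset), restricted to ``segment = (t0, t1)``;
    then ``E = R_p / (G* slope)``.
    """
    time = np.asarray(time, float)
    pressure = np.asarray(pressure, float)
    lp = np.asarray(aspirated_length, float)
    if segment is not None:
        mask = (time >= segment[0]) & (time <= segment[1])
    else:
        mask = np.ones_like(time, dtype=bool)
        segment = (float(time[0]), float(time[-1]))
    p, y = pressure[mask], lp[mask]
    if p.size < 10:
        raise ValueError(f"segment holds only {p.size} samples (need >= 10)")
    if np.ptp(p) == 0:
        raise ValueError("pressure is constant over the segment")

    slope, intercept = np.polyfit(p, y, 1)
    if slope <= 0 or not np.any(y != 0):
        raise ValueError("non-positive aspiration slope: no valid elastic fit")
    resid = y - (slope * p + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")

    gstar = geometry_factor(geom)
    E = geom.pipette_radius / (gstar * slope)
    return QuasiStaticResult(E=float(E), slope=float(slope),
                             intercept=float(intercept), fit_r2=r2,
                             segment=(float(segment[0]), float(segment[1])),
                             n_points=int(p.size))


def radial_strain(dR: float, R0: float) -> float:
    """Nominal radial strain dR/R0 of a deformed layer of thickness R0."""
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    return dR / R0


def hydrostatic_pressure(height: float, rho: float = 998.2,
                         g: float = 9.80665) -> float:
    """Hydrostatic pressure rho*g*h (Pa) of a water column of height h (m).

    Used to bound the pressure uncertainty introduced by the reservoir
    positioning accuracy (~50 um of water column is below 0.5 Pa).
    """
    return rho * g * height
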