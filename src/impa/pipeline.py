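"""End-to-end orchestration: simulate -> demodulate -> filter -> analyse.

Presets bundle a sample model, a pressure protocol, and the matching
analysis for the instrument's validation experiments:

``alginate-trapezoid``
    elastic alginate microbead (E = 50 kPa, R_c = 150 um) under the
    trapezoidal quasi-static protocol; elastic-modulus fit on the ramp.
``fishroe-triangle``
    elastic flying-fish roe (E = 360 kPa, R_c = 750 um) under the
    triangular hysteresis protocol; fit on the first loading ramp.
``zp-dma``
    zona pellucida with a fixed complex modulus per test frequency
    (E' = 39, E'' = 6 kPa at 0.05 Hz; E' = 62, E'' = 14 kPa at 1 Hz),
    half-space geometry, oscillatory protocol; per-frequency DMA.
``oocyte-capture``
    zona pellucida modelled by the two-term power law under the gentle
    capture protocol; demodulated traces only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import protocols
from .demodulation import demodulate_stack
from .dma import analyze_dma, power_law_fit
from .preprocess import FilterSpec, lowpass
from .quasistatic import GeometryParams, fit_elastic_modulus
from .spectral_forward import (AcquisitionConfig, ProbeConfig, SampleModel,
                               simulate_experiment)

__all__ = ["RunConfig", "PRESETS", "build_preset", "run_pipeline"]

#: half-width (m) of the OPL search window around each expected peak
WINDOW_HALFWIDTH = 50e-6


@dataclass(frozen=True)
class RunConfig:
    """Flat, JSON-serialisable configuration of one pipeline run."""

    preset: str
    seed: int = 0
    sampling_rate: float = 1000.0
    noise_sd: float = 0.01
    filter_order: int = 3
    filter_cutoff_hz: float = 25.0
    probe_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        return cls(**payload)


def _zp_table() -> dict[float, tuple[float, float]]:
    return {0.05: (39e3, 6e3), 1.0: (62e3, 14e3)}


def build_preset(name: str, probe_overrides: dict | None = None):
    """Resolve a preset name into (probe, sample, protocol, analysis kind)."""
    over = dict(probe_overrides or {})
    if name == "alginate-trapezoid":
        probe = ProbeConfig(**{"pipette_radius": 45e-6, **over})
        sample = SampleModel.elastic(50e3, sample_radius=150e-6)
        protocol = protocols.trapezoid_protocol()
        return probe, sample, protocol, "quasistatic"
    if name == "fishroe-triangle":
        probe = ProbeConfig(**{"pipette_radius": 45e-6, **over})
        sample = SampleModel.elastic(360e3, sample_radius=750e-6)
        protocol = protocols.triangle_protocol()
        return probe, sample, protocol, "quasistatic"
    if name == "zp-dma":
        probe = ProbeConfig(**{"pipette_radius": 20e-6, **over})
        sample = SampleModel.fixed_complex(_zp_table())  # half-space
        protocol = protocols.oocyte_protocol(frequencies=(0.05, 1.0))
        return probe, sample, protocol, "dma"
    if name == "oocyte-capture":
        probe = ProbeConfig(**{"pipette_radius": 20e-6, **over})
        sample = SampleModel.power_law(40.50e3, 0.0908, 4.32e3)
        protocol = protocols.PressureProtocol(
            [protocols.Ramp(50.0, 50.0), protocols.Hold(2.0),
             protocols.Ramp(50.0, 100.0), protocols.Hold(4.0)])
        return probe, sample, protocol, "traces"
    raise ValueError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")


PRESETS = ("alginate-trapezoid", "fishroe-triangle", "zp-dma", "oocyte-capture")


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute one full run and return a result bundle.

    The bundle always holds the demodulated and filtered traces plus the
    ground truth; quasi-static presets add an elastic-modulus fit, DMA
    presets a per-frequency modulus table (and a power-law fit when three
    or more frequencies are present).  Deterministic for a fixed config.
    """
    probe, sample, protocol, analysis = build_preset(config.preset,
                                                     config.probe_overrides)
    acq = AcquisitionConfig(sampling_rate=config.sampling_rate,
                            intensity_noise_sd=config.noise_sd,
                            seed=config.seed)
    stack, truth = simulate_experiment(probe, sample, protocol, acq)

    opl_s, opl_p = probe.sample_opl(), probe.pressure_opl()
    demod = demodulate_stack(
        stack,
        sample_window=(opl_s - WINDOW_HALFWIDTH, opl_s + WINDOW_HALFWIDTH),
        pressure_window=(opl_p - WINDOW_HALFWIDTH, opl_p + WINDOW_HALFWIDTH),
        n_medium=probe.medium_ri, sensitivity=probe.mems_sensitivity)

    fspec = FilterSpec(order=config.filter_order,
                       cutoff_hz=config.filter_cutoff_hz)
    pressure = lowpass(demod.pressure, config.sampling_rate, fspec)
    displacement = lowpass(demod.displacement, config.sampling_rate, fspec)

    bundle: dict = {
        "config": config.to_dict(),
        "protocol": protocol.to_descriptor(),
        "truth": truth,
        "demodulation": demod,
        "time": demod.time,
        "pressure": pressure,
        "displacement": displacement,
    }

    geom = GeometryParams(pipette_radius=probe.pipette_radius,
                          sample_radius=sample.sample_radius)
    if analysis == "quasistatic":
        ramp = next(s for s in protocol.segment_spans() if s.kind == "ramp")
        bundle["quasistatic"] = fit_elastic_modulus(
            demod.time, pressure, displacement, geom,
            segment=(ramp.t_start, ramp.t_end))
    elif analysis == "dma":
        table = analyze_dma(demod.time, pressure, displacement,
                            protocol.segment_spans(), geom)
        bundle["dma"] = table
        if len(table) >= 3:
            bundle["power_law"] = power_law_fit(
                [r.frequency for r in table], [r.e_prime for r in table],
                [r.e_doubleprime for r in table])

    if out_dir is not None:
        _write_bundle(Path(out_dir), bundle, demod)
    return bundle


def _write_bundle(out_dir: Path, bundle: dict, demod) -> None:
    from .io import write_json, write_timeseries
    out_dir.mkdir(parents=True, exist_ok=True)
    write_timeseries(out_dir / "traces.csv", bundle["time"],
                     {"pressure_Pa": bundle["pressure"],
                      "Lp_m": bundle["displacement"]})
    results: dict = {"config": bundle["config"],
                     "protocol": bundle["protocol"],
                     "demodulation": demod.metadata()}
    if "quasistatic" in bundle:
        qs = bundle["quasistatic"]
        results["quasistatic"] = {"E_Pa": qs.E, "slope_m_per_Pa": qs.slope,
                                  "r2": qs.fit_r2, "segment_s": qs.segment}
    if "dma" in bundle:
        results["dma"] = [r.to_dict() for r in bundle["dma"]]
    if "power_law" in bundle:
        results["power_law"] = bundle["power_law"].to_dict()
    write_json(out_dir / "results.json", results)


def seeds_from(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) >> 1 for s in ss.generate_state(n, dtype=np.uint32)]
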