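"""Forward model: wavenumber grid, frame rendering, sample mechanics."""

import math

import numpy as np
import pytest

from impa import protocols
from impa.demodulation import cavity_space, select_peak
from impa.dma import power_law_eval
from impa.spectral_forward import (AcquisitionConfig, OpticalCavity,
                                   ProbeConfig, SampleModel, SpectrometerSpec,
                                   sample_response, simulate_experiment,
                                   simulate_frame, source_envelope,
                                   wavenumber_grid)

TWO_PI = 2.0 * math.pi


class TestWavenumberGrid:
    def test_pixel_count_and_uniformity(self, spec):
        k = wavenumber_grid(spec)
        assert len(k) == 512
        steps = np.diff(k)
        assert np.all(steps > 0)
        assert np.allclose(steps, steps[0], rtol=1e-12)

    def test_span_matches_wavelength_range(self, spec):
        k = wavenumber_grid(spec)
        expected = TWO_PI * (1 / 1510e-9 - 1 / 1595e-9)
        assert k[-1] - k[0] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValueError):
            SpectrometerSpec(lambda_min_nm=1550, lambda_max_nm=1550)


class TestSimulateFrame:
    def test_zero_visibility_gives_pure_envelope(self, spec):
        cav = OpticalCavity("a", 300e-6, 1.331, visibility=0.0)
        frame = simulate_frame([cav], spec)
        assert np.allclose(frame, source_envelope(spec), atol=1e-15)

    def test_noise_free_frame_nonnegative(self, spec):
        frame = simulate_frame([OpticalCavity("a", 300e-6, 1.331, 0.5)], spec)
        assert np.all(np.isfinite(frame)) and np.all(frame >= 0)

    def test_deterministic_for_fixed_seed(self, spec):
        cavs = [OpticalCavity("a", 300e-6, 1.331, 0.3)]
        f1 = simulate_frame(cavs, spec, noise_sd=0.01,
                            rng=np.random.default_rng(7))
        f2 = simulate_frame(cavs, spec, noise_sd=0.01,
                            rng=np.random.default_rng(7))
        assert np.array_equal(f1, f2)

    def test_visibility_sum_warning(self, spec):
        cavs = [OpticalCavity("a", 300e-6, 1.0, 0.6),
                OpticalCavity("b", 500e-6, 1.0, 0.6)]
        with pytest.warns(UserWarning, match="unphysical"):
            simulate_frame(cavs, spec)

    @pytest.mark.parametrize("d,n", [(300e-6, 1.331), (800e-6, 1.0)])
    def test_fft_peak_at_cavity_opl(self, spec, d, n):
        frame = simulate_frame([OpticalCavity("a", d, n, 0.4)], spec)
        space = cavity_space(frame, spec)
        peak = int(np.argmax(space.magnitude[6:])) + 6
        bin_width = space.opl[1] - space.opl[0]
        assert abs(space.opl[peak] - n * d) <= bin_width

    def test_two_cavities_give_two_separable_peaks(self, spec):
        frame = simulate_frame([OpticalCavity("a", 300e-6, 1.0, 0.3),
                                OpticalCavity("b", 700e-6, 1.0, 0.3)], spec)
        space = cavity_space(frame, spec)
        b1 = select_peak(space, (250e-6, 350e-6))
        b2 = select_peak(space, (650e-6, 750e-6))
        assert b1 != b2
        bin_width = space.opl[1] - space.opl[0]
        assert abs(space.opl[b1] - 300e-6) <= bin_width
        assert abs(space.opl[b2] - 700e-6) <= bin_width

    def test_empty_cavity_list_rejected(self, spec):
        with pytest.raises(ValueError):
            simulate_frame([], spec)


class TestSampleResponse:
    def test_elastic_aspiration_depth(self):
        # E = 50 kPa, Rp = 45 um, Rc = 150 um, dP = 1 kPa -> ~1.45 um
        model = SampleModel.elastic(50e3, sample_radius=150e-6)
        prot = protocols.PressureProtocol([protocols.Ramp(100.0, 1000.0)])
        lp = sample_response(model, prot, 45e-6, np.array([10.0]))
        expected = 3 * 45e-6 * 1000 / (50e3 * 2.0142 * (1 - 0.3 ** 2.1187))
        assert lp[0] == pytest.approx(expected, rel=1e-12)
        assert lp[0] == pytest.approx(1.454e-6, rel=1e-3)

    def test_elastic_response_proportional_to_pressure(self):
        model = SampleModel.elastic(80e3, sample_radius=200e-6)
        prot = protocols.trapezoid_protocol()
        t = np.linspace(0, prot.duration, 500)
        lp = sample_response(model, prot, 45e-6, t)
        p = prot.pressure(t)
        nz = p != 0
        ratio = lp[nz] / p[nz]
        assert np.allclose(ratio, ratio[0], rtol=1e-12)

    def test_purely_elastic_complex_table_is_in_phase(self):
        model = SampleModel.fixed_complex({0.5: (40e3, 0.0)})
        prot = protocols.PressureProtocol(
            [protocols.Sine(60.0, 0.5, n_periods=4)])
        t = np.arange(0, prot.duration, 1e-3)
        lp = sample_response(model, prot, 45e-6, t, sample_radius=None)
        p = prot.pressure(t)
        # in-phase: L_p proportional to P throughout the oscillation
        assert np.corrcoef(lp, p)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_power_law_segment_matches_constitutive_model(self):
        model = SampleModel.power_law(40.50e3, 0.0908, 4.32e3)
        rp = 20e-6
        gstar = 2.0142 / 3.0
        for f in protocols.DMA_FREQUENCIES:
            prot = protocols.PressureProtocol(
                [protocols.Sine(60.0, f, n_periods=5)])
            t = np.arange(0, prot.duration, 1e-3)
            lp = sample_response(model, prot, rp, t)
            estar = power_law_eval(f, 40.50e3, 0.0908, 4.32e3)
            expected = rp * 60.0 / (gstar * abs(estar)) * np.sin(
                TWO_PI * f * t - math.atan2(estar.imag, estar.real))
            assert np.allclose(lp, expected, atol=1e-15)

    def test_undefined_frequency_rejected_for_fixed_complex(self):
        model = SampleModel.fixed_complex({0.05: (39e3, 6e3)})
        with pytest.raises(KeyError):
            model.complex_modulus(0.75)


class TestSimulateExperiment:
    def test_zero_amplitude_protocol_frames_identical(self, probe, spec):
        sample = SampleModel.elastic(50e3, sample_radius=150e-6)
        prot = protocols.PressureProtocol([protocols.Hold(0.05)])
        acq = AcquisitionConfig(intensity_noise_sd=0.0, seed=0)
        stack, _ = simulate_experiment(probe, sample, prot, acq, spec)
        assert np.array_equal(stack.frames, np.broadcast_to(
            stack.frames[0], stack.frames.shape))

    def test_suction_sign_convention(self, probe, spec):
        # suction shortens the sample cavity and lengthens the MEMS cavity
        sample = SampleModel.elastic(50e3, sample_radius=150e-6)
        prot = protocols.PressureProtocol([protocols.Ramp(100.0, 500.0)])
        acq = AcquisitionConfig(intensity_noise_sd=0.0, seed=0)
        _, truth = simulate_experiment(probe, sample, prot, acq, spec)
        assert np.all(np.diff(truth.sample_cavity_length) < 0)
        assert np.all(np.diff(truth.mems_cavity_length) > 0)
        assert np.all(np.diff(truth.aspirated_length) > 0)

    def test_mems_travel_tracks_sensitivity(self, probe, spec):
        # a pressure step of exactly S Pa moves the membrane by 1 nm
        sample = SampleModel.elastic(50e3, sample_radius=150e-6)
        prot = protocols.PressureProtocol(
            [protocols.Ramp(1000.0, probe.mems_sensitivity),
             protocols.Hold(0.05)])
        acq = AcquisitionConfig(intensity_noise_sd=0.0, seed=0)
        _, truth = simulate_experiment(probe, sample, prot, acq, spec)
        travel = truth.mems_cavity_length[-1] - truth.mems_cavity_length[0]
        assert travel == pytest.approx(1e-9, rel=1e-6)

    def test_seed_reproducibility(self, probe, spec):
        sample = SampleModel.elastic(50e3, sample_radius=150e-6)
        prot = protocols.PressureProtocol([protocols.Ramp(100.0, 200.0)])
        acq = AcquisitionConfig(intensity_noise_sd=0.01, seed=42)
        s1, _ = simulate_experiment(probe, sample, prot, acq, spec)
        s2, _ = simulate_experiment(probe, sample, prot, acq, spec)
        assert np.array_equal(s1.frames, s2.frames)

    def test_nyquist_violation_rejected(self, probe, spec):
        sample = SampleModel.fixed_complex({600.0: (40e3, 1e3)})
        prot = protocols.PressureProtocol(
            [protocols.Sine(10.0, 600.0, n_periods=1200)])
        acq = AcquisitionConfig(sampling_rate=1000.0, seed=0)
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_experiment(probe, sample, prot, acq, spec)

    def test_inseparable_cavities_rejected(self, spec):
        probe = ProbeConfig(sample_cavity_rest_length=300e-6, medium_ri=1.0,
                            pressure_cavity_rest_length=301e-6)
        sample = SampleModel.elastic(50e3, sample_radius=150e-6)
        prot = protocols.PressureProtocol([protocols.Hold(0.01)])
        with pytest.raises(ValueError, match="separable"):
            simulate_experiment(probe, sample, prot, acq=AcquisitionConfig(),
                                spec=spec)


class TestProtocols:
    def test_trapezoid_shape(self):
        prot = protocols.trapezoid_protocol()
        assert prot.duration == pytest.approx(30.0)
        t = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
        p = prot.pressure(t)
        assert np.allclose(p, [0, 500, 1000, 1000, 1000, 500, 0])

    def test_triangle_returns_to_zero_each_cycle(self):
        prot = protocols.triangle_protocol()
        assert prot.duration == pytest.approx(100.0)
        p = prot.pressure(np.array([10.0, 20.0, 30.0, 40.0]))
        assert np.allclose(p, [1500, 0, 1500, 0])

    def test_dma_segments_expose_frequencies(self):
        prot = protocols.dma_protocol()
        sines = [s for s in prot.segment_spans() if s.kind == "sine"]
        assert [s.frequency for s in sines] == list(protocols.DMA_FREQUENCIES)
        for s in sines:
            assert (s.t_end - s.t_start) * s.frequency == pytest.approx(5.0)
            assert s.base_pressure == pytest.approx(1500.0)

    def test_pressure_is_continuous(self):
        prot = protocols.dma_protocol(frequencies=(0.35, 1.0))
        t = np.arange(0, prot.duration, 1e-3)
        p = prot.pressure(t)
        assert np.max(np.abs(np.diff(p))) < 1.0  # Pa per ms
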