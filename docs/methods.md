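# Methods

## The measurement principle

Micropipette aspiration (MPA) draws a soft body into a glass capillary of
internal radius `R_p` with a controlled suction `ΔP` and infers mechanics
from the aspirated length `L_p`. `impa` models an MPA instrument whose
readout is interferometric rather than camera-based: a broadband source
(superluminescent diode, 1550 nm centre, 50 nm FWHM) illuminates two
low-finesse extrinsic Fabry–Pérot cavities through optical fibre —

* the **sample cavity**, fibre end-facet to the aspirated surface, filled
  with the working medium (water, n = 1.331); suction shortens it by
  `L_p(t)`;
* the **pressure cavity**, fibre to the membrane of a sealed MEMS pressure
  sensor (air, n = 1); the membrane travels `P/S` with sensitivity
  `S = 76.59 Pa/nm`.

Both cavities share one source and one spectrometer (1510–1595 nm, 166 pm
pixels, even in wavenumber k), so excitation and response are encoded in
the same interferogram and are intrinsically synchronous.

## Forward model

Each cavity is treated in the two-beam approximation appropriate for low
finesse: one cosine per cavity,

    I(k) = E0(k) · [1 + Σᵢ Vᵢ cos(2 k nᵢ dᵢ + φᵢ)] + ε,

with `E0` a Gaussian envelope (the conventional model for an SLD
spectrum), `Vᵢ` the fringe
visibility, and `ε` additive white Gaussian intensity noise per pixel.
Phase origins `φᵢ` are drawn once per experiment from the seed; only phase
*variation* carries signal. Static parasitic cavities may be added to
emulate the extra reflections of a real probe. Everything is reproducible
bit-for-bit from the acquisition seed.

Defaults and their rationale:

| parameter | default | why |
|---|---|---|
| sample cavity rest length | 500 µm | mid-range of the 300–1600 µm probes discussed |
| pressure cavity rest length | 300 µm | free design parameter; short cavities sit near their mirror image in cavity space and the leakage biases the phase slope (~1e-4 at 150 µm, <1e-5 at 300 µm) |
| visibilities | 0.3 / 0.4 | low-contrast fringes typical of weakly reflecting wet samples |
| acquisition rate | 1 kHz | the instrument's interferogram rate |
| intensity noise sd | 0.01 of the envelope peak | puts the demodulated displacement noise floor at ~0.4 nm rms at 1 kHz, consistent with a sub-nanometre resolution claim |

## Sample mechanics

The constitutive link between pressure and aspirated length is the
linearized small-strain aspiration model for an incompressible sphere
(ν = 0.5 fixed),

    ΔP/E = β₁ [1 − (R_p/R_c)^β₃] / 3 · L_p/R_p,   β₁ = 2.0142, β₃ = 2.1187,

abbreviated `L_p = R_p ΔP / (G* E)` with geometry factor
`G* = β₁[1−(R_p/R_c)^β₃]/3` (half-space limit `β₁/3` as `R_p/R_c → 0`).
Three sample variants are simulated:

* **elastic** — `L_p ∝ P` exactly at all times;
* **fixed_complex** — a table of (E′, E″) per drive frequency; sinusoidal
  segments respond at steady state with amplitude `R_p P₀/(G*|E*|)` and
  phase lag `δ = arg E*`;
* **power_law** — `E*(ω) = A(iω)^α + B(iω)^{3/4}`.

Ramp and hold segments of viscoelastic samples use the quasi-static
magnitude `|E*|` at the lowest defined frequency: **creep transients are
not simulated** (no constitutive creep law is published for these
specimens), which is the main respect in which the synthetic data are
cleaner than real records — passing recovery tests demonstrates the
correctness of the analysis chain, not robustness to creep, seal leakage,
or drift of a real experiment.

## Demodulation

Frames are mean-subtracted, Hann-windowed, and FFT'd over the uniform k
grid; bin `m` maps to OPL `π m/(N Δk)` (bin width ≈ 14.2 µm at the
defaults). The working cavity is located as the prominent magnitude peak
inside a user-supplied OPL window (background estimated outside the main
lobe; a DC guard of 6 bins excludes the envelope). Phase is read at that
fixed bin — not interpolated — because only variation matters; it is
unwrapped, zeroed at the first frame, and converted by

    δOPL(t) = φ(t) · λ̄ / 4π,   L_p = −δOPL/n_medium,   P = S · δOPL[nm].

`λ̄` defaults to the *effective* mean wavelength: the centroid of the
wavenumber grid weighted by window × estimated source envelope
(≈ 1550.7 nm here). This is the value for which the fixed-bin phase slope
per unit motion is exact to first order; using the nominal 1550 nm instead
leaves a ~0.09 % scale error, i.e. nanometres over micron-scale
aspiration. With the effective wavelength the noise-free round trip
recovers ground truth to < 0.001 nm rms.

Limits: the fringe aliases at OPL = λ̄²/(4·pitch) ≈ 3.62 mm (≈ 2.7 mm of
geometric length in water); windows beyond the bound are rejected. An
inter-frame phase step within 5 % of ±π flags the trace as aliased —
faster motion wraps to an arbitrary step and is undetectable in
principle, so the flag is a guard band, not a guarantee.

## Filtering

Demodulated traces are low-pass filtered with a third-order Butterworth
(maximally flat passband), applied forward-backward by default so that
DMA phase lags are untouched (< 1e−3 rad at any common frequency). The
25 Hz default cutoff can be recomputed from data as the lowest frequency
where the max-normalized Welch PSD stays below −40 dB for a configurable
band (5 Hz default); a flat spectrum returns the default. The reference
level for the −40 dB criterion is the PSD maximum, a scale-invariant
choice.

## Quasi-static and dynamic analysis

The elastic fit is ordinary least squares of `L_p` on `P` with an
intercept (absorbing any capture offset) over an explicitly chosen ramp
segment — presets locate the ramp from the protocol definition;
`E = R_p/(G*·slope)`. On noise-free forward data the inversion is exact
to machine precision.

DMA fits each oscillation burst independently on the basis
{sin ωt, cos ωt, 1, t}; the {1, t} terms implement the linear drift
correction and are orthogonal to the sinusoid over the burst's integer
number of periods. The phase lag `δ = δ_P − δ_L` is wrapped into (−π, π],
clamped to 0 when within 0.01 rad below zero, and rejected outside
[0, π/2]. Then

    |E*| = R_p/G* · P₀/L₀,   E′ = |E*| cos δ,   E″ = |E*| sin δ.

The two-term power law is fitted to the per-frequency (E′, E″) by bounded
nonlinear least squares on stacked real/imaginary residuals
(A, B ≥ 0, α ∈ [0, 1]), multi-started over α ∈ {0.05, 0.1, 0.2, 0.5} with
A seeded at the median E′ and B from the top-frequency residual. Whether
ω enters in rad/s or Hz is genuinely ambiguous in the field's usage; both
conventions are supported behind an explicit flag (default rad/s) that is
recorded in every result.

## Validation experiments and problem sizes

The package's acceptance suite reproduces the instrument's validation as
parameter-recovery studies: alginate beads (E = 50 kPa, R_p = 45 µm,
R_c = 150 µm, trapezoid 100 Pa/s → 1 kPa → 10 s hold), flying fish roe
(E = 360 kPa, triangle 1500 Pa at 150 Pa/s ×5), and zona pellucida DMA
(half-space, R_p = 20 µm, ground truth E′/E″ = 39/6 kPa at 0.05 Hz and
62/14 kPa at 1 Hz, 40 Pa amplitude — the middle of the instrument's
30–50 Pa oocyte range). Each uses 10 seeded end-to-end runs at the full
1 kHz acquisition rate; the DMA study simulates the two frequencies with
tabulated ground truth. The cavity-reach study sweeps geometric lengths
0.2–2.5 mm (water) with a 100 nm ramp over 100 frames. These sizes were
chosen to mirror the instrument's stated protocols while each study
completes in seconds to a couple of minutes.

## Known limitations

* No creep/viscoelastic transients on ramps; oscillations are pure steady
  state (no start-up transient).
* Two-beam cavities only: multiple reflections, inter-reflector cross
  terms, and contrast loss with cavity length are not modelled, so the
  long-cavity sweep probes demodulation accuracy, not SNR.
* Parasitic cavity visibilities are static during aspiration.
* Absolute cavity length / sample refractive-index estimation is out of
  scope; only differential phase is used.
* The noise model is white in intensity; real detectors add shot noise,
  fixed-pattern structure and source power drift.
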