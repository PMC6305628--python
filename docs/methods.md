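# Methods

This note documents the models behind `hifupwm`, the defaults and why
they were chosen, the numerical choices, and what the synthetic test
conditions do and do not demonstrate about hardware and tissue.

## Excitation design

HRPWM is realized as direct selective-harmonic-elimination on a
quarter-wave-symmetric five-level staircase, rather than as a
carrier-based modulator: the two formulations satisfy the same contract
(amplitude control through a modulation index, active nulling of selected
harmonics, one or two pulses per half cycle) and the switching-angle form
is self-contained and testable against closed forms. The modulation
index is normalized so that m = 1 is the fundamental of the full
un-nulled staircase (all angles at zero); the "70 % duty" operating
point of the hardware is mapped to m = 0.70 by default and is
configurable, since carrier-based duty and modulation index coincide
only approximately.

The angle system is solved by damped Newton iteration with eight
deterministic evenly spaced multi-starts, tolerance 1e-9, 100-iteration
cap. With H3 nulled and one pulse per half cycle the feasible band is
m ∈ [√3/4, √3/2] with two closed-form branches (α₂ = π/3 ± α₁); below
the band the solver escalates to four angles with alternating step signs
(two pulses per half cycle, peaking at level 1) and closes the
underdetermined system by additionally nulling H5 and H7. Above the band
no five-level H3-nulled solution exists and the error names the feasible
band. A repeated angle (e.g. (30°, 30°) at m = √3/2) is a valid
degenerate double step.

Switching instants are quantized to the nearest output sample with exact
midpoints resolved to the earlier sample. This keeps synthesis
deterministic but leaves a quantization residual at the nulled
harmonics: measured worst cases over the feasible band are −23.7 dB at
64 samples/cycle and −34.8 dB at 256 samples/cycle (worst near the band
edges where d cos 3α/dα is maximal), against an exactly nulled
continuous design. The sampled fundamental is within 2 % of the design
at 256 samples/cycle (worst case ~1.5 %) but can deviate by up to ~5 %
at the 64-sample floor; consumers needing tight amplitude fidelity
should sample at ≥ 256 samples/cycle, which the pipeline does.

## Gate compilation

The six-gate bridge schedule treats the ground clamp as the resting
state. At every transition between distinct conducting paths a dead gap
of at least one sample (default 100 ns, a typical MOSFET-driver scale;
not a measured hardware value) is carved from the clamp side when one
exists — clamp released early, engaged late — and from the outgoing run
otherwise, so the output floats only during dead time. The four
level-shifted rail gates carry a 1 ms on-time limit (capacitive level
shifters droop); the clamp pair is exempt. Whether real hardware
interleaves the clamp at every transition is unknown; this is a stated
compiler convention, not a claim about a fabricated board.

## Electrical power

P(f) = Re(V(f) I(f)*) with a one-sided density that carries the factor
2/Δf at every bin, including DC and Nyquist; this makes the trapezoidal
full-band integral telescope exactly to the two-sided Parseval sum, i.e.
to mean(v·i), for even-length records. Records are not windowed — the
intended captures are synchronous multi-cycle bursts (the bench used
100-cycle excitations) — so band-edge leakage on asynchronous records is
the caller's risk. The default integration band is 500 kHz–10 MHz.

## Acoustic field

The transducer is a 64 mm aperture / 63 mm focal-length spherical cap at
1.1 MHz. Its electromechanical response is a 50-order FIR low-pass
(Kaiser design, cutoff midway between 3f₀ and 4f₀) for which only the
magnitude contract is normative: passband flat over f₀..3f₀ (measured
ripple < 0.05 dB), stopband ≥ 40 dB at 4f₀ and above (measured ≥ 62 dB).

Propagation is a **linear per-harmonic surrogate**: for each populated
harmonic the lossless axisymmetric Rayleigh integral of the uniformly
vibrating cap is evaluated through its exact spherical-harmonic
expansion about the centre of curvature (coefficients from closed-form
Legendre cap integrals; spherical Bessel functions by Miller downward
recurrence). The series is the same bowl radiation pattern direct
surface quadrature produces (agreement ~1e-6 in cross-checks, and
~1e-13 against the on-axis closed form); its truncation error
concentrates on the source sphere itself, i.e. the cells nearest the
transducer face, which play no role in focal dosimetry. Attenuation is
applied as a separable axial factor exp(−∫α(f, z′)dz′) with power-law
α = α₀(f/MHz)^b per layer; obliquity of the converging rays and
refraction at layer boundaries are ignored (sound-speed contrast is ~4 %
and one sound speed — the first layer's — sets the wavenumber).

Defaults for the layer stack are literature chicken-muscle stand-ins
(water: c = 1482 m/s, ρ = 1000 kg/m³, lossless; tissue: c = 1547 m/s,
ρ = 1060 kg/m³, α₀ = 0.52 dB/(cm·MHz^1.1), b = 1.1, 45 mm thick), all
overridable through the config. The tissue front face sits at 43 mm so
the focus lies 20 mm deep in tissue, matching the fixed lesioning depth
used on the bench. Power calibration equates the plane-wave surface
power Σ pₕ²/(2ρc) × cap area to the 26 W target after the transfer
function; harmonic ratios are preserved exactly.

Beamwidth convention: the −6 dB *pressure* width of this geometry is
~1.87 mm (jinc closed form; a membrane-hydrophone measurement of this
transducer type reads 1.85 mm), while the full width at half-maximum
*intensity* is ~1.37 mm and corresponds to the 1.33 mm datasheet figure.
`focal_beamwidth` exposes both conventions explicitly.

## Heating, dose and lesions

Q = Σₕ αₕ pₕ²/(ρc) over harmonics 1–6, with absorption taken equal to
the power-law attenuation (no absorption/scattering split — the stack
does not distinguish them). Pennes' equation is solved with an explicit
finite-difference scheme on the axisymmetric grid: the radial operator
is flux-conservative (with the axis cell treated as a disc of radius
Δr/2 the discrete enthalpy balance is exact to roundoff under insulated
boundaries, which the tests verify at 1e-9), the axis uses the symmetric
4(T₁−T₀)/Δr² Laplacian, and the stability bound 1/(κ(4/Δr² + 2/Δz²))
(plus the perfusion rate when nonzero) is checked, with the maximum
stable step named in the error. Perfusion defaults to zero for
ex-vivo-like comparisons; a nonzero rate enables the standard sink term
with blood at 37 °C. Exposures default to 20 s on + 10 s cooling from a
uniform 37 °C start (the simulated ambient, though benches typically run
cooler). Tissue thermal properties (C_p = 3421 J/kg·K, k_t = 0.49
W/m·K) apply over the whole grid; heating is nonzero only inside
absorbing layers, and the error from using tissue conductivity in the
water region is immaterial next to the surrogate's other
approximations.

CEM43 uses the Sapareto–Dewey rates (R = 0.5 at or above 43 °C, 0.25
below), integrated with the trapezoidal rule over the stored frames, and
the lesion is CEM43 ≥ 240 min, the standard coagulative-necrosis
threshold. Lesion cross-section area mirrors the half-plane mask about
the axis (2 Δr Δz per off-axis cell, Δr Δz on axis).

## Scheme comparison and problem sizes

The comparison pipeline synthesizes each scheme at 256 samples/cycle,
calibrates all of them to the same 26 W surface acoustic power, reuses
the cached per-harmonic unit fields across schemes, and runs the thermal
solve per scheme. The production grid is 112 µm over 64 mm × 78 mm; the
default comparison grid is a coarsened 0.5 mm version of the same
domain (marked `scaled_down` in reports) which resolves the fundamental
beam with ~4 cells across its half-width and runs the full three-scheme
comparison in seconds. Unit tests use a 1 mm variant of the same
pipeline.

**Known limitation — and an important one.** The linear surrogate makes
harmonics exist only where the drive puts them; nonlinear harmonic
generation during propagation is deliberately out of scope. This has a
qualitative consequence for the scheme comparison: a harmonic arriving
at the focus is absorbed *more* strongly (α ∝ f^1.1) and focuses *more*
sharply (gain ∝ f) than the fundamental, so with only ~20 mm of
prefocal tissue the bi-level drive's 3rd harmonic adds focal heating
faster than its 10 % fundamental deficit removes it. The model therefore
predicts a slightly *larger* bi-level lesion (+10 % at the default
operating point, with a markedly hotter focal peak) and an HRPWM lesion
identical to the sine reference (their calibrated spectra agree to
~−55 dB). Full nonlinear simulations and bench measurements show the
opposite sign for bi-level (lesion shrinkage), driven by prefocal energy
transfer into rapidly absorbed higher harmonics — a mechanism this
package does not model. Treat the comparison pipeline as a tool for
exploring *linear* redistribution of drive energy, not as a predictor of
nonlinear lesion shrinkage.

The synthetic fixtures (lumped R-L + shunt-C load, Gaussian-noise PCD
traces with injected tone/broadband bursts) exercise every analysis path
deterministically, but they idealize hardware: the load model has no
frequency-dependent matching network, PCD bursts are stationary packets
rather than physical bubble emissions, and passing tests on them
demonstrates correctness of the signal processing, not fidelity to any
particular transducer or cavitation event.

## PCD analysis

Triggering follows segmented-oscilloscope semantics: |x| > 380 mV
(triggering on magnitude since broadband emissions are bipolar), 50 ms
hold-off, up to 256 segments of 250 µs. Counts above 10 classify an
exposure as mechanically rather than thermally formed. Emission spectra
are taken after a ≥ 60 dB linear-phase FIR high-pass (stopband to 5 MHz,
passband from 6 MHz) and reported in dB relative to the median in-band
noise magnitude. Line labelling checks candidates at nf₀ and
(2n+1)f₀/2 against a 6 dB prominence floor over the local median of a
5-bin power-smoothed spectrum and requires the candidate to be the local
maximum of its neighbourhood; with pure noise the false-label rate is
roughly one line in five traces, so line lists from near-threshold data
should be read alongside the raw spectrum.
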