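# Methods

`fusviz` implements and tests, at desk scale, a method for visualizing a
focused-ultrasound (FUS) beam from the ultrasonic backscatter of a short
focused visualization pulse, received by the same linear imaging array that
forms a coaligned B-mode image. This note records the model, the numerical
choices, and what the synthetic experiments do and do not establish.

## Signal model and forward simulator

The received channel signal is modeled as the excitation pulse convolved
with the two-way electromechanical response of the probe and the medium's
scattering function. The package collapses the excitation and the two-way
electromechanical response into a single band-limited wavelet (a tapered
tone burst), and replaces the diffraction spatial impulse responses of the
physical elements with point-element superposition: every element radiates
a spherical wavelet delayed by its transmit law, every scatterer re-radiates
it to every element. Optional per-path factors model 1/r spherical
spreading (default on) and a hard-baffle cosine directivity (default off).
The simulator is exactly linear in scatterer reflectivity, deterministic
under a fixed seed (additive sensor noise included), and evaluates the
double sum over transmit elements and scatterers exactly via a two-stage
factorization (transmit field at each scatterer, then receive scattering),
with linear interpolation for subsample delays in both stages.

Not modeled, by design: nonlinear propagation (the real therapy beam is
strongly nonlinear at treatment pressures), multiple scattering, phase
aberration, dispersive attenuation, elevation focusing, element sub-dicing,
and time-gain compensation.

## Default acquisition conditions

The defaults emulate a 128-element, 5 MHz linear probe (L9-4/38 class):
pitch 0.3048 mm (the probe's 38.7 mm aperture; the pitch itself is a
package choice, configurable), RF sampling at 20 MHz (four samples per
wavelength), c = 1540 m/s in phantom/tissue scenes and 1480 m/s in water
scenes. One excitation sequence contains:

1. a focused 25-cycle mock therapy burst (logged, never reconstructed),
2. a focused 2-cycle visualization burst with the same delay law,
3. seven steered plane waves at −18°…+18° in 6° steps for B-mode.

All transmit delay laws are normalized so the earliest element fires at
t = 0; the simulator and the beamformer share this time origin.

## Scenes

A scene is a cloud of point scatterers with uniform random positions and
zero-mean Gaussian reflectivities — a discrete realization of the
scattering function. The background density default is 15 scatterers per
−6 dB resolution cell (cell = n_cycles·λ/2 axially × λ·f# laterally),
enough for fully developed speckle. A circular region with echogenicity
offset g dB multiplies in-region reflectivities by 10^(g/20), so the local
backscattered intensity is offset by g dB; point/wire targets are single
scatterers 40 dB above the background scale. Regeneration from the same
(spec, seed) pair is bit-identical.

The default demo field (≈10 × 8–10 mm around a 30 mm focus, ≈10⁴–2·10⁴
scatterers) is a deliberate scale-down of a physical phantom: it keeps the
full 128-element, 8-transmit sequence while the whole pipeline runs in
seconds on one CPU. What the synthetic scenes do not reproduce from real
data: frequency-dependent attenuation, reverberation and bright specular
interfaces, probe lens effects, and electronic-noise spectra. Passing
tests therefore establish internal physical consistency of the method, not
calibrated agreement with any physical phantom.

## Beamforming

The focused visualization frame is beamformed with delay-and-sum (DAS) and
dynamic receive focusing on a grid with one lateral line per element and
axial step Δz = c/(2 fs). The receive delay law is

    τ(x, z) = τ_F(x_c) + (z + √(z² + (x − x_c)²)) / c,

where τ_F(x_c) is the transmit delay of the line's element. For a single
focused transmit this model is exact at the focus and approximate
elsewhere — acceptable because the goal is localizing the focal region.
The delay law is additionally shifted by the wavelet's own peak time so the
echo peak, not its onset, lands at the scatterer depth.

The dynamic receive subaperture has half-width z/(2 f#) (f# = 1 by
default), clipped at the array edges, apodized with a Hanning window
defined over the full nominal width (elements at the exact edge get zero
weight and are excluded from the channel count N). Plane-wave frames use
the standard transmit time (z cos θ + x sin θ)/c, shifted consistently with
the delay normalization, then are coherently compounded (pointwise sum in
the RF domain) and envelope-detected (analytic signal magnitude per line).

The coherence factor at each point is

    CF = |Σᵢ sᵢ|² / (N Σᵢ sᵢ²) ∈ [0, 1],

computed by default from the same Hanning-apodized delayed samples that
feed the DAS sum (the alternative — raw samples — is a switch; the
published description does not specify, and the apodized choice keeps the
CF consistent with the samples actually summed). CF = 0 is defined where
the subaperture carries no energy. The beamformer output is y_CF = CF · y.

## Intensity reconstruction and echogenicity normalization

The beam intensity is a sliding pulse-intensity integral along each line:
I(x, z) = Σ_{i<L} Δz |y_CF(x, z+i)|², with L the visualization pulse
length in samples (8 by default); the window is truncated by zero padding
at the deep edge, so the intensity peak sits ≈(L−1)/2 samples shallow of
the envelope peak — well inside the pulse's −6 dB length.

The coaligned B-mode's *linear* envelope is smoothed with a 5.5 × 7
wavelength (axial × lateral) moving-average kernel (converted to odd pixel
counts, nearest-odd rounding, reflective edges), giving B(x, z). The
normalization factor is λ = B_max / B, applied as I_norm = I · L · λ².
λ is held at 1 where B falls below the gate (−60 dB relative to B_max by
default): such pixels are treated as noise, and keeping λ = 1 preserves
the equation's form while the constant L cancels under max-normalization.
Normalization is applied to the integrated intensity rather than to y_CF;
the two routes are equivalent and the integral route is cheaper. With the
gate disabled, pixels where B is exactly zero also keep λ = 1 (no
backscatter at all cannot be equalized).

Display: intensities use 10·log10, envelopes 20·log10, always normalized to
the image maximum; the overlay renders beam pixels above a threshold
(−20 dB default) in a warm colormap with opacity ramping linearly to full
at 0 dB over the grayscale B-mode.

## Metrics

Theoretical focal dimensions under continuous-wave excitation:
R₋₃dB = 1.028 λ f# and DOF₋₃dB = 7.08 λ (f#)². The convention λ =
0.296 mm (5 MHz in water) with f# = 0.756 reproduces the conventionally
printed 0.23 mm and 1.20 mm. Measured widths are level crossings of a dB
profile nearest its peak, located by linear interpolation in dB; profiles
from speckle scenes are noisy and the measured widths are reported as
qualitative only (the method is a localization aid, not a beam
profilometer).

The reconstruction-fidelity protocol compares intensity images after
10·log10 conversion, max-normalization, clipping to [−60, 0] dB, and a
5.5 × 5 wavelength median filter; the mean squared pixel difference is
averaged over five homogeneous baseline reconstructions with distinct
speckle seeds. Because all synthetic images share one grid, no
registration step is needed. At the default desk scale, normalization cuts
the averaged MSE of a +15 dB contrast-target scene roughly in half,
approaching the pure speckle floor measured between the baselines
themselves — the same direction the full-scale phantom experiments show.

## Validated properties (what the tests compute)

- CF ∈ [0, 1], its boundary cases, and scale invariance; |y_CF| ≤ |y|
  pointwise on every session reconstruction.
- DAS equals an independently coded brute-force delay-and-sum to < 10⁻⁶
  relative error; simulated echo peaks match an independent time-of-flight
  oracle within one sample.
- A point scatterer at the transmit focus reconstructs its intensity
  maximum within one lateral line and one axial −6 dB pulse length.
- Echogenicity equalization: for one scatterer geometry with and without a
  +15 dB disk at the focus, normalized max-normalized reconstructions
  agree within 1 dB (mean) in the kernel-eroded disk interior, while the
  unnormalized pair differs by > 10 dB in the beam-path background. The
  disk sits at the focus (as in the targeting experiments): in weakly
  insonified regions the CF responds to the changed coherence and the
  pixel-level scaling argument breaks down, so placements off the beam
  axis do not show the clean 1 dB agreement.
- Sidelobe directions on a wire-in-water scene (gate disabled, worst
  case): CF weighting lowers the lateral peak sidelobe of DAS by tens of
  dB, and normalization raises the DAS sidelobe level by well over 5 dB
  (≈12 dB at this scale; ≈15 dB is reported at full scale) — the reason CF
  weighting is part of the method.
- Multiplying all RF data by a power of two leaves every max-normalized dB
  product bit-identical.

## Numerical and degenerate-input choices

- Subsample delays: linear interpolation everywhere; image grid points
  whose delays fall outside the record window are zero-filled with a
  warning.
- Kernel sizes in wavelengths round to the nearest odd pixel count ≥ 1
  per axis.
- Wavelet sampled at bin centers so tapers never produce exact zero
  endpoints; peak absolute amplitude is normalized to the requested
  amplitude.
- All-zero images are rejected by log compression, normalization and the
  MSE protocol rather than silently propagating −inf.
- Seeds are explicit everywhere; per-frame noise seeds are spawned from
  the acquisition seed.

## Known limitations

Point-element superposition overestimates edge-element contributions
(no element directivity by default); the single-transmit Eq.-3-style delay
law defocuses away from the transmit focus, so off-focus image regions are
qualitative; wire scenes need a small additive noise floor for ungated
normalization to be finite; and none of the quantitative MSE values are
comparable to full-scale phantom numbers — only their directions are.
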