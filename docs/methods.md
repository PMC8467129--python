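# Methods

This note records the models, parameter choices and numerical decisions
behind `sfdikit`, and what the simulator-backed tests do and do not
demonstrate.

## Diffuse reflectance model

The forward model is the steady-state diffusion approximation for a
homogeneous semi-infinite medium under spatially modulated planar
illumination. At spatial frequency fx (mm⁻¹),

    Rd(fx) = 3 A μs′/μtr / ((μ′eff/μtr + 1)(μ′eff/μtr + 3A)),

with μtr = μa + μs′, μeff = √(3 μa μtr), μ′eff = √(μeff² + (2π fx)²), and
A = (1 − Reff)/(2(1 + Reff)). Reff is the empirical polynomial
Reff = 0.0636 n + 0.668 + 0.71/n − 1.44/n², validated to lie in (0, 1);
coefficient/index combinations outside that range are rejected as
unphysical rather than propagated. The linear coefficient is configurable
(`MediumConstants.reff_linear_coeff`) but 0.0636 is the standard
diffusion-theory value and the default.

**Refractive index.** Aqueous phantoms and fruit flesh are both close to
water-rich soft tissue; n = 1.35 is used for both by default and is
configurable per run.

**Validity.** The diffusion approximation assumes μs′ ≫ μa and modest
spatial frequencies. Within the instrument band (fx ≤ 0.14 mm⁻¹) and for
μs′ ≥ 0.5 mm⁻¹, Rd is strictly decreasing in fx and μa and increasing in
μs′ — the property tests assert this on a dense grid. Outside the validity
regime (μa approaching μs′ at high fx) the μa-monotonicity genuinely fails;
this is a property of the model, not of the implementation, and the model
should not be trusted there.

## Demodulation convention

The three-phase amplitude is implemented exactly as
Mac = (2/3)√((I1−I2)² + (I2−I3)² + (I1−I3)²). For a sinusoid of amplitude
a this evaluates to √2·a (the conventional estimator uses √2/3 and returns
a). The constant cancels identically in the whiteboard ratio
Rd = (Mac/Mac,ref)·Rd,ref, which is the only downstream consumer, so the
2/3 form is kept; anyone using Mac as an absolute amplitude must divide
by √2. The fx = 0 channel cannot be demodulated this way (three identical
phases give zero) and always goes through the planar ratio
Rac = (Iac/Iref)·Rd,ref. The whiteboard reflectance default is
Rd,ref = 0.99.

Reference-amplitude pixels below 1e−6 of the image maximum are masked (NaN)
rather than divided; masks propagate through inversion. How a physical rig
should treat saturated or dark pixels is a policy choice — masking is ours.

## Inversion

Per spectrum, (μa, μs′) is fit by bounded trust-region nonlinear least
squares (μa ∈ [1e−6, 5], μs′ ∈ [1e−3, 10] mm⁻¹), initialised at
(0.01, 1.0) mm⁻¹ with one retry from (0.1, 0.5) when the first fit stalls.
All available frequencies enter the fit, including the planar channel.
Ill-posed spectra (fewer than two distinct frequencies) are flagged in the
result rather than raised, so per-pixel maps degrade gracefully. A
brute-force 200 × 200 grid search over the bounds serves as an independent
oracle in the tests: the optimiser's residual is never above the best grid
point's.

Per-pixel fits can be replaced by b × b mean-binned superpixel fits
(`bin_factor`) where throughput matters; the classification cohort uses
binning since its features are ROI means anyway.

The phantom linear correction is k = (1/m) Σ ref_i/measured_i per
wavelength and coefficient, applied as calibrated = k·measured; a purely
multiplicative system bias is removed exactly, which the tests assert.

## Projector geometry and keystone correction

The projector is a pinhole with intrinsics (fu, fv, cu, cv), mounted at
height h above the target plane and rotated by pitch α about the image
x-axis then yaw β about the image y-axis; roll is taken as zero (the rig's
mechanical design constrains it). Image→plane and plane→image maps are
derived directly from this composition and are exact mutual inverses
(round-trip asserted at 1e−9 px). The reference rig instance is
fu = 2116.8, fv = 2122.4, cu = 670.4, cv = −186.8 px, h = 527 mm.

Pre-correction evaluates, for every projector pixel, the plane point its
ray hits under the assumed tilt, and paints the pattern value an untilted
projector would need there; sinusoid specs are evaluated analytically
(phase-accurate, no quantisation), while arbitrary pattern images go
through bilinear resampling with out-of-frame pixels set to 0. Projected
through the true geometry, a correctly parameterised pattern lands as
straight vertical fringes.

The fringe-uniformity error ep is the mean per-column standard deviation of
the min–max-normalised fringe image. The sample standard deviation
(ddof = 1) is used; the choice (vs population std) rescales ep slightly but
cannot move the location of the sweep minimum. The angle sweep evaluates ep
over candidate (α, β) grids — default pitch 12–22° step 1°, yaw 0–1° step
0.1° — correcting at the candidate angles and simulating the projection at
the true ones; ties resolve to the lowest pitch, then yaw, with a warning.
Plane renderings are scored inside an axis-aligned window inscribed in the
projector footprint.

## Frequency calibration

The realised fringe period on the sample plane is estimated from a 1-D
reflectance profile averaged along the fringes: local minima of a lightly
smoothed (Gaussian, σ = 2 px) profile, refined to sub-pixel positions by a
three-point parabolic fit, with the period as the mean minima spacing. At
least two full periods must fit in the analysis window; with a 140 mm
window (inset from the 150 mm whiteboard) exactly the nine reference
frequencies above 0.014 mm⁻¹ qualify, and lower frequencies get their
period ratio by linear-in-frequency extrapolation, flagged as estimates.

The calibration chain is Tr = Tc·Xr/Xc̄ (checkerboard scale: Xr = 5 mm
cells, Xc̄ = 78.3 px in the reference rig), rrp = Tp/Tr, and
Tp = rrp·Tre for a requested plane period Tre. Generated periods are kept
at 0.1 px precision via phase-accurate synthesis — integer rounding alone
would reintroduce errors of the size the calibration removes. The two-step
procedure generates all targets from the bootstrap ratio rrp(0), measures
the realised periods Tv, updates per-frequency ratios rrp(k) = Tp(k)/Tv(k),
and regenerates: a frequency-independent multiplicative bias is removed
exactly in one update, which the simulator tests confirm (2% bias → under
0.05% mean error). Measurement failures flag their frequency and leave the
rest of the batch intact.

## Phantom reference properties

Reference μa comes from Beer–Lambert, μa = −ln(T)/d, applied to collimated
transmittance of the pure-ink dilution. Reference μs′ comes from Mie
theory: the in-package Mie series (Bohren–Huffman logarithmic-derivative
recurrence, Wiscombe truncation order) yields Qsca and the asymmetry factor
g; with number density N = 6·vf/(π d³) under independent scattering
(vf ≤ 0.2%), μs′ = Qsca·(π d²/4)·N·(1 − g). The implementation reproduces
the classic non-absorbing benchmark sphere (m = 1.55, x = 5.2128,
Qext = 3.10543) and agrees with an independent spherical-Bessel evaluation
to machine precision.

The TiO2 particle diameter (500 nm), particle index (2.49), water index
(1.33) and the packaged ink extinction spectrum are synthetic stand-in
constants — spectrally plausible, clearly labeled, but not measured values
of any particular ink or powder batch. Reference tables built from them are
therefore structurally faithful (exact linearity in the volume fractions,
positive at all six wavelengths 460–675 nm) without claiming absolute
magnitudes. The two series follow the calibration protocol: series 1
(TiO2 fixed at 0.1%, ink 0.004–0.02%) calibrates μa, series 2 (ink fixed at
0.006%, TiO2 0.04–0.2%) calibrates μs′.

## Simulator

`simulate_stack` renders, per frequency and phase,
Ik(x) = gain·[0.5 + 0.5·Rd(x, fx)·cos(2πfx·x + 2πk/3)] plus additive
Gaussian noise expressed as a fraction of the gain; the whiteboard stack
uses Rd,ref everywhere. The spatial scale is 400 px / 26 mm ≈ 15.4 px/mm.
The illumination is a pure AC/DC sinusoid: no projector MTF, vignetting,
gamma, stray light or sample curvature. That matches the pipeline's working
assumption that whiteboard normalisation removes the system response —
so simulator-backed tests validate the computational chain, not those
physical non-idealities, and say nothing about e.g. MTF-induced
high-frequency attenuation on a real rig.

Damage scenes place class-specific lesions on a homogeneous background
(μa = 0.02, μs′ = 1.2 mm⁻¹): none (normal), a disc (bruise), thin vertical
stripes (scratch), a speckled patch (abrasion). Lesion contrasts are
synthetic stand-ins — bruise (+30% μa, −20% μs′), scratch (+15%, −10%),
abrasion (+40%, −35%) — as no measured per-class contrasts are available.
Footprints were chosen by a sensitivity analysis of the forward model
rather than by eye:

- at the background operating point, ∂Rd(0)/∂ln μa ≈ −∂Rd(0)/∂ln μs′, so a
  planar measurement sees only coverage × (dμa − dμs′). Abrasion coverage
  is set to 2/3 of bruise coverage, making the two classes nearly metameric
  under planar light while they stay separated in the (μa, μs′) plane —
  exactly the information the SFDI feature set adds;
- scratch effects are half the bruise effects, so scratch coverage is set
  to twice bruise coverage, making the two classes' ROI means coincide —
  the hard pair that only the three-class regrouping (normal / minor /
  serious) resolves.

Background jitter is 0.2% (controlled same-batch fruit), effect jitter 5%,
footprint jitter ±3%; all randomness flows through one seeded generator per
scene, and identical seeds give bit-identical stacks. Because the class
structure is designed, the cross-validated accuracies measure the
pipeline's ability to exploit that structure; the accuracy *orderings*
(SFDI ≥ planar, three-class ≥ four-class) are the meaningful outputs, not
the absolute percentages, which depend on real-fruit variability no desk
simulation reproduces.

## Classification

Features are ROI means after 2 × 2 binning (a 400 × 400 px ROI reduces to
200 × 200 samples): (mean μa, mean μs′) for the SFDI model, mean calibrated
planar reflectance for the planar model — a single DC measurement cannot
separate absorption from scattering, so a scalar is all planar light
provides. Accuracy is stratified 5-fold cross-validation of a linear
discriminant classifier with seeded fold assignment; stratification keeps
every class present in every training fold and is required for the small
per-class counts used here.

## Problem sizes

Simulated scenes are 64 × 64 px (classification) and 16–32 px squares
(recovery studies); cohorts are 20 scenes per class; keystone renderings
are 100–120 px square over 121 candidate angle pairs. These sizes keep the
full suite and the acceptance script in the tens of seconds while leaving
every estimate comfortably inside its tolerance; all of them scale up
linearly through the public APIs.

## Known limitations

- No projector MTF / gamma model, no lens-distortion or roll-angle
  correction, no sample-curvature (profilometry) correction.
- The inversion is a two-parameter homogeneous fit per pixel; layered media
  (fruit peel over flesh) bias the recovered coefficients toward a depth-
  weighted mixture.
- Phantom reference magnitudes depend on synthetic optical constants (see
  above); only their structure is meaningful.
- Sub-threshold frequencies receive extrapolated, not measured, period
  ratios.
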