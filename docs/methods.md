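# Methods

This note records the models behind `hsoct`, the defaults and why they
were chosen, and what the synthetic data can and cannot say about real
measurements.

## Optical material models

Wavelengths are vacuum wavelengths in nm throughout.  Eumelanin's real
index is an inverse-power-law fit (constant term 1.6840) and its
extinction coefficient κ a quartic fit derived from rodent-RPE absorption
via κ = μ_a λ/(4π); both are empirical fits trusted only on 400–700 nm, so
evaluation outside that window raises an error instead of extrapolating.
κ is clamped at zero in case the quartic undershoots inside the window.
The silicone host uses a quadratic fit with κ = 0 (transparent); the
non-melanin RPE medium is a wavelength-independent 1.368 + 0i (its
residual absorption is negligible next to melanin's); N-BK7 uses the
standard catalogue Sellmeier coefficients (valid 300–2500 nm).

Simulator caveat: detector pixels at the spectral edges (the default
spectrometer spans 425–735 nm, see below) fall slightly outside the fit
window; for scene reflectivities only, the indices are held at their
boundary values there.  The public material API still raises.

## Mie backscattering

Mie coefficients for an absorbing sphere in a lossless medium are computed
with the downward-recurrence logarithmic derivative (term count from the
Wiscombe rule n_max = ⌈x + 4x^{1/3} + 2⌉).  The exported quantity is the
radar backscattering efficiency

    Q_b = (1/x²) |Σ_n (2n+1)(−1)ⁿ(a_n − b_n)|²,

i.e. exact-backscatter rather than an NA-integrated cross-section, because
a conventional OCT detector collects the directly backscattered field.
μ_b = N·Q_b·π(d/2)² assumes independent scatterers, which is adequate at
the ≤30 mg/mL concentrations studied; dependent-scattering corrections are
out of scope.  Illumination is a plane wave — a focused Gaussian beam
shifts the Mie spectra slightly but leaves the modulation structure, which
is the detected signal, unchanged.  Granules are modelled as spheres; the
real granules are small ellipsoids, so simulated spectra are an idealized
stand-in for the per-granule variability seen in tissue.

Mass concentration converts to number density as N = c/(ρ·(π/6)d³) with a
melanosome mass density ρ = 1.7 g/cm³ (literature value; configurable).

## Ball-lens optics

The phantom's N-BK7 ball lens is modelled paraxially: f(λ) = n(λ)D/(4(n−1)),
with focal shifts quoted against a 500 nm reference.  A paraxial model
ignores spherical aberration, which moves the best focus slightly; the
chromatic *difference* it predicts is the quantity of interest and is
accurate to within ~10–15% of a full ray trace.  The beam waist at focus is
taken as the diffraction-limited Airy radius for a user-supplied input beam
diameter (there is no default claim of fidelity for that diameter), and the
in-focus depth range is the intersection over λ of [f − b/2, f + b/2] with
b = 2πw₀²/λ.  The length of that overlap depends strongly on the input
beam diameter: 0.5 mm gives ≈50 μm for the 3 mm lens, 1 mm gives none.

## Forward model (synthetic interferograms)

Each A-scan's detector spectrum is

    I(p) = S(λ_p)[R_ref + Σ r_j + 2Σ √(R_ref r_j) cos(2k_p n_g z_j + φ(k_p))] + noise,

with φ(k) = a₂(k−k₀)² + a₃(k−k₀)³ and k₀ the centre of the detector's k
range.  Defaults, chosen once as a plausible white-light retinal system:

* spectrometer: 2048 pixels uniform in λ over 425–735 nm (hence nonuniform
  in k).  The span extends past the 440–700 nm band centres so the
  edge-band Gaussian windows lose <1% of their energy at the grid edge.
* source: Gaussian (centre 565 nm, σ 120 nm) times a magenta-filter dip
  (depth 0.55 at 545 nm, σ 40 nm).  The real filter curve is unpublished;
  the dip depth is a free parameter.
* noise: additive Gaussian read noise, SD 1.5×10⁻³ of the peak source
  power (≈35 dB image SNR for a typical granule); optional Poisson-like
  shot noise, off by default.  Sensitivity roll-off in depth is available
  as a Gaussian envelope but off by default.
* lateral PSF: Gaussian, FWHM 2.5 μm at 550 nm scaling ∝ λ; A-scan pitch
  1.5 μm.
* axial sampling: the resampled k span gives a depth pitch of ≈0.50 μm
  optical path per pixel, so the 6 μm resolution and 50 μm windows span
  ≥12 and ≥100 pixels respectively.

Speckle is not modelled multiplicatively: it emerges from coherent
summation of randomly placed sub-resolution scatterers, which preserves
the wavelength dependence of speckle that the watershed binning exists to
handle.

Scenes: the *phantom* scene is a bright flat-spectrum interface line at
the lens surface plus granules drawn as a homogeneous Poisson process in a
slab (170 μm deep, slice thickness 2.5 μm), diameters log-normal with mode
2.4 μm (σ_log = 0.25, matching the measured peak diameter of precipitated
eumelanin particles); granule reflectivity is r(λ) = 10⁻⁴·Q_b(λ).  The
*retina* scene places sparse RPE granules (diameters 0.3–1.0 μm, ≈1.5 per
2.5 μm lateral resolution cell, mirroring the low granule counts per
A-scan in the pigmented rat) nearest the zero delay (enhanced-depth
convention) with flat-spectrum diffuse layers behind; the albino variant
shares the identical layer realization (same seed) and simply omits the
granules — in an albino RPE the melanosomes that dominate its backscatter
are absent.  All randomness flows from one integer seed.

## Reconstruction

Background removal divides out the detected reference spectrum
((I − I_ref)/I_ref), masking pixels where the reference falls below 2% of
its peak.  Cubic splines resample the fringes onto a uniform k grid.  The
27 Gaussian windows share one FWHM in k derived from the Gaussian
coherence-length relation Δk = 4·ln2/(n_tissue·δz); the 6 μm in-tissue
target with n_tissue = 1.38 gives 0.3349 rad/μm.  That FWHM value itself
is this package's operational definition — only the resolution target is
prescribed.  Windows are peak-normalized (not area-normalized) so band
intensities report spectral density; since the DFM statistic subtracts
per-basin means, this choice only sets an overall scale.

Dispersion is compensated by multiplying with exp(−iφ̂(k)).  When the
coefficients are estimated from the data, the estimator minimizes the
entropy of the normalized reconstructed intensity — an image-sharpness
criterion chosen here (the published method's metric is unspecified) —
over a full 2-D coarse grid followed by a Nelder–Mead polish.  The grid
matters: the entropy landscape couples a₂ and a₃, and sequential 1-D
searches can stall in local minima.

Each windowed band is FFT'd; the positive-delay half is kept (the sample
sits entirely at positive delay, per the enhanced-depth convention) and
stored as linear intensity |A|².  The first 4 depth pixels are zeroed to
suppress the residual DC line.  Band images are registered by integer
axial shifts maximizing cross-correlation of mean A-scan envelopes against
the middle (570 nm) band — an automated replacement for what was
originally a manual step; sub-pixel registration is deferred.  Repeats are
reconstructed independently and averaged pixelwise in linear intensity
before any analysis.

Axial PSF widths are measured on the *amplitude* envelope (√intensity),
consistent with the coherence-length definition of resolution.

## DFM analysis

The MIP across bands is watershed-segmented (basins around local maxima of
the MIP, i.e. watershed of the inverted image, seeded by local minima).
Basins smaller than 8 μm² — just below the resolution cell — are merged
into the neighbor sharing the longest boundary, with union–find semantics
so mutually-small neighbors collapse correctly.  Per-basin band means,
deviation spectra and DFM = ∫|I_dev|dλ (trapezoidal rule on the 10 nm
grid; "numerical integral" left the rule open) follow.  DFM is always
computed on basin-mean spectra, never per pixel: single-pixel spectra are
speckle-corrupted, which is the reason for the watershed binning.

Thresholding: the noise region of interest is the signal-free area
anterior to the shallowest detected surface row (the surface is the first
50%-of-column-max crossing, median-filtered over 5 columns).  For the
basin-painted DFM map, noise statistics use only basins fully contained in
that region, because straddling basins carry values driven by the bright
structure below.  The binary maps mark pixels above *noise mean + k·SD*
(k = 3 by default).  Adding the mean matters: DFM is a one-sided integral
of absolute deviations, so its noise distribution has a positive mean of
the same order as its SD, and a bare 3·SD cut would sit below the noise
floor and mark roughly half of all empty basins.  With the mean included
the empty-region false-positive rate is ~1%, matching the observed
behaviour of the method (albino retinas essentially dark after
thresholding).  The same definition is applied to the intensity images for
consistency.  The concentration metric is the percentage of pixels above
threshold over 50 μm of depth starting one axial resolution (6 μm) below
the surface line, which is excluded because its DFM values are dominated
by saturation effects rather than spectral structure.

## What the synthetic data shows — and does not

The simulator reproduces the mechanisms the method relies on: Mie spectral
modulation, wavelength-dependent speckle, band-window spectral smoothing
(granules much larger than ~2 μm have Mie oscillations faster than the
window bandwidth and lose contrast — visible in simulation exactly as the
sampling-density argument predicts), interface flatness, and the
concentration saturation of the DFM fraction.  It does not model motion,
multiple scattering, attenuation by overlying layers, polarization,
ellipsoidal granule shapes, or instrument-specific roll-off; passing tests
therefore validate the *processing chain and statistic*, not instrument
performance.  Absolute percentages from the concentration analysis are
simulator-specific; only their shapes (intensity ≈ linear, DFM rising then
plateauing; pigmented≫albino RPE contrast) transfer.

## Problem sizes

Tests and the acceptance script use B-scans of 128 A-scans × 2048 pixels
with 3 repeats, 5 seeds per concentration, and 24-granule validation
grids — sizes at which every stage's statistical behaviour (Poisson counts,
√R noise averaging, threshold false-positive rates) is already stable.
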