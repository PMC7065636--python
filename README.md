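# hsoct — hyperspectral visible-light OCT for Mie-regime melanin detection

Melanin granules in the retinal pigment epithelium (RPE) are comparable in
size to visible wavelengths, so they backscatter in the Mie regime: their
backscattering coefficient μ_b(λ) oscillates with wavelength, unlike the
flat spectra of large interfaces or bulk tissue.  A visible-light
spectral-domain OCT system can expose these modulations by splitting each
acquired spectrum into 27 sub-bands (centres 440–700 nm, 10 nm steps,
constant bandwidth in wavenumber) and Fourier-transforming each band into
its own depth-resolved image.  The result is a hyperspectral B-scan stack
in which every pixel carries a 27-sample spectrum — and melanin granules
stand out because their spectra deviate strongly from flat.

`hsoct` implements this method end to end, for people who want to study,
stress-test or extend it without an instrument:

* **Optical models** — wavelength-dependent complex refractive indices
  n(λ) + iκ(λ) for eumelanin, silicone, the RPE medium and N-BK7 glass;
  Mie backscattering efficiencies and μ_b(λ) spectra of granule
  populations; the paraxial chromatic-focus model of the ball-lens eye
  phantom (focal shift and confocal-parameter overlap).
* **Simulator** — a seeded SD-OCT interferogram generator: white-light
  source with suppressed mid band, spectrometer sampling nonlinear in
  wavenumber, 2nd/3rd-order dispersion, Mie-granule / interface / tissue
  scatterers, speckle from random sub-resolution scatterer placement,
  additive noise, repeated B-scans.
* **Reconstruction** — background removal, k-linearization, the 27
  Gaussian band windows, numerical dispersion compensation (entropy
  minimization), per-band FFT, axial registration.
* **Detection statistic** — watershed segmentation of the across-band
  maximum intensity projection into single-speckle basins, per-basin band
  spectra, and the deviation-from-mean statistic

      DFM = ∫|I(λ) − ⟨I⟩| dλ   over λ = 440…700 nm,

  mapped back into image space, thresholded against the noise level, and
  summarized as the fraction of pixels above threshold in a 50 μm depth
  window below the sample surface.

## Worked example

Simulate a 10 mg/mL melanin-in-silicone phantom B-scan (128 A-scans,
3 repeats), reconstruct the 27-band stack, and run the DFM analysis:

```bash
cat > run.yaml <<EOF
simulate:
  scene: phantom
  concentration_mg_ml: 10.0
  n_ascans: 128
  repeats: 3
  seed: 42
EOF
hsoct simulate   --config run.yaml --out sim
hsoct reconstruct sim/raw.npz  --config run.yaml --out rec
hsoct analyze     rec/stack.tiff --config run.yaml --out ana
```

which prints

```
wrote sim/raw.npz (73 granules)
wrote rec/stack.tiff (27 bands)
{
  "intensity_pct": 11.707589285714286,
  "dfm_pct": 47.505580357142854
}
```

and writes `ana/summary.json`, the per-basin table `ana/basins.csv`, and
PNG renderings of the MIP, the DFM map, its thresholded binary version and
the 540/550/560 nm RGB encoding.  Reading the numbers: the scene drew 73
granules from the Poisson process implied by 10 mg/mL; after
reconstruction, 11.7% of the pixels in the 50 μm analysis window exceed
the intensity threshold (noise mean + 3·SD of the intensity image) while
47.5% exceed the DFM threshold — the DFM map marks whole speckle basins
whose spectra are modulated, which is what makes sparse Mie scatterers
conspicuous.  The bright lens–silicone interface, being spectrally flat,
is suppressed in the DFM map relative to the intensity image.

Mie reference spectra (the model curves the detection rests on) come from

```bash
hsoct mie --out mie_out     # μ_b(λ) CSV + plot for d = 0.3/0.5/0.7/1.0 μm
```

## Layout

| module | contents |
| --- | --- |
| `hsoct.materials` | complex refractive index models |
| `hsoct.mie` | Mie coefficients, Q_b, μ_b spectra, concentration → number density |
| `hsoct.optics` | ball-lens focal shift, confocal parameter, focus overlap |
| `hsoct.synth` | scenes, forward model, archive I/O |
| `hsoct.recon` | k-linearization, band windows, dispersion, registration |
| `hsoct.dfm` | watershed basins, DFM statistic, thresholding, summaries |
| `hsoct.cli` / `hsoct.config` | `hsoct` command-line pipeline and YAML config |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
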