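"""Seeded synthetic spectral-domain OCT interferogram generator.

Forward model
-------------
A white-light source with a suppressed mid band (magenta-filter emulation)
illuminates a Michelson interferometer.  A spectrometer with a pixel→λ
mapping that is uniform in wavelength — hence nonlinear in wavenumber —
records, for each A-scan,

    I(p) = S(λ_p) [ R_ref + Σ_j r_j(λ_p)
           + 2 Σ_j sqrt(R_ref r_j(λ_p)) cos(2 k_p n_g z_j + φ(k_p)) ] + noise

with k_p = 2π/λ_p, group index n_g, scatterer depths z_j (μm), spectral
reflectivities r_j(λ) and residual dispersion phase
φ(k) = a₂(k−k₀)² + a₃(k−k₀)³.

Scatterers come in three kinds: Mie ``granule`` (r(λ) ∝ Q_b(λ) for the
sampled diameter), flat-spectrum ``interface`` lines and flat-spectrum
diffuse ``tissue`` scatterers.  Speckle arises naturally from coherent
summation of randomly placed sub-resolution scatterers, so its wavelength
decorrelation — the effect the watershed binning exists to handle — is
reproduced rather than modelled multiplicatively.  The lateral point-spread
function is a Gaussian whose width scales with λ (≈2.5 μm FWHM at 550 nm).

Noise is additive Gaussian read noise plus optional Poisson-like shot
noise.  Every stochastic operation is reproducible from an integer seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import materials as mat
from . import mie

__all__ = [
    "SourceModel",
    "SpectrometerModel",
    "DispersionModel",
    "Scene",
    "RawInterferogram",
    "default_source",
    "default_spectrometer",
    "scene_reflectivity_spectra",
    "simulate_ascan",
    "simulate_bscan",
    "make_single_reflector_scene",
    "make_phantom_scene",
    "make_retina_scene",
    "save_interferogram",
    "load_interferogram",
    "scene_table",
]

# ---------------------------------------------------------------------------
# Models

@dataclass(frozen=True)
class SourceModel:
    """Source spectral power density on the spectrometer's λ grid.

    The default emulates a white-light supercontinuum whose green mid band
    is suppressed by a magenta filter, leaving relatively more power at the
    spectral edges.
    """

    lam_nm: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        power = np.asarray(self.power, dtype=float)
        if np.any(power < 0):
            raise ValueError("source power density must be non-negative")
        if power[0] == 0 or power[-1] == 0:
            raise ValueError("source must be nonzero at both band edges")


@dataclass(frozen=True)
class SpectrometerModel:
    """Detector geometry: pixel→λ mapping and noise parameters.

    ``lam_nm`` maps pixel index to wavelength; the default mapping is
    uniform in λ (hence nonuniform in k = 2π/λ).  ``read_noise_sd`` is in
    units of the peak source power; ``rolloff_depth_um`` sets the 1/e depth
    of a Gaussian sensitivity roll-off emulating finite pixel integration
    (``None`` disables it).
    """

    lam_nm: np.ndarray
    read_noise_sd: float = 1.5e-3
    shot_noise: bool = False
    shot_noise_scale: float = 1e-6
    rolloff_depth_um: float | None = None

    def __post_init__(self):
        lam = np.asarray(self.lam_nm, dtype=float)
        d = np.diff(lam)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("pixel→λ mapping must be strictly monotone")

    @property
    def n_pixels(self) -> int:
        return int(np.asarray(self.lam_nm).size)

    @property
    def k_per_um(self) -> np.ndarray:
        """Wavenumber per pixel, rad/μm."""
        return 2.0 * np.pi / (np.asarray(self.lam_nm, dtype=float) / 1000.0)

    def unambiguous_depth_um(self, n_group: float) -> float:
        """Largest optical depth representable without fringe aliasing."""
        dk = np.abs(np.diff(self.k_per_um)).max()
        return float(np.pi / (2.0 * dk * n_group))


@dataclass(frozen=True)
class DispersionModel:
    """Residual 2nd/3rd-order dispersion phase φ(k) = a₂(k−k₀)² + a₃(k−k₀)³.

    a₂ in μm² (rad per (rad/μm)²), a₃ in μm³; ``k0_per_um`` defaults to the
    centre of the spectrometer's k range at simulation time.
    """

    a2_um2: float = 0.0
    a3_um3: float = 0.0
    k0_per_um: float | None = None

    def phase(self, k_per_um: np.ndarray, k0_default: float) -> np.ndarray:
        k0 = self.k0_per_um if self.k0_per_um is not None else k0_default
        dk = np.asarray(k_per_um, dtype=float) - k0
        return self.a2_um2 * dk**2 + self.a3_um3 * dk**3


@dataclass(frozen=True)
class Scene:
    """Ground-truth scatterer description for one B-scan.

    Scatterers are points at depth ``z_um`` (physical μm below zero delay)
    and lateral position ``x_um``.  ``kind`` labels each as ``granule``,
    ``interface`` or ``tissue``; granules carry a diameter and get a Mie
    reflectivity spectrum r(λ) = r_scale · Q_b(λ); the others are
    wavelength-flat with r(λ) = r_scale.
    """

    z_um: np.ndarray
    x_um: np.ndarray
    kind: np.ndarray
    diameter_um: np.ndarray
    r_scale: np.ndarray
    medium: str = "rpe_medium"
    n_group: float = 1.38
    lateral_extent_um: float = 256.0
    slice_thickness_um: float = 2.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        z = np.asarray(self.z_um, dtype=float)
        if np.any(z < 0):
            raise ValueError("scatterer depths must be non-negative")
        r = np.asarray(self.r_scale, dtype=float)
        if np.any(r < 0):
            raise ValueError("reflectivities must be non-negative")

    @property
    def n_scatterers(self) -> int:
        return int(np.asarray(self.z_um).size)

    def mask(self, kind: str) -> np.ndarray:
        return np.asarray(self.kind) == kind


@dataclass(frozen=True)
class RawInterferogram:
    """Simulated detector spectra: (pixels × A-scans × repeats) + calibration."""

    spectra: np.ndarray
    spectrometer: SpectrometerModel
    source: SourceModel
    reference: np.ndarray          # detected reference spectrum S(λ)·R_ref
    dispersion: DispersionModel
    scene: Scene
    seed: int
    lateral_pitch_um: float
    r_ref: float = 1.0

    @property
    def n_ascans(self) -> int:
        return self.spectra.shape[1]

    @property
    def n_repeats(self) -> int:
        return self.spectra.shape[2]


# ---------------------------------------------------------------------------
# Defaults

#: Default spectrometer wavelength span, nm.  Wider than the 440–700 nm band
#: centres so the edge-band Gaussian windows are not truncated.
DEFAULT_LAMBDA_SPAN = (425.0, 735.0)
DEFAULT_N_PIXELS = 2048
#: Lateral PSF FWHM at 550 nm, μm.
DEFAULT_LATERAL_FWHM_UM = 2.5
#: Lateral A-scan pitch, μm.
DEFAULT_LATERAL_PITCH_UM = 1.5


def default_spectrometer(
    n_pixels: int = DEFAULT_N_PIXELS,
    lam_span_nm: tuple[float, float] = DEFAULT_LAMBDA_SPAN,
    **kwargs,
) -> SpectrometerModel:
    """Spectrometer with pixels uniform in wavelength over ``lam_span_nm``."""
    lam = np.linspace(lam_span_nm[0], lam_span_nm[1], n_pixels)
    return SpectrometerModel(lam_nm=lam, **kwargs)


def default_source(
    spectrometer: SpectrometerModel,
    center_nm: float = 565.0,
    sigma_nm: float = 120.0,
    suppression_depth: float = 0.55,
    suppression_center_nm: float = 545.0,
    suppression_sigma_nm: float = 40.0,
) -> SourceModel:
    """Broad Gaussian source with a magenta-filter mid-band suppression."""
    lam = np.asarray(spectrometer.lam_nm, dtype=float)
    base = np.exp(-0.5 * ((lam - center_nm) / sigma_nm) ** 2)
    dip = suppression_depth * np.exp(
        -0.5 * ((lam - suppression_center_nm) / suppression_sigma_nm) ** 2
    )
    return SourceModel(lam_nm=lam, power=base * (1.0 - dip))


# ---------------------------------------------------------------------------
# Reflectivity spectra

def scene_reflectivity_spectra(scene: Scene, lam_nm: np.ndarray) -> np.ndarray:
    """Per-scatterer reflectivity spectra r_j(λ) on ``lam_nm``: (n_scat, n_λ).

    Granules get r_scale · Q_b(λ) for their diameter in the scene medium;
    interface and tissue scatterers are wavelength-flat at r_scale.
    """
    lam = np.asarray(lam_nm, dtype=float)
    n = scene.n_scatterers
    r = np.empty((n, lam.size))
    r[:] = np.asarray(scene.r_scale, dtype=float)[:, None]
    gmask = scene.mask("granule")
    if np.any(gmask):
        medium = mat.material(scene.medium)
        melanin = mat.material("melanin")
        # Detector pixels at the spectral edges can sit slightly outside the
        # index fits' validity window; hold the indices at the boundary value
        # there rather than extrapolating the fit polynomials.
        lam_med = np.clip(lam, *medium.valid_range)
        lam_mel = np.clip(lam, *melanin.valid_range)
        n_med = np.real(np.asarray(medium.n(lam_med), dtype=float))
        m_gran = np.asarray(melanin.m(lam_mel))
        m_rel = m_gran / n_med
        for j in np.flatnonzero(gmask):
            d = float(np.asarray(scene.diameter_um)[j])
            x = mie.size_parameter(d, lam, n_med)
            r[j] *= mie.backscattering_efficiency_grid(x, m_rel)
    return r


# ---------------------------------------------------------------------------
# Forward model

def _lateral_sigma_um(lam_nm: np.ndarray) -> np.ndarray:
    """λ-dependent lateral PSF sigma (μm); FWHM 2.5 μm at 550 nm."""
    return (DEFAULT_LATERAL_FWHM_UM / 2.355) * np.asarray(lam_nm, dtype=float) / 550.0


def _deterministic_spectrum(
    scene: Scene,
    source: SourceModel,
    spectrometer: SpectrometerModel,
    dispersion: DispersionModel,
    x_um: float,
    r_spectra: np.ndarray,
    r_ref: float,
) -> np.ndarray:
    lam = np.asarray(spectrometer.lam_nm, dtype=float)
    k = spectrometer.k_per_um
    k0_default = 0.5 * (k.min() + k.max())
    phi = dispersion.phase(k, k0_default)

    sigma_x = _lateral_sigma_um(lam)
    dx = np.asarray(scene.x_um, dtype=float) - x_um
    near = np.abs(dx) < 4.0 * sigma_x.max()
    I = np.full(lam.size, r_ref)
    if np.any(near):
        z = np.asarray(scene.z_um, dtype=float)[near]
        w = np.exp(-0.5 * (dx[near][:, None] / sigma_x[None, :]) ** 2)
        r_eff = r_spectra[near] * w                       # (n_near, n_pix)
        if spectrometer.rolloff_depth_um is not None:
            atten = np.exp(-((z * scene.n_group) / spectrometer.rolloff_depth_um) ** 2)
            r_eff = r_eff * atten[:, None] ** 2
        phase = 2.0 * k[None, :] * scene.n_group * z[:, None] + phi[None, :]
        I = I + r_eff.sum(axis=0)
        I = I + 2.0 * (np.sqrt(r_ref * r_eff) * np.cos(phase)).sum(axis=0)
    return np.asarray(source.power, dtype=float) * I


def simulate_ascan(
    scene: Scene,
    source: SourceModel,
    spectrometer: SpectrometerModel,
    dispersion: DispersionModel,
    x_um: float = 0.0,
    rng: np.random.Generator | None = None,
    r_ref: float = 1.0,
    r_spectra: np.ndarray | None = None,
) -> np.ndarray:
    """Detector spectrum for the A-scan at lateral position ``x_um``.

    Deterministic given the ``rng`` state; pass ``rng=None`` for a
    noise-free spectrum.
    """
    z_max = float(np.max(scene.z_um)) if scene.n_scatterers else 0.0
    z_lim = spectrometer.unambiguous_depth_um(scene.n_group)
    if z_max > z_lim:
        warnings.warn(
            f"scene depth {z_max:.0f} μm exceeds the unambiguous range "
            f"{z_lim:.0f} μm; deep reflectors will alias (wrap)",
            stacklevel=2,
        )
    if r_spectra is None:
        r_spectra = scene_reflectivity_spectra(scene, spectrometer.lam_nm)
    I = _deterministic_spectrum(
        scene, source, spectrometer, dispersion, x_um, r_spectra, r_ref
    )
    if rng is not None:
        s_max = float(np.max(source.power))
        if spectrometer.read_noise_sd > 0:
            I = I + rng.normal(0.0, spectrometer.read_noise_sd * s_max, I.shape)
        if spectrometer.shot_noise:
            I = I + rng.normal(0.0, 1.0, I.shape) * np.sqrt(
                np.maximum(I, 0.0) * spectrometer.shot_noise_scale
            )
    return I


def simulate_bscan(
    scene: Scene,
    source: SourceModel | None = None,
    spectrometer: SpectrometerModel | None = None,
    dispersion: DispersionModel | None = None,
    n_ascans: int = 128,
    repeats: int = 1,
    seed: int = 0,
    lateral_pitch_um: float = DEFAULT_LATERAL_PITCH_UM,
) -> RawInterferogram:
    """Simulate ``repeats`` noise realizations of a B-scan.

    A-scans are taken at ``n_ascans`` lateral positions spaced
    ``lateral_pitch_um`` apart, starting at x = 0.  Repeats share the
    deterministic interference signal and differ only in noise.
    """
    spectrometer = spectrometer or default_spectrometer()
    source = source or default_source(spectrometer)
    dispersion = dispersion or DispersionModel()
    rng = np.random.default_rng(seed)

    r_spectra = scene_reflectivity_spectra(scene, spectrometer.lam_nm)
    n_pix = spectrometer.n_pixels
    out = np.empty((n_pix, n_ascans, repeats))
    s_max = float(np.max(source.power))
    for ia in range(n_ascans):
        x = ia * lateral_pitch_um
        det = _deterministic_spectrum(
            scene, source, spectrometer, dispersion, x, r_spectra, 1.0
        )
        for rep in range(repeats):
            I = det
            if spectrometer.read_noise_sd > 0:
                I = I + rng.normal(0.0, spectrometer.read_noise_sd * s_max, n_pix)
            if spectrometer.shot_noise:
                I = I + rng.normal(0.0, 1.0, n_pix) * np.sqrt(
                    np.maximum(I, 0.0) * spectrometer.shot_noise_scale
                )
            out[:, ia, rep] = I

    return RawInterferogram(
        spectra=out,
        spectrometer=spectrometer,
        source=source,
        reference=np.asarray(source.power, dtype=float).copy(),
        dispersion=dispersion,
        scene=scene,
        seed=seed,
        lateral_pitch_um=lateral_pitch_um,
    )


# ---------------------------------------------------------------------------
# Scene factories

#: Default reflectivity scale of a granule (multiplies Q_b(λ)).
GRANULE_R_SCALE = 1.0e-4
#: Flat reflectivity of the bright lens–silicone interface line.
INTERFACE_R = 2.0e-3
#: Mean flat reflectivity of a diffuse tissue scatterer.
TISSUE_R_MEAN = 3.0e-5


def make_single_reflector_scene(
    z_um: float = 100.0,
    r: float = 1.0e-3,
    x_um: float | None = None,
    lateral_extent_um: float = 48.0,
    medium: str = "rpe_medium",
    n_group: float = 1.38,
) -> Scene:
    """One flat-spectrum point reflector — the PSF measurement target."""
    if x_um is None:
        x_um = lateral_extent_um / 2.0
    return Scene(
        z_um=np.array([z_um]),
        x_um=np.array([x_um]),
        kind=np.array(["interface"]),
        diameter_um=np.array([np.nan]),
        r_scale=np.array([r]),
        medium=medium,
        n_group=n_group,
        lateral_extent_um=lateral_extent_um,
        meta={"type": "single_reflector"},
    )


def make_granule_grid_scene(
    diameter_um: float = 0.7,
    n_lateral: int = 6,
    n_axial: int = 4,
    seed: int = 0,
    z_start_um: float = 60.0,
    z_step_um: float = 35.0,
    lateral_extent_um: float = 192.0,
    medium: str = "rpe_medium",
    n_group: float = 1.38,
    granule_r_scale: float = 1.0e-4,
) -> Scene:
    """Well-separated monodisperse granules on a jittered grid.

    A validation scene: every granule shares one known Mie spectrum and is
    isolated in its own resolution cell, so the recovered per-basin band
    spectra can be compared against the model μ_b(λ) granule by granule.
    """
    rng = np.random.default_rng(seed)
    xs = (np.arange(n_lateral) + 0.5) * (lateral_extent_um / n_lateral)
    zs = z_start_um + z_step_um * np.arange(n_axial)
    gx, gz = np.meshgrid(xs, zs)
    gx = gx.ravel() + rng.uniform(-1.0, 1.0, gx.size)
    gz = gz.ravel() + rng.uniform(-3.0, 3.0, gz.size)
    n = gx.size
    return Scene(
        z_um=gz,
        x_um=gx,
        kind=np.full(n, "granule"),
        diameter_um=np.full(n, diameter_um),
        r_scale=np.full(n, granule_r_scale),
        medium=medium,
        n_group=n_group,
        lateral_extent_um=lateral_extent_um,
        meta={"type": "granule_grid", "diameter_um": diameter_um},
    )


def sample_phantom_diameters(rng: np.random.Generator, n: int) -> np.ndarray:
    """Log-normal diameter sampler with mode 2.4 μm (σ_log = 0.25)."""
    sigma = 0.25
    mu = np.log(2.4) + sigma**2
    return rng.lognormal(mu, sigma, n)


def make_phantom_scene(
    c_mg_ml: float,
    seed: int = 0,
    surface_z_um: float = 30.0,
    depth_extent_um: float = 170.0,
    lateral_extent_um: float = 192.0,
    slice_thickness_um: float = 2.5,
    diameter_sampler=sample_phantom_diameters,
    granule_r_scale: float = GRANULE_R_SCALE,
    interface_r: float = INTERFACE_R,
    rho_g_cm3: float = mie.MELANOSOME_DENSITY_G_CM3,
) -> Scene:
    """Melanin-in-silicone phantom: interface line + Poisson granules.

    Granule positions are a homogeneous Poisson process in the simulated
    slab (lateral extent × depth extent below the lens surface × slice
    thickness) with number density derived from the mass concentration
    ``c_mg_ml`` at the sampler's modal diameter.  Diameters are drawn from
    ``diameter_sampler`` (default log-normal, mode 2.4 μm).  A flat-spectrum
    bright interface line sits at the lens surface depth.
    """
    if c_mg_ml < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(seed)

    # Interface line: dense flat scatterers along the surface.
    xi = np.arange(0.0, lateral_extent_um, 1.0)
    z_list = [np.full(xi.size, surface_z_um)]
    x_list = [xi]
    kind_list = [np.full(xi.size, "interface")]
    d_list = [np.full(xi.size, np.nan)]
    r_list = [np.full(xi.size, interface_r)]

    n_density = mie.concentration_to_number_density(c_mg_ml, 2.4, rho_g_cm3)
    volume_um3 = lateral_extent_um * depth_extent_um * slice_thickness_um
    n_granules = rng.poisson(n_density * volume_um3)
    if n_granules > 0:
        z_list.append(surface_z_um + 4.0 + rng.uniform(0, depth_extent_um - 4.0, n_granules))
        x_list.append(rng.uniform(0, lateral_extent_um, n_granules))
        kind_list.append(np.full(n_granules, "granule"))
        d_list.append(diameter_sampler(rng, n_granules))
        r_list.append(np.full(n_granules, granule_r_scale))

    return Scene(
        z_um=np.concatenate(z_list),
        x_um=np.concatenate(x_list),
        kind=np.concatenate(kind_list),
        diameter_um=np.concatenate(d_list),
        r_scale=np.concatenate(r_list),
        medium="silicone",
        n_group=1.41,
        lateral_extent_um=lateral_extent_um,
        slice_thickness_um=slice_thickness_um,
        meta={
            "type": "phantom",
            "c_mg_ml": c_mg_ml,
            "surface_z_um": surface_z_um,
            "n_granules": int(n_granules),
            "number_density_per_um3": n_density,
        },
    )


def make_retina_scene(
    pigmented: bool,
    seed: int = 0,
    rpe_depth_um: float = 40.0,
    rpe_band_halfwidth_um: float = 2.5,
    granule_diameter_range_um: tuple[float, float] = (0.3, 1.0),
    granules_per_um: float = 0.6,
    lateral_extent_um: float = 192.0,
    granule_r_scale: float = GRANULE_R_SCALE,
) -> Scene:
    """Layered synthetic retina, pigmented (RPE granules) or albino (none).

    The RPE sits nearest the zero delay (enhanced-depth convention) with the
    inner retinal layers behind it, each layer a band of diffuse
    flat-spectrum scatterers dense enough to produce fully developed
    speckle.  When ``pigmented``, sparse melanin granules (≈1–2 per lateral
    resolution cell) with Mie spectra for diameters in
    ``granule_diameter_range_um`` are added in the RPE band.  The layer
    geometry and the non-granule scatterers are derived from ``seed`` alone,
    so a pigmented/albino pair with the same seed is matched.
    """
    ss = np.random.SeedSequence(seed)
    layer_rng, granule_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    z_list, x_list, kind_list, d_list, r_list = [], [], [], [], []
    # (z_lo, z_hi, scatterers per μm lateral, mean r) — inner retina layers.
    layers = [
        (60.0, 85.0, 2.0, TISSUE_R_MEAN),
        (95.0, 140.0, 2.5, 0.6 * TISSUE_R_MEAN),
        (150.0, 165.0, 2.0, TISSUE_R_MEAN),
    ]
    for z_lo, z_hi, dens, r_mean in layers:
        n = layer_rng.poisson(dens * lateral_extent_um)
        z_list.append(layer_rng.uniform(z_lo, z_hi, n))
        x_list.append(layer_rng.uniform(0, lateral_extent_um, n))
        kind_list.append(np.full(n, "tissue"))
        d_list.append(np.full(n, np.nan))
        r_list.append(layer_rng.exponential(r_mean, n))

    if pigmented:
        n_gran = granule_rng.poisson(granules_per_um * lateral_extent_um)
        z_list.append(
            rpe_depth_um
            + granule_rng.uniform(-rpe_band_halfwidth_um, rpe_band_halfwidth_um, n_gran)
        )
        x_list.append(granule_rng.uniform(0, lateral_extent_um, n_gran))
        kind_list.append(np.full(n_gran, "granule"))
        d_list.append(granule_rng.uniform(*granule_diameter_range_um, n_gran))
        r_list.append(np.full(n_gran, granule_r_scale))

    return Scene(
        z_um=np.concatenate(z_list),
        x_um=np.concatenate(x_list),
        kind=np.concatenate(kind_list),
        diameter_um=np.concatenate(d_list),
        r_scale=np.concatenate(r_list),
        medium="rpe_medium",
        n_group=1.38,
        lateral_extent_um=lateral_extent_um,
        meta={
            "type": "retina",
            "pigmented": bool(pigmented),
            "rpe_depth_um": rpe_depth_um,
            "rpe_band_halfwidth_um": rpe_band_halfwidth_um,
        },
    )


# ---------------------------------------------------------------------------
# Archive I/O (binary array container + JSON manifest sidecar)

def scene_table(scene: Scene) -> pd.DataFrame:
    """Scene as a table: one row per scatterer (z, x, label, d, peak_r)."""
    return pd.DataFrame(
        {
            "z_um": np.asarray(scene.z_um, dtype=float),
            "x_um": np.asarray(scene.x_um, dtype=float),
            "label": np.asarray(scene.kind, dtype=str),
            "diameter_um": np.asarray(scene.diameter_um, dtype=float),
            "peak_r": np.asarray(scene.r_scale, dtype=float),
        }
    )


def save_interferogram(raw: RawInterferogram, path: str | Path) -> Path:
    """Write raw spectra + calibration + ground truth as ``<path>.npz`` + JSON."""
    path = Path(path)
    npz_path = path.with_suffix(".npz")
    np.savez_compressed(
        npz_path,
        spectra=raw.spectra,
        lam_nm=np.asarray(raw.spectrometer.lam_nm, dtype=float),
        reference=raw.reference,
        source_power=np.asarray(raw.source.power, dtype=float),
        scene_z_um=np.asarray(raw.scene.z_um, dtype=float),
        scene_x_um=np.asarray(raw.scene.x_um, dtype=float),
        scene_kind=np.asarray(raw.scene.kind, dtype=str),
        scene_diameter_um=np.asarray(raw.scene.diameter_um, dtype=float),
        scene_r_scale=np.asarray(raw.scene.r_scale, dtype=float),
    )
    manifest = {
        "format": "hsoct-raw-v1",
        "seed": int(raw.seed),
        "r_ref": raw.r_ref,
        "lateral_pitch_um": raw.lateral_pitch_um,
        "n_pixels": int(raw.spectra.shape[0]),
        "n_ascans": int(raw.spectra.shape[1]),
        "n_repeats": int(raw.spectra.shape[2]),
        "spectrometer": {
            "read_noise_sd": raw.spectrometer.read_noise_sd,
            "shot_noise": bool(raw.spectrometer.shot_noise),
            "shot_noise_scale": raw.spectrometer.shot_noise_scale,
            "rolloff_depth_um": raw.spectrometer.rolloff_depth_um,
        },
        "dispersion": {
            "a2_um2": raw.dispersion.a2_um2,
            "a3_um3": raw.dispersion.a3_um3,
            "k0_per_um": raw.dispersion.k0_per_um,
        },
        "scene": {
            "medium": raw.scene.medium,
            "n_group": raw.scene.n_group,
            "lateral_extent_um": raw.scene.lateral_extent_um,
            "slice_thickness_um": raw.scene.slice_thickness_um,
            "meta": raw.scene.meta,
        },
    }
    manifest_path = path.with_suffix(".json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return npz_path


def load_interferogram(path: str | Path) -> RawInterferogram:
    """Read an archive written by :func:`save_interferogram`."""
    path = Path(path)
    npz_path = path.with_suffix(".npz")
    manifest = json.loads(path.with_suffix(".json").read_text())
    if manifest.get("format") != "hsoct-raw-v1":
        raise ValueError(f"not an hsoct raw archive: {path}")
    with np.load(npz_path, allow_pickle=False) as data:
        sm = manifest["spectrometer"]
        spectrometer = SpectrometerModel(
            lam_nm=data["lam_nm"],
            read_noise_sd=sm["read_noise_sd"],
            shot_noise=sm["shot_noise"],
            shot_noise_scale=sm["shot_noise_scale"],
            rolloff_depth_um=sm["rolloff_depth_um"],
        )
        source = SourceModel(lam_nm=data["lam_nm"], power=data["source_power"])
        dm = manifest["dispersion"]
        sc = manifest["scene"]
        scene = Scene(
            z_um=data["scene_z_um"],
            x_um=data["scene_x_um"],
            kind=data["scene_kind"],
            diameter_um=data["scene_diameter_um"],
            r_scale=data["scene_r_scale"],
            medium=sc["medium"],
            n_group=sc["n_group"],
            lateral_extent_um=sc["lateral_extent_um"],
            slice_thickness_um=sc["slice_thickness_um"],
            meta=sc["meta"],
        )
        return RawInterferogram(
            spectra=data["spectra"],
            spectrometer=spectrometer,
            source=source,
            reference=data["reference"],
            dispersion=DispersionModel(dm["a2_um2"], dm["a3_um3"], dm["k0_per_um"]),
            scene=scene,
            seed=manifest["seed"],
            lateral_pitch_um=manifest["lateral_pitch_um"],
            r_ref=manifest["r_ref"],
        )
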