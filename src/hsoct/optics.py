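"""Paraxial chromatic model of the N-BK7 ball-lens eye phantom.

A ball lens of diameter D and index n(λ) has paraxial effective focal length
f(λ) = n D / (4 (n − 1)), measured from the lens centre.  Because n(λ)
decreases with wavelength (normal dispersion), the focus shifts with colour;
over the 400–700 nm band the shift of a 3 mm N-BK7 ball is a few tens of
micrometres.  Whether all wavelengths can be considered simultaneously in
focus is decided by the confocal parameter b = 2π w₀²/λ: the usable depth
range is the intersection of the per-wavelength in-focus intervals
[f − b/2, f + b/2].

The beam waist at focus is taken as the diffraction-limited Airy radius for
a user-supplied input beam diameter (the spot is diffraction limited for
these lenses); the Gaussian-waist equivalent w₀ is set equal to that radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import nbk7_index

__all__ = [
    "BallLensSpec",
    "FocusProfile",
    "ball_lens_focal_length",
    "ball_lens_focal_shift",
    "confocal_parameter",
    "airy_waist",
    "focus_profile",
    "focus_overlap_interval",
]


@dataclass(frozen=True)
class BallLensSpec:
    """N-BK7 ball lens of diameter ``diameter_mm``."""

    diameter_mm: float

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("lens diameter must be positive")


@dataclass(frozen=True)
class FocusProfile:
    """Chromatic focus description on a wavelength grid.

    ``focal_shift_um`` is f(λ) − f(λ_ref); ``w0_um`` the beam waist;
    ``b_um`` the confocal parameter.  Focal positions are relative, so they
    are invariant to whether f is referenced to the lens centre or its back
    surface.
    """

    lam_nm: np.ndarray
    focal_shift_um: np.ndarray
    w0_um: np.ndarray
    b_um: np.ndarray
    lam_ref_nm: float

    def __post_init__(self):
        lam = np.asarray(self.lam_nm, dtype=float)
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(np.asarray(self.b_um) <= 0):
            raise ValueError("confocal parameter must be positive")


def ball_lens_focal_length(lens: BallLensSpec, lam_nm) -> np.ndarray:
    """Paraxial EFL f(λ) = n D / (4(n−1)) in mm, from the lens centre."""
    n = np.asarray(nbk7_index(lam_nm), dtype=float)
    if np.any(n <= 1):
        raise ValueError("ball lens focal length undefined for n <= 1")
    return n * lens.diameter_mm / (4.0 * (n - 1.0))


def ball_lens_focal_shift(
    lens: BallLensSpec,
    lam_nm: np.ndarray,
    lam_ref_nm: float = 500.0,
) -> np.ndarray:
    """Chromatic focal shift f(λ) − f(λ_ref) in μm."""
    lam = np.asarray(lam_nm, dtype=float)
    if not (lam.min() <= lam_ref_nm <= lam.max()):
        raise ValueError("reference wavelength outside the wavelength grid")
    f = ball_lens_focal_length(lens, lam)
    f_ref = float(ball_lens_focal_length(lens, lam_ref_nm))
    return (f - f_ref) * 1000.0


def confocal_parameter(w0_um, lam_nm) -> np.ndarray:
    """Confocal parameter b = 2π w₀²/λ in μm (twice the Rayleigh range)."""
    w0 = np.asarray(w0_um, dtype=float)
    lam = np.asarray(lam_nm, dtype=float)
    if np.any(w0 <= 0) or np.any(lam <= 0):
        raise ValueError("waist and wavelength must be positive")
    return 2.0 * np.pi * w0**2 / (lam / 1000.0)


def airy_waist(lens: BallLensSpec, lam_nm, beam_diameter_mm: float) -> np.ndarray:
    """Diffraction-limited waist: Airy radius 1.22 λ f / d_beam, in μm."""
    if beam_diameter_mm <= 0:
        raise ValueError("beam diameter must be positive")
    lam_um = np.asarray(lam_nm, dtype=float) / 1000.0
    f_um = ball_lens_focal_length(lens, lam_nm) * 1000.0
    return 1.22 * lam_um * f_um / (beam_diameter_mm * 1000.0)


def focus_profile(
    lens: BallLensSpec,
    lam_nm: np.ndarray,
    beam_diameter_mm: float,
    lam_ref_nm: float = 500.0,
) -> FocusProfile:
    """Chromatic focal shift, Airy waist and confocal parameter vs λ."""
    lam = np.asarray(lam_nm, dtype=float)
    shift = ball_lens_focal_shift(lens, lam, lam_ref_nm)
    w0 = airy_waist(lens, lam, beam_diameter_mm)
    b = confocal_parameter(w0, lam)
    return FocusProfile(lam, shift, w0, b, lam_ref_nm)


def focus_overlap_interval(profile: FocusProfile) -> tuple[float, float] | None:
    """Depth interval (μm) where every wavelength is in focus, or ``None``.

    Intersection over λ of [f(λ) − b(λ)/2, f(λ) + b(λ)/2], expressed
    relative to the reference-wavelength focus.
    """
    lo = np.max(profile.focal_shift_um - profile.b_um / 2.0)
    hi = np.min(profile.focal_shift_um + profile.b_um / 2.0)
    if hi <= lo:
        return None
    return float(lo), float(hi)
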