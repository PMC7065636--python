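"""Wavelength-dependent complex refractive index models.

All wavelengths are vacuum wavelengths in nanometres.  Four materials are
provided:

``melanin``
    Eumelanin granules.  The real part is an empirical inverse-power-law fit
    and the extinction coefficient κ is a quartic fit derived from the
    absorption coefficient of rodent-RPE melanin via κ = μ_a λ / (4π).
``silicone``
    The transparent elastomer used as the phantom host medium (quadratic fit
    to published dispersion data; κ = 0).
``rpe_medium``
    The non-melanin fraction of the retinal pigment epithelium, taken as a
    wavelength-independent n = 1.368 with κ = 0 (its residual absorption is
    negligible next to melanin's).
``nbk7``
    N-BK7 crown glass (standard Sellmeier form), the ball-lens material of
    the model-eye phantoms.

The fits are only trusted over the visible window they were built for;
evaluation outside ``valid_range`` raises :class:`WavelengthRangeError`
rather than extrapolating a diverging polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "WavelengthRangeError",
    "ComplexIndexModel",
    "melanin_index_real",
    "melanin_index_imag",
    "absorption_from_kappa",
    "kappa_from_absorption",
    "silicone_index",
    "rpe_medium_index",
    "nbk7_index",
    "material",
    "MATERIALS",
]

VISIBLE_RANGE = (400.0, 700.0)


class WavelengthRangeError(ValueError):
    """Wavelength outside the validity window of a refractive index fit."""


def _check_range(lam, valid_range, name: str):
    lam = np.asarray(lam, dtype=float)
    lo, hi = valid_range
    if np.any(lam < lo) or np.any(lam > hi):
        raise WavelengthRangeError(
            f"wavelength outside the {name} model's valid range "
            f"[{lo:g}, {hi:g}] nm"
        )
    return lam


@dataclass(frozen=True)
class ComplexIndexModel:
    """A material's complex refractive index n(λ) + iκ(λ), λ in nm."""

    name: str
    n_fn: Callable[[np.ndarray], np.ndarray]
    kappa_fn: Callable[[np.ndarray], np.ndarray]
    valid_range: tuple[float, float] = field(default=VISIBLE_RANGE)

    def n(self, lam_nm):
        """Real refractive index at ``lam_nm`` (scalar or array)."""
        lam = _check_range(lam_nm, self.valid_range, self.name)
        return self.n_fn(lam)

    def kappa(self, lam_nm):
        """Extinction coefficient at ``lam_nm`` (clamped at zero)."""
        lam = _check_range(lam_nm, self.valid_range, self.name)
        return np.maximum(self.kappa_fn(lam), 0.0)

    def m(self, lam_nm):
        """Complex index n + iκ at ``lam_nm``."""
        return self.n(lam_nm) + 1j * self.kappa(lam_nm)


def melanin_index_real(lam_nm):
    """Real refractive index of eumelanin, valid 400–700 nm."""
    lam = _check_range(lam_nm, VISIBLE_RANGE, "melanin")
    return (
        1.6840
        - 1.8723e4 * lam**-2
        + 1.0964e10 * lam**-4
        - 8.6484e14 * lam**-6
    )


def melanin_index_imag(lam_nm):
    """Extinction coefficient κ of eumelanin, valid 400–700 nm.

    Quartic fit to κ = μ_a λ/(4π) for rodent RPE melanin; clamped at zero in
    case the fit polynomial undershoots inside the window.
    """
    lam = _check_range(lam_nm, VISIBLE_RANGE, "melanin")
    kappa = (
        9.452e-13 * lam**4
        - 2.452e-9 * lam**3
        + 2.447e-6 * lam**2
        - 1.133e-3 * lam
        + 0.2124
    )
    return np.maximum(kappa, 0.0)


def absorption_from_kappa(kappa, lam_nm):
    """Absorption coefficient μ_a = 4πκ/λ in nm⁻¹ (inverse of κ = μ_a λ/4π)."""
    lam = np.asarray(lam_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("extinction coefficient must be non-negative")
    return 4.0 * np.pi * kappa / lam


def kappa_from_absorption(mu_a_per_nm, lam_nm):
    """Extinction coefficient κ = μ_a λ/(4π); μ_a in nm⁻¹."""
    lam = np.asarray(lam_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    return np.asarray(mu_a_per_nm, dtype=float) * lam / (4.0 * np.pi)


def silicone_index(lam_nm):
    """Complex index of the silicone elastomer host (κ = 0), 400–700 nm."""
    lam = _check_range(lam_nm, VISIBLE_RANGE, "silicone")
    n = 1.527e-7 * lam**2 - 2.260e-4 * lam + 1.494
    return n + 0j * lam


def rpe_medium_index(lam_nm):
    """Complex index of the non-melanin RPE medium: constant 1.368 + 0i."""
    lam = np.asarray(lam_nm, dtype=float)
    return 1.368 + 0j * lam


# N-BK7 Sellmeier coefficients (λ in μm), standard catalogue values.
_NBK7_B = (1.03961212, 0.231792344, 1.01046945)
_NBK7_C = (0.00600069867, 0.0200179144, 103.560653)
NBK7_RANGE = (300.0, 2500.0)


def nbk7_index(lam_nm):
    """Real refractive index of N-BK7 glass (Sellmeier), 300–2500 nm."""
    lam = _check_range(lam_nm, NBK7_RANGE, "N-BK7")
    lam_um2 = (lam / 1000.0) ** 2
    n2 = 1.0
    for b, c in zip(_NBK7_B, _NBK7_C):
        n2 = n2 + b * lam_um2 / (lam_um2 - c)
    return np.sqrt(n2)


MATERIALS: dict[str, ComplexIndexModel] = {
    "melanin": ComplexIndexModel(
        "melanin", melanin_index_real, melanin_index_imag, VISIBLE_RANGE
    ),
    "silicone": ComplexIndexModel(
        "silicone",
        lambda lam: np.real(silicone_index(lam)),
        lambda lam: np.zeros_like(np.asarray(lam, dtype=float)),
        VISIBLE_RANGE,
    ),
    "rpe_medium": ComplexIndexModel(
        "rpe_medium",
        lambda lam: np.full_like(np.asarray(lam, dtype=float), 1.368),
        lambda lam: np.zeros_like(np.asarray(lam, dtype=float)),
        VISIBLE_RANGE,
    ),
    "nbk7": ComplexIndexModel(
        "nbk7",
        nbk7_index,
        lambda lam: np.zeros_like(np.asarray(lam, dtype=float)),
        NBK7_RANGE,
    ),
}


def material(name: str) -> ComplexIndexModel:
    """Look up a material model by name ("melanin", "silicone", ...)."""
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(MATERIALS)}"
        ) from None
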