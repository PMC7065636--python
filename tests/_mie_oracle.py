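"""Independent brute-force Mie series used as a test oracle.

Evaluates the Mie coefficients directly from the Bohren–Huffman ratio
formulas using scipy's spherical Bessel functions (complex-argument
capable), with no logarithmic-derivative recurrence — a code path fully
independent of the package implementation.  Accurate for small-to-moderate
size parameters, which is all the oracle is used for.
"""

from __future__ import annotations

import numpy as np
from scipy.special import spherical_jn, spherical_yn


def _psi(n: int, z: complex) -> complex:
    return z * spherical_jn(n, z)


def _chi(n: int, z: float) -> float:
    return -z * spherical_yn(n, z)


def mie_ab_oracle(x: float, m: complex, n_max: int):
    """(a_n, b_n) for n = 1..n_max from the direct ratio formulas."""
    a = np.empty(n_max, dtype=complex)
    b = np.empty(n_max, dtype=complex)
    mx = m * x
    for n in range(1, n_max + 1):
        psi_x, psi_x_m1 = _psi(n, x), _psi(n - 1, x)
        psi_mx, psi_mx_m1 = _psi(n, mx), _psi(n - 1, mx)
        chi_x, chi_x_m1 = _chi(n, x), _chi(n - 1, x)
        xi_x = psi_x - 1j * chi_x
        xi_x_m1 = psi_x_m1 - 1j * chi_x_m1
        # derivatives via ψ_n'(z) = ψ_{n-1}(z) − n ψ_n(z)/z (same for ξ)
        dpsi_x = psi_x_m1 - n * psi_x / x
        dpsi_mx = psi_mx_m1 - n * psi_mx / mx
        dxi_x = xi_x_m1 - n * xi_x / x
        a[n - 1] = (m * psi_mx * dpsi_x - psi_x * dpsi_mx) / (
            m * psi_mx * dxi_x - xi_x * dpsi_mx
        )
        b[n - 1] = (psi_mx * dpsi_x - m * psi_x * dpsi_mx) / (
            psi_mx * dxi_x - m * xi_x * dpsi_mx
        )
    return a, b


def q_back_oracle(x: float, m: complex, n_max: int | None = None) -> float:
    """Radar backscattering efficiency from the oracle coefficients."""
    if n_max is None:
        n_max = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    a, b = mie_ab_oracle(x, m, n_max)
    n = np.arange(1, n_max + 1)
    s = np.sum((2 * n + 1) * (-1.0) ** n * (a - b))
    return float(np.abs(s) ** 2 / x**2)


def q_back_rayleigh(x: float, m: complex) -> float:
    """Rayleigh-limit closed form Q_b → 4x⁴ |(m²−1)/(m²+2)|²."""
    return float(4.0 * x**4 * np.abs((m**2 - 1.0) / (m**2 + 2.0)) ** 2)


def a1_rayleigh(x: float, m: complex) -> complex:
    """First-order small-x limit a₁ → −i(2x³/3)(m²−1)/(m²+2)."""
    return -1j * (2.0 * x**3 / 3.0) * (m**2 - 1.0) / (m**2 + 2.0)
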