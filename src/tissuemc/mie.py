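"""Mie scattering for homogeneous spheres in a non-absorbing medium.

Implements the Bohren–Huffman formulation: the a_n/b_n expansion
coefficients via a downward-recurrence logarithmic derivative, the angular
amplitudes S1/S2 via the pi_n/tau_n recurrences, and the closed-form
scattering efficiency and asymmetry factor.  All quantities are for
unpolarized light; the relative refractive index may not be complex
(absorbing spheres are out of scope).
"""

from __future__ import annotations

import numpy as np

__all__ = ["mie_coefficients", "mie_intensity", "mie_g", "mie_qsca"]

# Above this size parameter the series length (and the downward-recurrence
# start) grows past what this implementation has been validated for.
_MAX_SIZE_PARAMETER = 300.0


def _n_terms(x: float) -> int:
    # Wiscombe series-truncation criterion.
    return int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(diameter, n_sphere, n_medium, wavelength):
    """Return the Mie expansion coefficients ``(a, b)`` and size parameter x.

    ``diameter`` and ``wavelength`` are in metres (wavelength in vacuum);
    the size parameter uses the wavelength in the medium.
    """
    if diameter <= 0 or wavelength <= 0:
        raise ValueError("diameter and wavelength must be positive")
    if n_sphere < 1 or n_medium < 1:
        raise ValueError("refractive indices must be >= 1")
    x = np.pi * diameter * n_medium / wavelength
    if x > _MAX_SIZE_PARAMETER:
        raise ValueError(
            f"size parameter {x:.1f} exceeds the series convergence budget "
            f"({_MAX_SIZE_PARAMETER:g})"
        )
    m = n_sphere / n_medium
    mx = m * x
    nmax = _n_terms(x)
    nmx = int(max(nmax, np.ceil(abs(mx))) + 16)

    # Logarithmic derivative D_n(mx) by downward recurrence.
    d = np.zeros(nmx + 1)
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    # Riccati-Bessel psi_n and chi_n by upward recurrence (psi_n[n] = psi_n).
    psi_n = np.empty(nmax + 1)
    chi_n = np.empty(nmax + 1)
    psi_n[0], chi_n[0] = np.sin(x), np.cos(x)
    pm1, cm1 = np.cos(x), -np.sin(x)
    for n in range(1, nmax + 1):
        psi_n[n] = (2 * n - 1) / x * psi_n[n - 1] - pm1
        chi_n[n] = (2 * n - 1) / x * chi_n[n - 1] - cm1
        pm1 = psi_n[n - 1]
        cm1 = chi_n[n - 1]
    xi_n = psi_n - 1j * chi_n

    a = np.empty(nmax, dtype=np.complex128)
    b = np.empty(nmax, dtype=np.complex128)
    for n in range(1, nmax + 1):
        da = d[n] / m + n / x
        db = d[n] * m + n / x
        a[n - 1] = (da * psi_n[n] - psi_n[n - 1]) / (da * xi_n[n] - xi_n[n - 1])
        b[n - 1] = (db * psi_n[n] - psi_n[n - 1]) / (db * xi_n[n] - xi_n[n - 1])
    return a, b, x


def mie_intensity(diameter, n_sphere, n_medium, wavelength, cos_theta):
    """Unpolarized angular intensity (|S1|² + |S2|²)/2 at ``cos_theta``.

    Unnormalized; callers converting to a phase-function density must divide
    by the integral over cosθ ∈ [−1, 1].
    """
    a, b, _x = mie_coefficients(diameter, n_sphere, n_medium, wavelength)
    mu = np.atleast_1d(np.asarray(cos_theta, dtype=float))
    nmax = a.size
    s1 = np.zeros(mu.shape, dtype=np.complex128)
    s2 = np.zeros(mu.shape, dtype=np.complex128)
    pi_nm1 = np.zeros_like(mu)  # pi_0
    pi_n = np.ones_like(mu)  # pi_1
    for n in range(1, nmax + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        f = (2 * n + 1) / (n * (n + 1))
        s1 += f * (a[n - 1] * pi_n + b[n - 1] * tau_n)
        s2 += f * (a[n - 1] * tau_n + b[n - 1] * pi_n)
        pi_np1 = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_np1
    return 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)


def mie_qsca(diameter, n_sphere, n_medium, wavelength):
    """Scattering efficiency Q_sca from the expansion coefficients."""
    a, b, x = mie_coefficients(diameter, n_sphere, n_medium, wavelength)
    n = np.arange(1, a.size + 1)
    return 2.0 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))


def mie_g(diameter, n_sphere, n_medium, wavelength):
    """Asymmetry factor ⟨cosθ⟩ from the closed-form coefficient series.

    Independent of any angular tabulation; used to cross-check phase
    functions built from :func:`mie_intensity`.
    """
    a, b, x = mie_coefficients(diameter, n_sphere, n_medium, wavelength)
    n = np.arange(1, a.size + 1)
    t1 = np.sum(
        n[:-1]
        * (n[:-1] + 2)
        / (n[:-1] + 1)
        * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:]))
    )
    t2 = np.sum((2 * n + 1) / (n * (n + 1)) * np.real(a * np.conj(b)))
    qsca = 2.0 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    return 4.0 / (x**2 * qsca) * (t1 + t2)
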