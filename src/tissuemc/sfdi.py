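"""Spatial-frequency-domain reflectance from spatially resolved profiles.

A radially symmetric per-area reflectance profile R(r) maps to the spatial
frequency domain through the zero-order Hankel transform,

    R(f) = 2π Σ_i R(r_i) J₀(2π f r_i) r_i Δr_i ,

evaluated over the annular bins with r_i the area-centroid radius of each
ring (this representative-radius choice keeps the quadrature accurate for
log-spaced rings near a steep source peak).  An x-resolved, y-integrated
profile that is symmetric about x = 0 (the tilted-camera configuration)
maps through the 1D cosine transform — symmetry makes the sine part
vanish.  Spatial-frequency-domain reflectance is unitless; at f = 0 both
transforms reduce to the total collected reflectance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import j0

__all__ = [
    "FrequencyGrid",
    "default_frequency_grid",
    "hankel_srr",
    "fourier_srr_x",
]


@dataclass
class FrequencyGrid:
    """Uniform nonnegative spatial-frequency grid (1/m)."""

    frequencies: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("need a 1D grid of >= 2 frequencies")
        if f[0] < 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be nonnegative and increasing")
        step = np.diff(f)
        if not np.allclose(step, step[0], rtol=1e-9, atol=0.0):
            raise ValueError("frequency grid must be uniform")
        self.frequencies = f

    @property
    def count(self) -> int:
        return self.frequencies.size


def default_frequency_grid(f_max: float = 0.8e3, count: int = 81) -> FrequencyGrid:
    """Uniform grid from 0 to ``f_max`` (default 0.8 mm⁻¹, 81 points)."""
    return FrequencyGrid(np.linspace(0.0, f_max, count))


def _ring_centroid_radii(r_edges: np.ndarray) -> np.ndarray:
    """Area-centroid radius of each annular ring,
    r_c = (2/3)(r₂³ − r₁³)/(r₂² − r₁²)."""
    r1 = r_edges[:-1]
    r2 = r_edges[1:]
    return (2.0 / 3.0) * (r2**3 - r1**3) / (r2**2 - r1**2)


def hankel_srr(srr: np.ndarray, r_edges: np.ndarray, freqs: FrequencyGrid):
    """Discrete zero-order Hankel transform of a per-area radial profile.

    ``srr`` (1/m²) is defined on rings ``r_edges``; the returned spectrum is
    unitless.  A ``truncation_flag`` is set when the requested band exceeds
    what the bin resolution can resolve (finest local spacing should stay
    below a quarter period of the highest frequency).
    """
    srr = np.asarray(srr, dtype=float)
    r_edges = np.asarray(r_edges, dtype=float)
    if srr.size != r_edges.size - 1:
        raise ValueError("srr must have one value per ring")
    rc = _ring_centroid_radii(r_edges)
    ring_area = math.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
    f = freqs.frequencies
    # 2π R(r_i) r_i Δr_i == R(r_i) × ring area
    weights = srr * ring_area
    spectrum = j0(2.0 * math.pi * np.outer(f, rc)) @ weights
    f_max = f[-1]
    max_dr = np.max(np.diff(r_edges))
    truncation_flag = bool(f_max > 0 and max_dr > 0.25 / f_max)
    return spectrum, truncation_flag


def fourier_srr_x(srr_x: np.ndarray, x_edges: np.ndarray, freqs: FrequencyGrid):
    """Cosine transform of an x-resolved, y-integrated per-length profile.

    The profile must be symmetric about x = 0 within noise; by symmetry the
    transform is real: R(f) = Σ_i R(x_i) cos(2π f x_i) Δx_i.
    """
    srr_x = np.asarray(srr_x, dtype=float)
    x_edges = np.asarray(x_edges, dtype=float)
    if srr_x.size != x_edges.size - 1:
        raise ValueError("srr_x must have one value per bin")
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    dx = np.diff(x_edges)
    f = freqs.frequencies
    spectrum = np.cos(2.0 * math.pi * np.outer(f, xc)) @ (srr_x * dx)
    f_max = f[-1]
    truncation_flag = bool(f_max > 0 and np.max(dx) > 0.25 / f_max)
    return spectrum, truncation_flag
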