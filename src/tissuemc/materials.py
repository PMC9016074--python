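"""Refractive-index dispersion models and interface optics.

Wavelengths are metres throughout; refractive indices are dimensionless.
The dispersion models shipped here are the ones commonly used for optical
phantom work: the Malitson Sellmeier fit for fused silica, the
Daimon–Masumura Sellmeier fit for water at 20 °C, and the Nikolov–Ivanov
Cauchy fit for polystyrene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Material",
    "SellmeierMaterial",
    "CauchyMaterial",
    "ConstantIndexMaterial",
    "InterfaceEvent",
    "fused_silica",
    "water",
    "polystyrene",
    "MATERIALS",
    "get_material",
    "refractive_index",
    "fresnel",
    "specular_launch_reflectance",
]


class Material:
    """A named medium with a deterministic wavelength → index mapping."""

    name: str
    wavelength_range: tuple[float, float]

    def refractive_index(self, wavelength: float) -> float:
        self._check_range(wavelength)
        return self._n(wavelength)

    def _n(self, wavelength: float) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def _check_range(self, wavelength: float) -> None:
        lo, hi = self.wavelength_range
        if not (lo <= wavelength <= hi):
            raise ValueError(
                f"wavelength {wavelength * 1e9:.1f} nm outside the validity "
                f"range [{lo * 1e9:.0f}, {hi * 1e9:.0f}] nm of material "
                f"'{self.name}'"
            )

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.name!r})"


class SellmeierMaterial(Material):
    """n²(λ) = 1 + Σ_i B_i λ² / (λ² − C_i), with λ in μm and C_i in μm²."""

    def __init__(self, name, b, c, wavelength_range, note=""):
        self.name = name
        self.b = tuple(float(v) for v in b)
        self.c = tuple(float(v) for v in c)
        self.wavelength_range = wavelength_range
        self.note = note

    def _n(self, wavelength: float) -> float:
        lam2 = (wavelength * 1e6) ** 2
        n2 = 1.0
        for b, c in zip(self.b, self.c):
            n2 += b * lam2 / (lam2 - c)
        return math.sqrt(n2)


class CauchyMaterial(Material):
    """n(λ) = a0 + a1/λ² + a2/λ⁴, with λ in μm."""

    def __init__(self, name, coefficients, wavelength_range, note=""):
        self.name = name
        self.coefficients = tuple(float(v) for v in coefficients)
        self.wavelength_range = wavelength_range
        self.note = note

    def _n(self, wavelength: float) -> float:
        lam = wavelength * 1e6
        a0, a1, a2 = self.coefficients
        return a0 + a1 / lam**2 + a2 / lam**4


class ConstantIndexMaterial(Material):
    """Wavelength-independent index, for media declared as ``{"n": value}``."""

    def __init__(self, n: float, name: str = "constant"):
        if n < 1.0:
            raise ValueError("refractive index must be >= 1")
        self.name = name
        self.n = float(n)
        self.wavelength_range = (0.0, math.inf)

    def _n(self, wavelength: float) -> float:
        return self.n


#: Fused silica, Malitson Sellmeier fit (validity 0.21–3.71 μm).
fused_silica = SellmeierMaterial(
    "fused_silica",
    b=(0.6961663, 0.4079426, 0.8974794),
    c=(0.0684043**2, 0.1162414**2, 9.896161**2),
    wavelength_range=(0.21e-6, 3.71e-6),
    note="Malitson Sellmeier fit",
)

#: Water at 20 °C, Daimon–Masumura Sellmeier fit (validity 0.18–1.13 μm).
#: The temperature variant (20 °C) is recorded here because measured values
#: at other temperatures differ in the fourth decimal.
water = SellmeierMaterial(
    "water",
    b=(5.684027565e-1, 1.726177391e-1, 2.086189578e-2, 1.130748688e-1),
    c=(5.101829712e-3, 1.821153936e-2, 2.620722293e-2, 1.069792721e1),
    wavelength_range=(0.18e-6, 1.13e-6),
    note="Daimon-Masumura Sellmeier fit at 20 C",
)

#: Polystyrene, Nikolov–Ivanov Cauchy fit (validity 0.44–1.05 μm).
polystyrene = CauchyMaterial(
    "polystyrene",
    coefficients=(1.5663, 0.00785, 0.000334),
    wavelength_range=(0.44e-6, 1.05e-6),
    note="Nikolov-Ivanov Cauchy fit",
)

MATERIALS: dict[str, Material] = {
    m.name: m for m in (fused_silica, water, polystyrene)
}


def get_material(spec) -> Material:
    """Resolve a material from a name, a ``{"n": value}`` mapping or a
    :class:`Material` instance."""
    if isinstance(spec, Material):
        return spec
    if isinstance(spec, str):
        try:
            return MATERIALS[spec]
        except KeyError:
            raise KeyError(
                f"unknown material '{spec}'; available: {sorted(MATERIALS)}"
            ) from None
    if isinstance(spec, dict) and "n" in spec:
        return ConstantIndexMaterial(spec["n"])
    if isinstance(spec, (int, float)):
        return ConstantIndexMaterial(float(spec))
    raise TypeError(f"cannot interpret {spec!r} as a material")


def refractive_index(material, wavelength: float) -> float:
    """Refractive index of ``material`` (name or instance) at ``wavelength`` (m)."""
    return get_material(material).refractive_index(wavelength)


@dataclass(frozen=True)
class InterfaceEvent:
    """Outcome of an unpolarized Fresnel interaction at a planar interface.

    ``cos_transmitted`` is ``None`` beyond the critical angle (total internal
    reflection), in which case ``reflectance`` is exactly 1.
    """

    n_incident: float
    n_transmitted: float
    cos_incident: float
    reflectance: float
    cos_transmitted: Optional[float]

    @property
    def total_internal_reflection(self) -> bool:
        return self.cos_transmitted is None


def fresnel(n1: float, n2: float, cos_i: float) -> InterfaceEvent:
    """Unpolarized Fresnel reflectance (average of s and p polarizations).

    ``cos_i`` is the cosine of the incidence angle w.r.t. the interface
    normal and must lie in (0, 1].  Beyond the critical angle the event
    carries reflectance 1 and no transmitted cosine.
    """
    if not (0.0 < cos_i <= 1.0):
        raise ValueError("cos_i must lie in (0, 1]")
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if n1 == n2:
        return InterfaceEvent(n1, n2, cos_i, 0.0, cos_i)
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) ** 2 * sin_i2
    if sin_t2 >= 1.0:
        return InterfaceEvent(n1, n2, cos_i, 1.0, None)
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
    rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    return InterfaceEvent(n1, n2, cos_i, 0.5 * (rs + rp), cos_t)


def specular_launch_reflectance(n_source: float, n_first: float) -> float:
    """Normal-incidence Fresnel reflectance R_sp at launch.

    A packet launched across the source–tissue index mismatch carries
    weight 1 − R_sp; the R_sp fraction is scored by the specular detector.
    """
    if n_source < 1.0 or n_first < 1.0:
        raise ValueError("refractive indices must be >= 1")
    return ((n_source - n_first) / (n_source + n_first)) ** 2
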