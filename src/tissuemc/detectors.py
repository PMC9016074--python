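"""Surface detectors, volumetric accumulators and the simulation result.

All accumulators store *raw* escaped/deposited weights next to their bin
edges; normalized views (per-area reflectance in 1/m², per-volume energy
deposition in 1/m³) are computed on demand and never replace the raw data.
Bins are half-open [low, high) with an upper-inclusive last bin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RadialDetector",
    "CartesianXDetector",
    "FiberArrayDetectorSpec",
    "FluenceGridSpec",
    "RadialAccumulator",
    "CartesianAccumulator",
    "FiberArrayAccumulator",
    "FluenceGrid",
    "SimResult",
    "linear_edges",
    "log_edges",
    "symmetric_log_edges",
    "na_to_cos_min",
    "score_exit",
    "normalize_radial",
    "normalize_fluence",
    "integrate_radial_to_fiber",
]


def linear_edges(r_max: float, n_bins: int, r_min: float = 0.0) -> np.ndarray:
    return np.linspace(r_min, r_max, n_bins + 1)


def log_edges(r_max: float, n_bins: int, r_first: float = 10e-6) -> np.ndarray:
    """Logarithmically spaced radial edges with a zero lower bound.

    The first edge sits at 0; the remaining ``n_bins`` edges are spaced
    logarithmically between ``r_first`` and ``r_max``.  ``r_first`` is an
    explicit parameter because "log-spaced from 0" admits several dialects.
    """
    if n_bins < 2 or not (0 < r_first < r_max):
        raise ValueError("need n_bins >= 2 and 0 < r_first < r_max")
    inner = np.geomspace(r_first, r_max, n_bins)
    return np.concatenate([[0.0], inner])


def symmetric_log_edges(x_max: float, n_bins: int, x_first: float = 10e-6) -> np.ndarray:
    """x-symmetric log-spaced edges on [−x_max, x_max] (n_bins must be even)."""
    if n_bins % 2:
        raise ValueError("n_bins must be even for a symmetric layout")
    half = log_edges(x_max, n_bins // 2, x_first)
    return np.concatenate([-half[::-1][:-1], half])


def na_to_cos_min(na: float, n_medium: float = 1.0) -> float:
    """Minimum direction cosine equivalent to a numerical aperture.

    The NA is specified in air; in a medium of index n the acceptance cone
    satisfies sinθ ≤ NA/n.
    """
    s = min(na / n_medium, 1.0)
    return math.sqrt(1.0 - s * s)


# ---------------------------------------------------------------------------
# detector specifications
# ---------------------------------------------------------------------------

@dataclass
class RadialDetector:
    """Annular-ring detector on the top or bottom surface."""

    r_edges: np.ndarray
    cos_min: float = 0.0

    def __post_init__(self):
        self.r_edges = np.asarray(self.r_edges, dtype=float)
        if self.r_edges.ndim != 1 or self.r_edges.size < 2:
            raise ValueError("r_edges must be a 1D array of >= 2 edges")
        if np.any(np.diff(self.r_edges) <= 0):
            raise ValueError("r_edges must be strictly increasing")
        if not 0.0 <= self.cos_min <= 1.0:
            raise ValueError("cos_min must lie in [0, 1]")

    @classmethod
    def from_na(cls, r_edges, na: float, n_exterior: float = 1.0):
        return cls(r_edges, na_to_cos_min(na, n_exterior))


@dataclass
class CartesianXDetector:
    """x-resolved, y-integrated detector, optionally about a tilted axis.

    The acceptance axis lies in the x–z plane, tilted by ``tilt_deg`` from
    the surface normal; exits within ``acceptance_deg`` of the axis are
    scored.
    """

    x_edges: np.ndarray
    tilt_deg: float = 0.0
    acceptance_deg: float = 90.0

    def __post_init__(self):
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        if np.any(np.diff(self.x_edges) <= 0):
            raise ValueError("x_edges must be strictly increasing")

    @property
    def axis(self) -> tuple[float, float]:
        """(x, z) components of the outward acceptance axis (z < 0 is up)."""
        t = math.radians(self.tilt_deg)
        return math.sin(t), -math.cos(t)

    @property
    def cos_min(self) -> float:
        return math.cos(math.radians(self.acceptance_deg))


@dataclass
class FiberArrayDetectorSpec:
    """Detector fibers identified by core centre, radius and NA."""

    centers: np.ndarray  # (F, 2)
    core_radius: float
    na: float
    n_medium: float = 1.0  # index of the medium the exit direction lives in

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.core_radius <= 0:
            raise ValueError("core radius must be positive")
        for i in range(len(self.centers)):
            for j in range(i + 1, len(self.centers)):
                if np.hypot(*(self.centers[i] - self.centers[j])) < 2 * self.core_radius:
                    raise ValueError("detector fibers overlap")

    @property
    def cos_min(self) -> float:
        return na_to_cos_min(self.na, self.n_medium)


@dataclass
class FluenceGridSpec:
    """3D Cartesian accumulator specification.

    ``mode`` selects what the normalized view means: raw deposits are
    always absorbed weight; in ``"fluence"`` mode the normalized view is
    additionally divided by the local μa.
    """

    origin: tuple[float, float, float]
    voxel_size: tuple[float, float, float]
    shape: tuple[int, int, int]
    mode: str = "energy_deposition"

    def __post_init__(self):
        if self.mode not in ("energy_deposition", "fluence"):
            raise ValueError("mode must be 'energy_deposition' or 'fluence'")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(int(s) < 1 for s in self.shape):
            raise ValueError("shape entries must be >= 1")
        self.shape = tuple(int(s) for s in self.shape)
        self.origin = tuple(float(v) for v in self.origin)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)


# ---------------------------------------------------------------------------
# accumulators (spec + raw weights + counters)
# ---------------------------------------------------------------------------

class RadialAccumulator:
    def __init__(self, spec: RadialDetector, n_reference: int = 0):
        self.spec = spec
        self.raw = np.zeros(spec.r_edges.size - 1)
        self.discarded = 0.0  # failed the acceptance test
        self.overflow = 0.0   # outside the edge span
        self.n_reference = int(n_reference)

    @property
    def r_edges(self):
        return self.spec.r_edges

    def ring_areas(self) -> np.ndarray:
        e = self.spec.r_edges
        return math.pi * (e[1:] ** 2 - e[:-1] ** 2)

    def normalized(self) -> np.ndarray:
        """Per-area profile: raw / (N · ring area), units 1/m²."""
        return normalize_radial(self)

    def score(self, position, direction, weight: float) -> bool:
        """Score one escaping packet (reference implementation of the
        kernel's scoring path).  ``direction`` is the exit direction in the
        exterior medium; the acceptance cosine is its |z| component."""
        if abs(direction[2]) < self.spec.cos_min:
            self.discarded += weight
            return False
        r = math.hypot(position[0], position[1])
        e = self.spec.r_edges
        if r < e[0] or r > e[-1]:
            self.overflow += weight
            return False
        i = min(int(np.searchsorted(e, r, side="right")) - 1, e.size - 2)
        self.raw[i] += weight
        return True


class CartesianAccumulator:
    def __init__(self, spec: CartesianXDetector, n_reference: int = 0):
        self.spec = spec
        self.raw = np.zeros(spec.x_edges.size - 1)
        self.discarded = 0.0
        self.overflow = 0.0
        self.n_reference = int(n_reference)

    def normalized(self) -> np.ndarray:
        """Per-length profile raw / (N · Δx), units 1/m (y-integrated)."""
        if self.n_reference <= 0:
            raise ValueError("n_reference must be positive for normalization")
        return self.raw / (self.n_reference * np.diff(self.spec.x_edges))

    def score(self, position, direction, weight: float) -> bool:
        ax, az = self.spec.axis
        if direction[0] * ax + direction[2] * az < self.spec.cos_min:
            self.discarded += weight
            return False
        e = self.spec.x_edges
        x = position[0]
        if x < e[0] or x > e[-1]:
            self.overflow += weight
            return False
        i = min(int(np.searchsorted(e, x, side="right")) - 1, e.size - 2)
        self.raw[i] += weight
        return True


class FiberArrayAccumulator:
    def __init__(self, spec: FiberArrayDetectorSpec, n_reference: int = 0):
        self.spec = spec
        self.raw = np.zeros(len(spec.centers))
        self.discarded = 0.0
        self.n_reference = int(n_reference)

    def reflectance(self) -> np.ndarray:
        """Per-fiber collected fraction, relative to N."""
        if self.n_reference <= 0:
            raise ValueError("n_reference must be positive for normalization")
        return self.raw / self.n_reference

    def score(self, position, direction, weight: float) -> bool:
        cos_min = self.spec.cos_min
        for i, (fx, fy) in enumerate(self.spec.centers):
            if (position[0] - fx) ** 2 + (position[1] - fy) ** 2 <= self.spec.core_radius**2:
                if abs(direction[2]) >= cos_min:
                    self.raw[i] += weight
                    return True
                self.discarded += weight
                return False
        return False


class FluenceGrid:
    """3D deposited-weight accumulator with on-demand normalization."""

    def __init__(self, spec: FluenceGridSpec, n_reference: int = 0):
        self.spec = spec
        self.raw = np.zeros(spec.shape)
        self.n_reference = int(n_reference)

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spec.voxel_size
        return dx * dy * dz

    def z_centers(self) -> np.ndarray:
        oz = self.spec.origin[2]
        dz = self.spec.voxel_size[2]
        return oz + (np.arange(self.spec.shape[2]) + 0.5) * dz

    def normalized(self, mua_map: Optional[np.ndarray] = None) -> np.ndarray:
        return normalize_fluence(self, mua_map)


def score_exit(accumulator, position, direction, weight: float) -> bool:
    """Score one escaping packet on any surface accumulator.

    The weight lands in the geometric bin iff the exit direction passes the
    acceptance test; otherwise it is counted as discarded (or overflow when
    the position lies outside all bins)."""
    return accumulator.score(position, direction, weight)


def normalize_radial(acc: RadialAccumulator) -> np.ndarray:
    """Spatially resolved reflectance/transmittance relative to N and per
    annular ring area: raw_i / (N · π(r_{i+1}² − r_i²)), units 1/m²."""
    if acc.n_reference <= 0:
        raise ValueError("n_reference must be positive for normalization")
    return acc.raw / (acc.n_reference * acc.ring_areas())


def normalize_fluence(grid: FluenceGrid, mua_map: Optional[np.ndarray] = None) -> np.ndarray:
    """Energy deposition relative to N and per voxel volume (1/m³).

    In ``"fluence"`` mode the deposition is further divided by the local
    absorption coefficient (raw deposits are absorbed weight, and fluence
    φ = deposition/μa); voxels with μa = 0 are returned as NaN.
    """
    if grid.n_reference <= 0:
        raise ValueError("n_reference must be positive for normalization")
    dep = grid.raw / (grid.n_reference * grid.voxel_volume)
    if grid.spec.mode == "fluence":
        if mua_map is None:
            raise ValueError("fluence mode requires a mua map on the grid")
        with np.errstate(divide="ignore", invalid="ignore"):
            dep = np.where(mua_map > 0, dep / mua_map, np.nan)
    return dep


# ---------------------------------------------------------------------------
# ring–disc overlap integration
# ---------------------------------------------------------------------------

def _circle_overlap_area(r: float, a: float, d: float) -> float:
    """Intersection area of origin-centred circle radius r with a disc of
    radius a centred at distance d."""
    if r <= 0 or a <= 0:
        return 0.0
    if d >= r + a:
        return 0.0
    if d <= abs(r - a):
        rr = min(r, a)
        return math.pi * rr * rr
    alpha = math.acos((d * d + r * r - a * a) / (2 * d * r))
    beta = math.acos((d * d + a * a - r * r) / (2 * d * a))
    return (r * r * (alpha - math.sin(2 * alpha) / 2)
            + a * a * (beta - math.sin(2 * beta) / 2))


def integrate_radial_to_fiber(srr: np.ndarray, r_edges: np.ndarray,
                              sds: float, core_radius: float) -> float:
    """Integrate a per-area radial profile over an off-axis fiber core.

    ``srr`` is the normalized profile (1/m²) on rings ``r_edges``; the
    detector core (radius ``core_radius``) is centred ``sds`` away from the
    source axis.  Exact ring–disc overlap areas are used, so a uniform
    profile c integrates to c·π·core_radius².
    """
    srr = np.asarray(srr, dtype=float)
    r_edges = np.asarray(r_edges, dtype=float)
    if srr.size != r_edges.size - 1:
        raise ValueError("srr must have one value per ring")
    if sds + core_radius > r_edges[-1] + 1e-15:
        raise ValueError("fiber footprint extends beyond the last bin edge")
    total = 0.0
    for i in range(srr.size):
        a_out = _circle_overlap_area(r_edges[i + 1], core_radius, sds)
        a_in = _circle_overlap_area(r_edges[i], core_radius, sds)
        total += srr[i] * (a_out - a_in)
    return total


# ---------------------------------------------------------------------------
# simulation result container
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """All accumulators of one run plus launch count and normalization
    metadata; serializable to HDF5 or NPZ."""

    n_packets: int
    seed: int
    specular: float
    reflectance: float
    transmittance: float
    absorbed: float
    absorbed_surface: float = 0.0
    killed: float = 0.0
    lateral: float = 0.0
    r_sumsq: float = 0.0
    t_sumsq: float = 0.0
    top: Optional[RadialAccumulator] = None
    bottom: Optional[RadialAccumulator] = None
    cartesian: Optional[CartesianAccumulator] = None
    fibers: Optional[FiberArrayAccumulator] = None
    fluence: Optional[FluenceGrid] = None
    trace: object = None
    trace_dropped: int = 0
    config_echo: Optional[dict] = None

    @property
    def total_reflectance(self) -> float:
        return self.reflectance / self.n_packets

    @property
    def total_transmittance(self) -> float:
        return self.transmittance / self.n_packets

    @property
    def specular_reflectance(self) -> float:
        return self.specular / self.n_packets

    @property
    def absorbed_fraction(self) -> float:
        return self.absorbed / self.n_packets

    def reflectance_stderr(self) -> float:
        """Monte Carlo standard error of total_reflectance."""
        n = self.n_packets
        mean = self.reflectance / n
        var = max(self.r_sumsq / n - mean * mean, 0.0)
        return math.sqrt(var / n)

    def transmittance_stderr(self) -> float:
        n = self.n_packets
        mean = self.transmittance / n
        var = max(self.t_sumsq / n - mean * mean, 0.0)
        return math.sqrt(var / n)

    def energy_balance_residual(self) -> float:
        """1 − (specular + R + T + A + A_surface + lateral)/N.

        Zero in expectation; exactly zero (to roundoff) when roulette is
        disabled.  With roulette enabled the residual is the net of killed
        weight against survivor multiplication, a zero-mean statistic whose
        spread is of order sqrt(killed · m · threshold)/N.  ``killed`` is a
        diagnostic counter and is deliberately not part of the sum — the
        multiplied weight of surviving packets already lands in the other
        accumulators and balances it in expectation.
        """
        total = (self.specular + self.reflectance + self.transmittance
                 + self.absorbed + self.absorbed_surface + self.lateral)
        return 1.0 - total / self.n_packets

    def roulette_residual_sigma(self, threshold: float = 1e-4,
                                m: float = 10.0) -> float:
        """Upper bound on the roulette-induced energy-balance fluctuation.

        K roulette events at weights w ≤ threshold have variance
        K·(m−1)·w̄²; expressed through the killed total (≈ K·w̄·(1−1/m))
        this is bounded by killed · m · threshold.
        """
        if self.killed <= 0:
            return 0.0
        return math.sqrt(self.killed * m * threshold) / self.n_packets

    # -- serialization ------------------------------------------------------

    def _payload(self) -> dict:
        data = {
            "n_packets": self.n_packets,
            "seed": self.seed,
            "specular": self.specular,
            "reflectance": self.reflectance,
            "transmittance": self.transmittance,
            "absorbed": self.absorbed,
            "absorbed_surface": self.absorbed_surface,
            "killed": self.killed,
            "lateral": self.lateral,
            "r_sumsq": self.r_sumsq,
            "t_sumsq": self.t_sumsq,
            "trace_dropped": self.trace_dropped,
        }
        arrays = {}
        if self.top is not None:
            arrays["top/raw"] = self.top.raw
            arrays["top/r_edges"] = self.top.r_edges
            data["top/cos_min"] = self.top.spec.cos_min
            data["top/discarded"] = self.top.discarded
            data["top/overflow"] = self.top.overflow
        if self.bottom is not None:
            arrays["bottom/raw"] = self.bottom.raw
            arrays["bottom/r_edges"] = self.bottom.r_edges
            data["bottom/cos_min"] = self.bottom.spec.cos_min
            data["bottom/discarded"] = self.bottom.discarded
            data["bottom/overflow"] = self.bottom.overflow
        if self.cartesian is not None:
            arrays["cartesian/raw"] = self.cartesian.raw
            arrays["cartesian/x_edges"] = self.cartesian.spec.x_edges
            data["cartesian/tilt_deg"] = self.cartesian.spec.tilt_deg
            data["cartesian/acceptance_deg"] = self.cartesian.spec.acceptance_deg
        if self.fibers is not None:
            arrays["fibers/raw"] = self.fibers.raw
            arrays["fibers/centers"] = self.fibers.spec.centers
            data["fibers/core_radius"] = self.fibers.spec.core_radius
            data["fibers/na"] = self.fibers.spec.na
        if self.fluence is not None:
            arrays["fluence/raw"] = self.fluence.raw
            data["fluence/origin"] = list(self.fluence.spec.origin)
            data["fluence/voxel_size"] = list(self.fluence.spec.voxel_size)
            data["fluence/mode"] = self.fluence.spec.mode
        return {"scalars": data, "arrays": arrays}

    def save_npz(self, path):
        p = self._payload()
        np.savez_compressed(
            path,
            __scalars__=json.dumps(p["scalars"]),
            __config__=json.dumps(self.config_echo or {}),
            **{k.replace("/", "__"): v for k, v in p["arrays"].items()},
        )

    def save_hdf5(self, path):
        import h5py

        p = self._payload()
        with h5py.File(path, "w") as f:
            for k, v in p["scalars"].items():
                f.attrs[k] = v
            f.attrs["config_json"] = json.dumps(self.config_echo or {})
            for k, v in p["arrays"].items():
                f.create_dataset(k, data=v)

    @staticmethod
    def load_scalars(path) -> dict:
        """Read back the scalar summary of a stored result (either format)."""
        path = str(path)
        if path.endswith(".npz"):
            with np.load(path, allow_pickle=False) as f:
                return json.loads(str(f["__scalars__"]))
        import h5py

        with h5py.File(path, "r") as f:
            return {k: (v.item() if hasattr(v, "item") else v)
                    for k, v in f.attrs.items() if k != "config_json"}
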