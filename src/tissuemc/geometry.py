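"""Sample geometry (layer stacks and voxel volumes), photon sources,
surface layouts and the photon-packet state.

Coordinate convention: z increases downward into the sample; the top
surface is the plane z = 0 and the source axis is the z axis.  Layer
intervals and voxels are half-open [low, high): a packet sitting exactly
on a boundary belongs to the deeper (greater-index) region.  All lengths
are metres, all coefficients 1/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .materials import fresnel, specular_launch_reflectance
from .phase import PhaseFunction, HenyeyGreenstein

__all__ = [
    "Layer",
    "BoundingMedium",
    "LayerStack",
    "VoxelMaterial",
    "VoxelVolume",
    "PhotonPacket",
    "Pencil",
    "LineSource",
    "IsotropicPoint",
    "GaussianBeam",
    "UniformBeam",
    "FiberSource",
    "RectangularSource",
    "FiberProbeLayout",
    "six_around_one_layout",
    "linear_array_layout",
    "locate_layer",
    "voxel_at",
    "launch",
    "surface_interact",
]


# ---------------------------------------------------------------------------
# Layered geometry
# ---------------------------------------------------------------------------

@dataclass
class Layer:
    """An interior layer: absorption/scattering coefficients (1/m),
    refractive index, thickness (m; may be ``inf`` for the last interior
    layer) and a scattering phase function."""

    mua: float
    mus: float
    n: float
    thickness: float
    phase_function: Optional[PhaseFunction] = None

    def __post_init__(self):
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be nonnegative")
        if not self.thickness > 0:
            raise ValueError("layer thickness must be positive")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.mus > 0 and self.phase_function is None:
            raise ValueError("a scattering layer needs a phase function")


@dataclass
class BoundingMedium:
    """Top/bottom bounding half-space; supplies only a refractive index."""

    n: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")


class LayerStack:
    """Ordered top-to-bottom stack; first and last entries are bounding
    media, the rest are interior layers starting at z = 0."""

    def __init__(self, entries: Sequence):
        if len(entries) < 3:
            raise ValueError("a stack needs two bounding media and >= 1 layer")
        if not isinstance(entries[0], BoundingMedium) or not isinstance(
            entries[-1], BoundingMedium
        ):
            raise TypeError("first and last stack entries must be bounding media")
        interior = list(entries[1:-1])
        for i, layer in enumerate(interior):
            if not isinstance(layer, Layer):
                raise TypeError("interior entries must be Layer instances")
            if math.isinf(layer.thickness) and i != len(interior) - 1:
                raise ValueError("only the last interior layer may be infinite")
        self.entries = list(entries)

    @classmethod
    def from_layers(cls, layers: Sequence[Layer], n_above: float, n_below: float):
        return cls([BoundingMedium(n_above), *layers, BoundingMedium(n_below)])

    @property
    def layers(self) -> list[Layer]:
        return self.entries[1:-1]

    @property
    def n_above(self) -> float:
        return self.entries[0].n

    @property
    def n_below(self) -> float:
        return self.entries[-1].n

    def interfaces(self) -> np.ndarray:
        """z coordinates of the interior interfaces, starting at 0."""
        t = np.array([layer.thickness for layer in self.layers])
        return np.concatenate([[0.0], np.cumsum(t)])

    @property
    def total_thickness(self) -> float:
        return float(sum(layer.thickness for layer in self.layers))

    def __len__(self):
        return len(self.entries)


def locate_layer(stack: LayerStack, z: float) -> int:
    """Index (into ``stack.entries``) of the region containing depth ``z``.

    Intervals are half-open [z_top, z_bottom); z < 0 is the top bounding
    medium (index 0), z at or below the last interface is the bottom
    bounding medium (last index).
    """
    if z < 0:
        return 0
    edges = stack.interfaces()  # length n_layers + 1
    idx = int(np.searchsorted(edges[1:], z, side="right"))
    if idx >= len(stack.layers):
        if math.isinf(stack.layers[-1].thickness):
            return len(stack.entries) - 2
        return len(stack.entries) - 1
    return idx + 1


# ---------------------------------------------------------------------------
# Voxel geometry
# ---------------------------------------------------------------------------

@dataclass
class VoxelMaterial:
    """Optical properties assigned to one label of a voxel volume."""

    mua: float
    mus: float
    n: float
    phase_function: Optional[PhaseFunction] = None

    def __post_init__(self):
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be nonnegative")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.mus > 0 and self.phase_function is None:
            raise ValueError("a scattering material needs a phase function")


class VoxelVolume:
    """A labeled 3D volume: integer labels plus a label → material table.

    The volume occupies ``origin + [0, shape*voxel_size)`` with half-open
    voxels; the top sample surface is the z = origin_z face (origin_z is 0
    unless stated otherwise).  Media above/below the volume supply only a
    refractive index, as in the layered geometry.
    """

    def __init__(self, labels, voxel_size, materials, origin=(None, None, 0.0),
                 n_above=1.0, n_below=1.0):
        labels = np.ascontiguousarray(labels, dtype=np.int32)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3D integer array")
        voxel_size = tuple(float(v) for v in np.broadcast_to(voxel_size, (3,)))
        if any(v <= 0 for v in voxel_size):
            raise ValueError("voxel sizes must be positive")
        present = set(np.unique(labels).tolist())
        missing = present - set(materials)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no material entry")
        self.labels = labels
        self.voxel_size = voxel_size
        self.materials = dict(materials)
        nx, ny, nz = labels.shape
        ox = -0.5 * nx * voxel_size[0] if origin[0] is None else float(origin[0])
        oy = -0.5 * ny * voxel_size[1] if origin[1] is None else float(origin[1])
        oz = float(origin[2]) if origin[2] is not None else 0.0
        self.origin = (ox, oy, oz)
        self.n_above = float(n_above)
        self.n_below = float(n_below)

    @property
    def shape(self):
        return self.labels.shape

    def extent(self):
        ox, oy, oz = self.origin
        nx, ny, nz = self.shape
        dx, dy, dz = self.voxel_size
        return ((ox, ox + nx * dx), (oy, oy + ny * dy), (oz, oz + nz * dz))


def voxel_at(volume: VoxelVolume, position):
    """Voxel index triple and material at ``position``.

    Returns ``None`` when the position lies outside the bounding box
    (half-open on the positive faces) — an escape signal, not an error.
    """
    x, y, z = position
    (x0, x1), (y0, y1), (z0, z1) = volume.extent()
    if not (x0 <= x < x1 and y0 <= y < y1 and z0 <= z < z1):
        return None
    dx, dy, dz = volume.voxel_size
    # the 1e-9-voxel nudge keeps exact corners (which round off in the
    # division) on the half-open side they belong to
    ijk = (
        int(math.floor((x - x0) / dx + 1e-9)),
        int(math.floor((y - y0) / dy + 1e-9)),
        int(math.floor((z - z0) / dz + 1e-9)),
    )
    ijk = tuple(min(i, n - 1) for i, n in zip(ijk, volume.shape))
    return ijk, volume.materials[int(volume.labels[ijk])]


# ---------------------------------------------------------------------------
# Photon packet
# ---------------------------------------------------------------------------

@dataclass
class PhotonPacket:
    """The transported entity: position, unit direction, statistical weight,
    current region and an alive flag."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    region: int = 1
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------

@dataclass
class Pencil:
    """Infinitely narrow beam entering at the origin along +z."""


#: The paper-style "line source": an infinitely narrow perpendicular line,
#: i.e. the pencil beam.
LineSource = Pencil


@dataclass
class IsotropicPoint:
    """Isotropic emitter at an interior point."""

    position: tuple[float, float, float]


@dataclass
class GaussianBeam:
    """Collimated beam with a Gaussian radial profile of the given FWHM."""

    fwhm: float

    def __post_init__(self):
        if not self.fwhm > 0:
            raise ValueError("FWHM must be positive")

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class UniformBeam:
    """Collimated beam, uniform over a disc of the given diameter."""

    diameter: float

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")


@dataclass
class RectangularSource:
    """Collimated beam, uniform over a rectangle width_x × width_y."""

    width_x: float
    width_y: float

    def __post_init__(self):
        if not (self.width_x > 0 and self.width_y > 0):
            raise ValueError("widths must be positive")


@dataclass
class FiberSource:
    """Multimode fiber butt-coupled to the surface at ``position``.

    Launch positions are uniform over the core disc; directions are uniform
    over the solid angle of the acceptance cone defined by the NA (specified
    in air, converted to the in-core cone via sinθ_core = NA/n_core) and are
    refracted through the core–sample interface.
    """

    core_diameter: float
    cladding_diameter: float
    na: float
    n_core: float
    position: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not 0 < self.na <= 1:
            raise ValueError("NA must lie in (0, 1]")
        if not 0 < self.core_diameter < self.cladding_diameter:
            raise ValueError("need 0 < core diameter < cladding diameter")
        if self.n_core < 1:
            raise ValueError("core index must be >= 1")

    @property
    def cos_max_core(self) -> float:
        s = min(self.na / self.n_core, 1.0)
        return math.sqrt(1.0 - s * s)


# ---------------------------------------------------------------------------
# Surface layouts
# ---------------------------------------------------------------------------

@dataclass
class FiberProbeLayout:
    """Tip of a fiber-optic probe pressed onto the top surface.

    Packets reaching z = 0 under a fiber core undergo a Fresnel decision
    against the core index (transmitted packets leave into that fiber);
    under the metal housing (inside the tip radius, outside all cores) they
    reflect back with the housing reflectivity; outside the tip the plain
    sample–exterior boundary applies.
    """

    fiber_positions: np.ndarray  # (F, 2) core centres on the surface
    core_radius: float
    cladding_radius: float
    na: float
    n_core: float
    tip_radius: float
    reflectivity: float = 0.6
    n_outside: float = 1.0
    reflection: str = "specular"  # or "lambertian"

    def __post_init__(self):
        self.fiber_positions = np.atleast_2d(
            np.asarray(self.fiber_positions, dtype=float)
        )
        if not 0 <= self.reflectivity <= 1:
            raise ValueError("housing reflectivity must lie in [0, 1]")
        if not 0 < self.core_radius <= self.cladding_radius:
            raise ValueError("need 0 < core radius <= cladding radius")
        if self.reflection not in ("specular", "lambertian"):
            raise ValueError("reflection must be 'specular' or 'lambertian'")
        # fibers must not overlap
        pos = self.fiber_positions
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = float(np.hypot(*(pos[i] - pos[j])))
                if d < 2 * self.cladding_radius - 1e-12:
                    raise ValueError("fibers overlap in the layout")

    @property
    def cos_min_core(self) -> float:
        """Minimum in-core cosine accepted by the fiber NA (NA in air)."""
        s = min(self.na / self.n_core, 1.0)
        return math.sqrt(1.0 - s * s)


def six_around_one_layout(core_diameter=200e-6, cladding_diameter=220e-6,
                          na=0.22, n_core=1.462, tip_radius=None,
                          reflectivity=0.6) -> FiberProbeLayout:
    """Tightly packed six-around-one probe: the centre-to-centre pitch (the
    smallest source–detector separation) equals the cladding diameter."""
    pitch = cladding_diameter
    centers = [(0.0, 0.0)]
    for k in range(6):
        a = k * math.pi / 3.0
        centers.append((pitch * math.cos(a), pitch * math.sin(a)))
    if tip_radius is None:
        tip_radius = 3.0 * cladding_diameter
    return FiberProbeLayout(
        np.array(centers), core_diameter / 2, cladding_diameter / 2,
        na, n_core, tip_radius, reflectivity,
    )


def linear_array_layout(n_fibers=6, core_diameter=200e-6,
                        cladding_diameter=220e-6, na=0.22, n_core=1.462,
                        tip_radius=None, reflectivity=0.6) -> FiberProbeLayout:
    """Tightly packed linear array along x; fiber 0 doubles as the source."""
    if n_fibers < 1:
        raise ValueError("need at least one fiber")
    pitch = cladding_diameter
    centers = [(k * pitch, 0.0) for k in range(n_fibers)]
    if tip_radius is None:
        tip_radius = (n_fibers + 1) * cladding_diameter
    return FiberProbeLayout(
        np.array(centers), core_diameter / 2, cladding_diameter / 2,
        na, n_core, tip_radius, reflectivity,
    )


# ---------------------------------------------------------------------------
# Launch and surface interaction (reference, single-packet implementations;
# the transport kernels inline the identical logic)
# ---------------------------------------------------------------------------

def _first_interior_n(geometry) -> float:
    if isinstance(geometry, LayerStack):
        return geometry.layers[0].n
    # voxel: index of the top-left voxel column's material
    mat = geometry.materials[int(geometry.labels[0, 0, 0])]
    return mat.n


def _n_above(geometry) -> float:
    return geometry.n_above


def launch(source, geometry, rng: np.random.Generator):
    """Launch one photon packet; returns ``(PhotonPacket, specular_weight)``.

    Collimated sources enter through the top surface at normal incidence and
    lose the normal-incidence Fresnel fraction to the specular detector.
    """
    n1 = _first_interior_n(geometry)
    if isinstance(source, (Pencil, GaussianBeam, UniformBeam, RectangularSource)):
        if isinstance(source, Pencil):
            x = y = 0.0
        elif isinstance(source, GaussianBeam):
            x, y = rng.normal(0.0, source.sigma, size=2)
        elif isinstance(source, UniformBeam):
            r = 0.5 * source.diameter * math.sqrt(rng.random())
            a = 2.0 * math.pi * rng.random()
            x, y = r * math.cos(a), r * math.sin(a)
        else:
            x = (rng.random() - 0.5) * source.width_x
            y = (rng.random() - 0.5) * source.width_y
        rsp = specular_launch_reflectance(_n_above(geometry), n1)
        packet = PhotonPacket(
            position=np.array([x, y, 0.0]),
            direction=np.array([0.0, 0.0, 1.0]),
            weight=1.0 - rsp,
        )
        return packet, rsp
    if isinstance(source, IsotropicPoint):
        uz = 2.0 * rng.random() - 1.0
        a = 2.0 * math.pi * rng.random()
        s = math.sqrt(max(0.0, 1.0 - uz * uz))
        packet = PhotonPacket(
            position=np.asarray(source.position, dtype=float),
            direction=np.array([s * math.cos(a), s * math.sin(a), uz]),
            weight=1.0,
        )
        return packet, 0.0
    if isinstance(source, FiberSource):
        r = 0.5 * source.core_diameter * math.sqrt(rng.random())
        a = 2.0 * math.pi * rng.random()
        x = source.position[0] + r * math.cos(a)
        y = source.position[1] + r * math.sin(a)
        # uniform over the solid angle of the in-core acceptance cone
        ct = 1.0 - rng.random() * (1.0 - source.cos_max_core)
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        b = 2.0 * math.pi * rng.random()
        ev = fresnel(source.n_core, n1, ct)
        rsp = ev.reflectance
        scale = source.n_core / n1
        ux, uy = st * math.cos(b) * scale, st * math.sin(b) * scale
        uz = ev.cos_transmitted if ev.cos_transmitted is not None else ct
        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
        packet = PhotonPacket(
            position=np.array([x, y, 0.0]),
            direction=np.array([ux, uy, uz]) / norm,
            weight=1.0 - rsp,
        )
        return packet, rsp
    raise TypeError(f"unsupported source kind: {type(source).__name__}")


def surface_interact(layout: Optional[FiberProbeLayout], packet: PhotonPacket,
                     rng: np.random.Generator, n_tissue: float):
    """Apply the surface layout to a packet sitting on z = 0 moving upward.

    Returns a ``(packet, outcome)`` pair where ``outcome`` is one of
    ``"fiber:<index>"`` (left into a detector fiber), ``"escaped"`` (left
    through a plain boundary), ``"reflected"`` (back into the sample) or
    ``"terminated"``.
    """
    x, y = packet.position[0], packet.position[1]
    ux, uy, uz = packet.direction
    if uz >= 0:
        raise ValueError("packet must move upward (uz < 0) at the top surface")
    ci = -uz

    def plain(n_out):
        ev = fresnel(n_tissue, n_out, ci)
        if ev.cos_transmitted is None or rng.random() < ev.reflectance:
            packet.direction[2] = -uz
            return packet, "reflected"
        scale = n_tissue / n_out
        packet.direction[:] = (ux * scale, uy * scale, -ev.cos_transmitted)
        packet.direction /= np.linalg.norm(packet.direction)
        return packet, "escaped"

    if layout is None:
        return plain(1.0)

    for i, (fx, fy) in enumerate(layout.fiber_positions):
        if (x - fx) ** 2 + (y - fy) ** 2 <= layout.core_radius**2:
            ev = fresnel(n_tissue, layout.n_core, ci)
            if ev.cos_transmitted is None or rng.random() < ev.reflectance:
                packet.direction[2] = -uz
                return packet, "reflected"
            scale = n_tissue / layout.n_core
            packet.direction[:] = (ux * scale, uy * scale, -ev.cos_transmitted)
            packet.direction /= np.linalg.norm(packet.direction)
            return packet, f"fiber:{i}"
    if x * x + y * y <= layout.tip_radius**2:
        packet.weight *= layout.reflectivity
        if packet.weight <= 0.0:
            packet.alive = False
            return packet, "terminated"
        if layout.reflection == "specular":
            packet.direction[2] = -uz
        else:  # lambertian: cosine-weighted hemisphere into the sample
            czz = math.sqrt(rng.random())
            szz = math.sqrt(1.0 - czz * czz)
            a = 2.0 * math.pi * rng.random()
            packet.direction[:] = (szz * math.cos(a), szz * math.sin(a), czz)
        return packet, "reflected"
    return plain(layout.n_outside)
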