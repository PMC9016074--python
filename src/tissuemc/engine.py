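"""The Monte Carlo propagation loop for layered and voxelated samples.

``run`` dispatches on the geometry: a :class:`~tissuemc.geometry.LayerStack`
is propagated by the layered engine (hop–drop–spin with Fresnel decisions
at layer interfaces, Albedo–Weight deposition), a
:class:`~tissuemc.geometry.VoxelVolume` by the voxel engine (steps clipped
at every sample-voxel face; Albedo–Weight, Albedo–Reject or Microscopic
Beer–Lambert deposition).  Both engines share the RNG streams, phase
function LUT sampling, detectors and normalization conventions.

This module also exposes the elementary transport operations
(:func:`sample_step`, :func:`deposit_aw`, :func:`deposit_mbl`,
:func:`ar_decide`, :func:`scatter_direction`, :func:`roulette`) as plain
Python reference implementations; the kernels inline identical logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from . import _kernels as K
from .detectors import (
    CartesianAccumulator,
    CartesianXDetector,
    FiberArrayAccumulator,
    FiberArrayDetectorSpec,
    FluenceGrid,
    FluenceGridSpec,
    RadialAccumulator,
    RadialDetector,
    SimResult,
)
from .geometry import (
    FiberProbeLayout,
    FiberSource,
    GaussianBeam,
    IsotropicPoint,
    LayerStack,
    Pencil,
    PhotonPacket,
    RectangularSource,
    UniformBeam,
    VoxelVolume,
)
from .phase import DEFAULT_LUT_SIZE, build_lut
from .rng import make_state
from .trace import TraceBuffer, TraceSpec

__all__ = [
    "Roulette",
    "DetectorSet",
    "EngineConfig",
    "run",
    "run_layered",
    "run_voxel",
    "sample_step",
    "deposit_aw",
    "deposit_mbl",
    "ar_decide",
    "scatter_direction",
    "roulette",
]

STEPPING = {"aw": K.STEP_AW, "ar": K.STEP_AR, "mbl": K.STEP_MBL}


@dataclass
class Roulette:
    """Russian-roulette policy for low-weight packets.

    When disabled, a packet below the threshold deposits its residual
    weight and terminates, which keeps the energy balance exact.
    """

    threshold: float = 1e-4
    m: float = 10.0
    enabled: bool = True

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("roulette threshold must lie in (0, 1)")
        if self.m < 1.0:
            raise ValueError("roulette multiplier must be >= 1")


@dataclass
class DetectorSet:
    top: Optional[RadialDetector] = None
    bottom: Optional[RadialDetector] = None
    cartesian: Optional[CartesianXDetector] = None
    fibers: Optional[FiberArrayDetectorSpec] = None


@dataclass
class EngineConfig:
    """One complete simulation: geometry, source, optional surface layout,
    detectors, fluence grid, trace request and run control."""

    geometry: Union[LayerStack, VoxelVolume]
    source: object
    n_packets: int
    seed: int = 0
    surface: Optional[FiberProbeLayout] = None
    detectors: DetectorSet = field(default_factory=DetectorSet)
    fluence: Optional[FluenceGridSpec] = None
    trace: Optional[TraceSpec] = None
    stepping: str = "aw"
    boundary_mode: str = "sample"  # or "split" (unbiased partial transmission)
    roulette: Roulette = field(default_factory=Roulette)
    rng: str = "xoshiro"
    lut_size: int = DEFAULT_LUT_SIZE

    def validate(self):
        if self.n_packets < 1:
            raise ValueError("n_packets must be >= 1")
        if self.stepping not in STEPPING:
            raise ValueError(f"stepping must be one of {sorted(STEPPING)}")
        if self.boundary_mode not in ("sample", "split"):
            raise ValueError("boundary_mode must be 'sample' or 'split'")
        if isinstance(self.geometry, LayerStack):
            if self.stepping != "aw":
                raise ValueError("the layered engine supports AW stepping only")
        elif isinstance(self.geometry, VoxelVolume):
            if self.surface is not None:
                raise ValueError("surface layouts apply to the layered engine")
            if self.trace is not None:
                raise ValueError("traces are recorded by the layered engine")
        else:
            raise TypeError("geometry must be a LayerStack or VoxelVolume")
        if self.surface is not None and self.detectors.fibers is not None:
            raise ValueError(
                "use either a probe surface layout or a standalone fiber "
                "detector, not both"
            )


# ---------------------------------------------------------------------------
# elementary operations (reference implementations)
# ---------------------------------------------------------------------------

def _uniform(rng) -> float:
    if hasattr(rng, "random"):
        return float(rng.random())
    raise TypeError("rng must expose .random()")


def sample_step(rng, mu_t: float) -> float:
    """Exponential step s = −ln(ξ)/μt with mean 1/μt; μt = 0 gives an
    infinite (geometric) step rather than an error."""
    if mu_t < 0:
        raise ValueError("mu_t must be nonnegative")
    xi = _uniform(rng)
    if mu_t == 0.0:
        return math.inf
    return -math.log(1.0 - xi) / mu_t


def deposit_aw(weight: float, mua: float, mut: float):
    """Albedo–Weight deposition at an extinction event:
    returns (deposited, surviving) with deposited + surviving == weight."""
    if not 0.0 <= mua <= mut or mut <= 0.0:
        raise ValueError("need 0 <= mua <= mut with mut > 0")
    deposited = weight * (mua / mut)
    return deposited, weight - deposited


def deposit_mbl(weight: float, mua: float, path: float):
    """Microscopic Beer–Lambert deposition along a path segment:
    returns (deposited, surviving) = (W(1−e^(−μa·ℓ)), W·e^(−μa·ℓ))."""
    if mua < 0 or path < 0:
        raise ValueError("mua and path must be nonnegative")
    surviving = weight * math.exp(-mua * path)
    return weight - surviving, surviving


def ar_decide(rng, mua: float, mut: float) -> bool:
    """Albedo–Reject: True (absorb full weight, terminate) with
    probability μa/μt."""
    if not 0.0 <= mua <= mut or mut <= 0.0:
        raise ValueError("need 0 <= mua <= mut with mut > 0")
    return _uniform(rng) < mua / mut


def scatter_direction(direction, cos_theta: float, phi: float) -> np.ndarray:
    """Rotate a unit vector by the deflection angle acos(cosθ) with azimuth
    φ (MCML rotation, with the numerically stable near-vertical branch)."""
    ux, uy, uz = (float(v) for v in direction)
    nx, ny, nz = K._spin(ux, uy, uz, float(cos_theta), float(phi))
    return np.array([nx, ny, nz])


def roulette(packet: PhotonPacket, threshold: float, m: float, rng) -> PhotonPacket:
    """Russian roulette: below the threshold, survive with probability 1/m
    and weight × m; expected weight is conserved."""
    if not 0.0 < threshold < 1.0 or m < 1.0:
        raise ValueError("need threshold in (0,1) and m >= 1")
    if packet.weight >= threshold:
        return packet
    if _uniform(rng) * m < 1.0:
        packet.weight *= m
    else:
        packet.weight = 0.0
        packet.alive = False
    return packet


# ---------------------------------------------------------------------------
# config → kernel-argument packing
# ---------------------------------------------------------------------------

_EMPTY = np.empty(0, dtype=np.float64)
_EMPTY_EDGES = np.array([0.0, 1.0])


def _pack_source(source, for_voxel=False):
    p = np.zeros(6)
    if isinstance(source, Pencil):
        return K.SRC_PENCIL, p
    if isinstance(source, IsotropicPoint):
        p[0:3] = source.position
        return K.SRC_ISOTROPIC, p
    if isinstance(source, GaussianBeam):
        p[0] = source.sigma
        return K.SRC_GAUSSIAN, p
    if isinstance(source, UniformBeam):
        p[0] = 0.5 * source.diameter
        return K.SRC_UNIFORM, p
    if isinstance(source, RectangularSource):
        p[0] = source.width_x
        p[1] = source.width_y
        return K.SRC_RECT, p
    if isinstance(source, FiberSource):
        if for_voxel:
            raise ValueError("the fiber source is a layered-engine source")
        p[0] = 0.5 * source.core_diameter
        p[1] = source.n_core
        p[2] = source.cos_max_core
        p[3:5] = source.position
        return K.SRC_FIBER, p
    raise TypeError(f"unsupported source kind: {type(source).__name__}")


def _lut_rows(phase_functions, lut_size):
    """One LUT row per entry; identical phase-function objects share work."""
    cache: dict[int, np.ndarray] = {}
    rows = np.zeros((len(phase_functions), lut_size))
    for i, pf in enumerate(phase_functions):
        if pf is None:
            continue
        key = id(pf)
        if key not in cache:
            cache[key] = build_lut(pf, lut_size).cos_theta
        rows[i] = cache[key]
    return rows


def _pack_detectors(det: DetectorSet, n_exterior_top: float):
    top = det.top
    bot = det.bottom
    cart = det.cartesian
    fib = det.fibers
    args = {}
    args["top_on"] = 1 if top is not None else 0
    args["redges_top"] = top.r_edges if top is not None else _EMPTY_EDGES
    args["cosmin_top"] = top.cos_min if top is not None else 0.0
    args["bot_on"] = 1 if bot is not None else 0
    args["redges_bot"] = bot.r_edges if bot is not None else _EMPTY_EDGES
    args["cosmin_bot"] = bot.cos_min if bot is not None else 0.0
    args["cart_on"] = 1 if cart is not None else 0
    if cart is not None:
        ax, az = cart.axis
        args["cxedges"] = cart.x_edges
        args["cax_x"] = ax
        args["cax_z"] = az
        args["c_cosmin"] = cart.cos_min
    else:
        args["cxedges"] = _EMPTY_EDGES
        args["cax_x"] = 0.0
        args["cax_z"] = -1.0
        args["c_cosmin"] = -1.0
    if fib is not None:
        args["fd_on"] = 1
        args["fd_x"] = np.ascontiguousarray(fib.centers[:, 0])
        args["fd_y"] = np.ascontiguousarray(fib.centers[:, 1])
        args["fd_r2"] = np.full(len(fib.centers), fib.core_radius**2)
        args["fd_cosmin"] = np.full(len(fib.centers), fib.cos_min)
    else:
        args["fd_on"] = 0
        args["fd_x"] = _EMPTY
        args["fd_y"] = _EMPTY
        args["fd_r2"] = _EMPTY
        args["fd_cosmin"] = _EMPTY
    return args


def _pack_fluence(spec: Optional[FluenceGridSpec]):
    if spec is None:
        return dict(fl_on=0, fx0=0.0, fy0=0.0, fz0=0.0, fdx=1.0, fdy=1.0,
                    fdz=1.0, fnx=0, fny=0, fnz=0,
                    fl_grid=np.zeros(1))
    nx, ny, nz = spec.shape
    return dict(
        fl_on=1,
        fx0=spec.origin[0], fy0=spec.origin[1], fz0=spec.origin[2],
        fdx=spec.voxel_size[0], fdy=spec.voxel_size[1], fdz=spec.voxel_size[2],
        fnx=nx, fny=ny, fnz=nz,
        fl_grid=np.zeros(nx * ny * nz),
    )


def _collect_result(config, out, rad_top, rad_bot, cart, fd_w, fl, trace_buf,
                    fiber_spec) -> SimResult:
    det = config.detectors
    n = config.n_packets
    res = SimResult(
        n_packets=n,
        seed=config.seed,
        specular=out[K.S_SPECULAR],
        reflectance=out[K.S_R_TOTAL],
        transmittance=out[K.S_T_TOTAL],
        absorbed=out[K.S_A_INTERIOR],
        absorbed_surface=out[K.S_A_SURFACE],
        killed=out[K.S_KILLED],
        lateral=out[K.S_LATERAL],
        r_sumsq=out[K.S_R_SUMSQ],
        t_sumsq=out[K.S_T_SUMSQ],
        trace_dropped=int(out[K.S_TRACE_DROPPED]),
        trace=trace_buf,
    )
    if det.top is not None:
        acc = RadialAccumulator(det.top, n)
        acc.raw[:] = rad_top
        acc.discarded = out[K.S_RAD_TOP_DISC]
        acc.overflow = out[K.S_RAD_TOP_OVER]
        res.top = acc
    if det.bottom is not None:
        acc = RadialAccumulator(det.bottom, n)
        acc.raw[:] = rad_bot
        acc.discarded = out[K.S_RAD_BOT_DISC]
        acc.overflow = out[K.S_RAD_BOT_OVER]
        res.bottom = acc
    if det.cartesian is not None:
        acc = CartesianAccumulator(det.cartesian, n)
        acc.raw[:] = cart
        acc.discarded = out[K.S_CART_DISC]
        acc.overflow = out[K.S_CART_OVER]
        res.cartesian = acc
    if fiber_spec is not None:
        acc = FiberArrayAccumulator(fiber_spec, n)
        acc.raw[:] = fd_w
        acc.discarded = out[K.S_FIB_DISC]
        res.fibers = acc
    if config.fluence is not None:
        grid = FluenceGrid(config.fluence, n)
        grid.raw[:] = fl["fl_grid"].reshape(config.fluence.shape)
        res.fluence = grid
    return res


def run_layered(config: EngineConfig) -> SimResult:
    """Propagate ``config.n_packets`` packets through a layer stack."""
    config.validate()
    stack: LayerStack = config.geometry
    n_regions = len(stack.entries)
    mua = np.zeros(n_regions)
    mus = np.zeros(n_regions)
    nn = np.zeros(n_regions)
    ztop = np.zeros(n_regions)
    zbot = np.zeros(n_regions)
    phase_list = [None] * n_regions
    nn[0] = stack.n_above
    nn[-1] = stack.n_below
    ztop[0], zbot[0] = -np.inf, 0.0
    edges = stack.interfaces()
    for i, layer in enumerate(stack.layers, start=1):
        mua[i] = layer.mua
        mus[i] = layer.mus
        nn[i] = layer.n
        ztop[i] = edges[i - 1]
        zbot[i] = edges[i - 1] + layer.thickness
        phase_list[i] = layer.phase_function
    ztop[-1], zbot[-1] = zbot[-2], np.inf
    luts = _lut_rows(phase_list, config.lut_size)

    src_kind, src_p = _pack_source(config.source)
    if src_kind == K.SRC_ISOTROPIC:
        z = src_p[2]
        if not 0.0 <= z < zbot[-2]:
            raise ValueError("isotropic source must sit inside the sample")

    lay = config.surface
    if lay is not None:
        lay_args = dict(
            lay_on=1,
            lay_tip_r2=lay.tip_radius**2,
            lay_refl=lay.reflectivity,
            lay_n_out=lay.n_outside,
            lay_lambert=1 if lay.reflection == "lambertian" else 0,
            lay_fx=np.ascontiguousarray(lay.fiber_positions[:, 0]),
            lay_fy=np.ascontiguousarray(lay.fiber_positions[:, 1]),
            lay_rcore2=np.full(len(lay.fiber_positions), lay.core_radius**2),
            lay_ncore=np.full(len(lay.fiber_positions), lay.n_core),
            lay_cosmin=np.full(len(lay.fiber_positions), lay.cos_min_core),
        )
        fiber_spec = FiberArrayDetectorSpec(
            lay.fiber_positions, lay.core_radius, lay.na, n_medium=lay.n_core
        )
    else:
        lay_args = dict(
            lay_on=0, lay_tip_r2=0.0, lay_refl=0.0, lay_n_out=1.0,
            lay_lambert=0, lay_fx=_EMPTY, lay_fy=_EMPTY, lay_rcore2=_EMPTY,
            lay_ncore=_EMPTY, lay_cosmin=_EMPTY,
        )
        fiber_spec = config.detectors.fibers

    det_args = _pack_detectors(config.detectors, nn[0])
    fl = _pack_fluence(config.fluence)

    # trace runs use sampled boundaries and residual-deposit termination so
    # that per-packet weights are non-increasing along the trace
    tr = config.trace
    if tr is not None:
        split_bnd = 0
        roul_on = 0
        tr_on = 1
        tr_cap = tr.capacity
        # np.empty: the kernel writes every event it reports via tr_nev
        tr_ev = np.empty((config.n_packets, tr_cap, 7), dtype=np.float32)
        tr_nev = np.zeros(config.n_packets, dtype=np.int64)
        tr_term = np.zeros((config.n_packets, 8))
    else:
        split_bnd = 1 if config.boundary_mode == "split" else 0
        roul_on = 1 if config.roulette.enabled else 0
        tr_on = 0
        tr_cap = 0
        tr_ev = np.zeros((1, 1, 7), dtype=np.float32)
        tr_nev = np.zeros(1, dtype=np.int64)
        tr_term = np.zeros((1, 8))

    rng_kind, su, ma3, st3 = make_state(config.rng, config.seed)
    out = np.zeros(K.N_SCALARS)
    rad_top = np.zeros(det_args["redges_top"].size - 1)
    rad_bot = np.zeros(det_args["redges_bot"].size - 1)
    cart = np.zeros(det_args["cxedges"].size - 1)
    n_fd = len(fiber_spec.centers) if fiber_spec is not None else (
        len(lay.fiber_positions) if lay is not None else 0)
    fd_w = np.zeros(max(n_fd, 1))

    K.run_layered_kernel(
        config.n_packets,
        mua, mus, nn, ztop, zbot, luts,
        src_kind, src_p,
        lay_args["lay_on"], lay_args["lay_tip_r2"], lay_args["lay_refl"],
        lay_args["lay_n_out"], lay_args["lay_lambert"],
        lay_args["lay_fx"], lay_args["lay_fy"], lay_args["lay_rcore2"],
        lay_args["lay_ncore"], lay_args["lay_cosmin"],
        det_args["top_on"], det_args["redges_top"], det_args["cosmin_top"],
        det_args["bot_on"], det_args["redges_bot"], det_args["cosmin_bot"],
        det_args["cart_on"], det_args["cxedges"], det_args["cax_x"],
        det_args["cax_z"], det_args["c_cosmin"],
        det_args["fd_on"] if lay is None else 0,
        det_args["fd_x"], det_args["fd_y"], det_args["fd_r2"],
        det_args["fd_cosmin"],
        fl["fl_on"], fl["fx0"], fl["fy0"], fl["fz0"], fl["fdx"], fl["fdy"],
        fl["fdz"], fl["fnx"], fl["fny"], fl["fnz"], fl["fl_grid"],
        tr_on, tr_cap, tr_ev, tr_nev, tr_term,
        split_bnd, roul_on, config.roulette.threshold, config.roulette.m,
        rng_kind, su, ma3, st3,
        out, rad_top, rad_bot, cart, fd_w,
    )

    trace_buf = None
    if tr is not None:
        trace_buf = TraceBuffer(tr_ev, tr_nev, tr_term, tr_cap)
    result = _collect_result(config, out, rad_top, rad_bot, cart, fd_w, fl,
                             trace_buf, fiber_spec)
    result.config_echo = _config_echo(config)
    return result


def run_voxel(config: EngineConfig) -> SimResult:
    """Propagate packets through a labeled voxel volume."""
    config.validate()
    vol: VoxelVolume = config.geometry
    labels_present = sorted(int(k) for k in vol.materials)
    remap = {lab: i for i, lab in enumerate(labels_present)}
    m_mua = np.array([vol.materials[lab].mua for lab in labels_present])
    m_mus = np.array([vol.materials[lab].mus for lab in labels_present])
    m_nn = np.array([vol.materials[lab].n for lab in labels_present])
    m_luts = _lut_rows(
        [vol.materials[lab].phase_function for lab in labels_present],
        config.lut_size,
    )
    lut_idx = np.vectorize(remap.get, otypes=[np.int32])(vol.labels)
    labels_flat = np.ascontiguousarray(lut_idx).ravel()

    src_kind, src_p = _pack_source(config.source, for_voxel=True)
    det_args = _pack_detectors(config.detectors, vol.n_above)
    fl = _pack_fluence(config.fluence)
    rng_kind, su, ma3, st3 = make_state(config.rng, config.seed)
    out = np.zeros(K.N_SCALARS)
    rad_top = np.zeros(det_args["redges_top"].size - 1)
    rad_bot = np.zeros(det_args["redges_bot"].size - 1)
    cart = np.zeros(det_args["cxedges"].size - 1)

    nx, ny, nz = vol.shape
    K.run_voxel_kernel(
        config.n_packets,
        labels_flat, nx, ny, nz,
        vol.origin[0], vol.origin[1], vol.origin[2],
        vol.voxel_size[0], vol.voxel_size[1], vol.voxel_size[2],
        m_mua, m_mus, m_nn, m_luts,
        vol.n_above, vol.n_below,
        src_kind, src_p,
        det_args["top_on"], det_args["redges_top"], det_args["cosmin_top"],
        det_args["bot_on"], det_args["redges_bot"], det_args["cosmin_bot"],
        det_args["cart_on"], det_args["cxedges"], det_args["cax_x"],
        det_args["cax_z"], det_args["c_cosmin"],
        fl["fl_on"], fl["fx0"], fl["fy0"], fl["fz0"], fl["fdx"], fl["fdy"],
        fl["fdz"], fl["fnx"], fl["fny"], fl["fnz"], fl["fl_grid"],
        STEPPING[config.stepping],
        1 if config.boundary_mode == "split" else 0,
        1 if config.roulette.enabled else 0,
        config.roulette.threshold, config.roulette.m,
        rng_kind, su, ma3, st3,
        out, rad_top, rad_bot, cart,
    )
    result = _collect_result(config, out, rad_top, rad_bot, cart,
                             np.zeros(1), fl, None, None)
    result.config_echo = _config_echo(config)
    return result


def run(config: EngineConfig) -> SimResult:
    """Run the engine matching the configured geometry."""
    if isinstance(config.geometry, LayerStack):
        return run_layered(config)
    if isinstance(config.geometry, VoxelVolume):
        return run_voxel(config)
    raise TypeError("geometry must be a LayerStack or VoxelVolume")


def _config_echo(config: EngineConfig) -> dict:
    try:
        from .config import dump_config

        return dump_config(config)
    except Exception:
        return {
            "n_packets": config.n_packets,
            "seed": config.seed,
            "stepping": config.stepping,
            "rng": config.rng,
        }
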