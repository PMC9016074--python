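"""Benchmark fixtures, reduced dataset enumeration and the validation
harness (cross-engine comparison, energy balance, RNG bias).

The shipped dataset analogs mirror the published reference-dataset
structure — five families (``mcml_comparison``, ``mcml``, ``mcvox``,
``sv``, ``sfdi``) enumerated as outer products of parameter grids — but
with reduced grids and packet counts sized for a desk CPU.  The grids are
plain data (module constants) so users can substitute full-size ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .detectors import (
    CartesianXDetector,
    FluenceGridSpec,
    RadialDetector,
    linear_edges,
    log_edges,
    symmetric_log_edges,
)
from .engine import DetectorSet, EngineConfig, Roulette, run, run_layered, run_voxel
from .geometry import (
    FiberSource,
    GaussianBeam,
    Layer,
    LayerStack,
    Pencil,
    VoxelMaterial,
    VoxelVolume,
    linear_array_layout,
    six_around_one_layout,
)
from .phase import (
    GegenbauerKernel,
    HenyeyGreenstein,
    MiePhaseFunction,
    ModifiedHenyeyGreenstein,
)
from .trace import TraceSpec

logger = logging.getLogger("tissuemc")

__all__ = [
    "DatasetSpec",
    "ValidationReport",
    "two_layer_benchmark",
    "layered_to_voxel",
    "build_skin_vessel_volume",
    "builtin_dataset",
    "enumerate_dataset",
    "run_dataset",
    "compare_engines",
    "rng_bias_experiment",
    "fixture_configs",
    "BENCHMARK_COMBOS_CM",
]

CM = 1e2  # 1/cm → 1/m

#: (μa [1/cm], μs' [1/cm], g) combinations of the two-layer cross-engine
#: benchmark; the first is the energy-deposition reference combination.
BENCHMARK_COMBOS_CM: tuple = ((2.5, 30.0, 0.9), (5.0, 20.0, 0.8), (1.0, 10.0, 0.9))

#: Fixed bottom layer of the two-layer benchmark (μa, μs' in 1/cm, g, n).
BENCHMARK_BOTTOM_CM = (0.5, 20.0, 0.9, 1.337)


def two_layer_benchmark(mua_cm: float, musp_cm: float, g: float,
                        n_tissue: float = 1.337) -> LayerStack:
    """Two-layer benchmark geometry: a 100 μm top layer with the given
    optical properties over a 1 mm bottom layer with fixed properties;
    air above, index-matched medium below."""
    mus_top = musp_cm * CM / (1.0 - g)
    b_mua, b_musp, b_g, b_n = BENCHMARK_BOTTOM_CM
    mus_bot = b_musp * CM / (1.0 - b_g)
    layers = [
        Layer(mua_cm * CM, mus_top, n_tissue, 100e-6, HenyeyGreenstein(g)),
        Layer(b_mua * CM, mus_bot, b_n, 1e-3, HenyeyGreenstein(b_g)),
    ]
    return LayerStack.from_layers(layers, n_above=1.0, n_below=b_n)


def one_layer_stack(mua_cm: float, musp_cm: float, g: float,
                    thickness: float, n_tissue: float = 1.337,
                    n_above: float = 1.0, n_below: float = 1.337) -> LayerStack:
    mus = musp_cm * CM / (1.0 - g)
    return LayerStack.from_layers(
        [Layer(mua_cm * CM, mus, n_tissue, thickness, HenyeyGreenstein(g))],
        n_above=n_above, n_below=n_below,
    )


def layered_to_voxel(stack: LayerStack, dz: float,
                     lateral_halfwidth: float = 1.0) -> VoxelVolume:
    """Express a finite layer stack as a laterally homogeneous voxel volume.

    Every layer thickness must be an integer multiple of ``dz``; the single
    lateral voxel is made huge so packets never reach the lateral faces.
    """
    boundaries = []
    nz = 0
    for layer in stack.layers:
        if math.isinf(layer.thickness):
            raise ValueError("cannot voxelize an infinite layer")
        k = layer.thickness / dz
        ki = round(k)
        if abs(k - ki) > 1e-9 or ki < 1:
            raise ValueError(
                f"layer thickness {layer.thickness} is not a multiple of dz={dz}"
            )
        nz += ki
        boundaries.append(nz)
    labels = np.zeros((1, 1, nz), dtype=np.int32)
    prev = 0
    materials = {}
    for i, (layer, b) in enumerate(zip(stack.layers, boundaries)):
        labels[0, 0, prev:b] = i
        materials[i] = VoxelMaterial(layer.mua, layer.mus, layer.n,
                                     layer.phase_function)
        prev = b
    return VoxelVolume(
        labels, (2 * lateral_halfwidth, 2 * lateral_halfwidth, dz), materials,
        origin=(None, None, 0.0), n_above=stack.n_above, n_below=stack.n_below,
    )


# ---------------------------------------------------------------------------
# skin model with an embedded vessel (voxel engine showcase)
# ---------------------------------------------------------------------------

#: Reduced-analog skin optical properties at 500 nm (μa, μs in 1/cm, g, n).
#: The dermis values are the printed reference pair; epidermis and whole
#: blood are representative literature values for this wavelength.
SKIN_MATERIALS_CM = {
    "epidermis": (16.6, 450.0, 0.9, 1.4),
    "dermis": (45.9, 356.5, 0.9, 1.4),
    "blood": (112.0, 565.0, 0.98, 1.37),
}


def build_skin_vessel_volume(z_vessel: float, voxel_size: float = 50e-6,
                             shape=(21, 21, 20),
                             epidermis_thickness: float = 100e-6,
                             vessel_radius: float = 100e-6) -> VoxelVolume:
    """Two-layer skin with a cylindrical blood vessel along y.

    The vessel axis sits at x = 0, depth ``z_vessel``; a voxel is labeled
    blood when its centre lies inside the cylinder.
    """
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int32)
    x0 = -0.5 * nx * voxel_size
    zc = (np.arange(nz) + 0.5) * voxel_size
    xc = x0 + (np.arange(nx) + 0.5) * voxel_size
    labels[:, :, zc < epidermis_thickness] = 0
    labels[:, :, zc >= epidermis_thickness] = 1
    xx, zz = np.meshgrid(xc, zc, indexing="ij")
    inside = (xx**2 + (zz - z_vessel) ** 2) <= vessel_radius**2
    for iy in range(ny):
        labels[:, iy, :][inside] = 2
    materials = {}
    for i, name in enumerate(("epidermis", "dermis", "blood")):
        mua, mus, g, n = SKIN_MATERIALS_CM[name]
        materials[i] = VoxelMaterial(mua * CM, mus * CM, n, HenyeyGreenstein(g))
    return VoxelVolume(labels, voxel_size, materials,
                       origin=(None, None, 0.0), n_above=1.0, n_below=1.4)


# ---------------------------------------------------------------------------
# dataset enumeration
# ---------------------------------------------------------------------------

@dataclass
class DatasetSpec:
    """A dataset family with its parameter grids.

    Enumeration is the deterministic outer product of the grids; the
    config count is a pure function of the spec.
    """

    name: str
    grids: dict = field(default_factory=dict)
    n_packets: int = 100_000

    def __post_init__(self):
        for key, grid in self.grids.items():
            if len(grid) == 0:
                raise ValueError(f"dataset grid '{key}' is empty")


_MCML_COMPARISON_GRID = {
    "geometry": ("one-layer-1-mm", "one-layer-100-mm", "two-layer-100-um-1-mm"),
    "mua_cm": (1.0, 2.5),
    "musp_cm": (10.0, 30.0),
    "g": (0.8, 0.9),
}

_MCML_GRID = {
    "subset": ("pencil", "gaussian-100-um", "fiber-200-um",
               "six-around-one", "linear-array-6", "single-fiber"),
    "phase_function": ("hg-0.8", "gk-0.9-1.5", "mhg-0.9-0.9", "mie-ps-1um"),
}

_MCVOX_GRID = {
    # 26 uniformly spaced vessel depths, 0.2 to 0.8 mm inclusive
    "z_vessel": tuple(np.round(np.linspace(0.2e-3, 0.8e-3, 26), 9).tolist()),
}

_SFDI_GRID = {
    "subset": ("perpendicular", "tilted"),
    "mua_cm": (0.1, 2.5),
    "musp_cm": (10.0, 30.0),
}

_SV_GRID = {"configuration": ("probe-500-um",)}


def builtin_dataset(name: str, n_packets: Optional[int] = None) -> DatasetSpec:
    grids = {
        "mcml_comparison": _MCML_COMPARISON_GRID,
        "mcml": _MCML_GRID,
        "mcvox": _MCVOX_GRID,
        "sv": _SV_GRID,
        "sfdi": _SFDI_GRID,
    }
    defaults = {"mcml_comparison": 100_000, "mcml": 50_000, "mcvox": 50_000,
                "sv": 100_000, "sfdi": 100_000}
    if name not in grids:
        raise ValueError(f"unknown dataset '{name}'; choose from {sorted(grids)}")
    return DatasetSpec(name, dict(grids[name]),
                       n_packets or defaults[name])


def _phase_by_name(name: str):
    if name.startswith("hg-"):
        return HenyeyGreenstein(float(name.split("-")[1]))
    if name.startswith("gk-"):
        _, g, a = name.split("-")
        return GegenbauerKernel(float(g), float(a))
    if name.startswith("mhg-"):
        _, g, b = name.split("-")
        return ModifiedHenyeyGreenstein(float(g), float(b))
    if name == "mie-ps-1um":
        from .materials import polystyrene, water

        wl = 500e-9
        return MiePhaseFunction(1e-6, polystyrene.refractive_index(wl),
                                water.refractive_index(wl), wl)
    raise ValueError(f"unknown phase-function tag '{name}'")


def _radial_5mm(na: float, n_exterior: float = 1.0) -> RadialDetector:
    return RadialDetector.from_na(linear_edges(5e-3, 500), na, n_exterior)


def _grid_items(grids: dict):
    keys = list(grids)
    idx = [0] * len(keys)
    sizes = [len(grids[k]) for k in keys]
    while True:
        yield {k: grids[k][i] for k, i in zip(keys, idx)}
        j = len(keys) - 1
        while j >= 0:
            idx[j] += 1
            if idx[j] < sizes[j]:
                break
            idx[j] = 0
            j -= 1
        if j < 0:
            return


def enumerate_dataset(spec: DatasetSpec) -> list[EngineConfig]:
    """Deterministically ordered configs, one per grid-point combination."""
    configs = []
    for i, point in enumerate(_grid_items(spec.grids)):
        configs.append(_config_for(spec, point, i))
    return configs


def _config_for(spec: DatasetSpec, point: dict, index: int) -> EngineConfig:
    n = spec.n_packets
    if spec.name == "mcml_comparison":
        mua, musp, g = point["mua_cm"], point["musp_cm"], point["g"]
        geom = point["geometry"]
        if geom == "one-layer-1-mm":
            stack = one_layer_stack(mua, musp, g, 1e-3)
        elif geom == "one-layer-100-mm":
            stack = one_layer_stack(mua, musp, g, 100e-3)
        else:
            stack = two_layer_benchmark(mua, musp, g)
        det = DetectorSet(top=_radial_5mm(1.0), bottom=_radial_5mm(1.0))
        fluence = FluenceGridSpec(
            origin=(-0.5e-3, -0.5e-3, 0.0), voxel_size=(25e-6,) * 3,
            shape=(40, 40, 40),
        )
        return EngineConfig(stack, Pencil(), n, seed=index,
                            detectors=det, fluence=fluence)
    if spec.name == "mcml":
        pf = _phase_by_name(point["phase_function"])
        mus = 30.0 * CM / (1.0 - 0.9)  # μs' = 30/cm at g-equivalent 0.9
        stack = LayerStack.from_layers(
            [Layer(2.5 * CM, mus, 1.337, math.inf, pf)],
            n_above=1.0, n_below=1.337,
        )
        subset = point["subset"]
        surface = None
        source = Pencil()
        det = DetectorSet(top=_radial_5mm(1.0))
        if subset == "gaussian-100-um":
            source = GaussianBeam(100e-6)
        elif subset == "fiber-200-um":
            # laterally uniform fused-silica boundary; radial detector with
            # the fiber NA so SRR can be integrated into fiber reflectance
            stack = LayerStack.from_layers(
                [Layer(2.5 * CM, mus, 1.337, math.inf, pf)],
                n_above=1.462, n_below=1.337,
            )
            source = FiberSource(200e-6, 220e-6, 0.22, 1.462)
            det = DetectorSet(top=RadialDetector.from_na(
                linear_edges(5e-3, 500), 0.22, 1.462))
        elif subset == "six-around-one":
            surface = six_around_one_layout()
            source = FiberSource(200e-6, 220e-6, 0.22, 1.462)
        elif subset == "linear-array-6":
            surface = linear_array_layout(6)
            source = FiberSource(200e-6, 220e-6, 0.22, 1.462)
        elif subset == "single-fiber":
            surface = linear_array_layout(1)
            source = FiberSource(200e-6, 220e-6, 0.22, 1.462)
        return EngineConfig(stack, source, n, seed=index, surface=surface,
                            detectors=det)
    if spec.name == "mcvox":
        volume = build_skin_vessel_volume(point["z_vessel"])
        det = DetectorSet(cartesian=CartesianXDetector(
            np.linspace(-0.525e-3, 0.525e-3, 22)))
        fluence = FluenceGridSpec(
            origin=(-0.525e-3, -0.525e-3, 0.0), voxel_size=(50e-6,) * 3,
            shape=(21, 21, 20),
        )
        return EngineConfig(volume, Pencil(), n, seed=index, detectors=det,
                            fluence=fluence, stepping="mbl")
    if spec.name == "sv":
        stack = one_layer_stack(2.5, 30.0, 0.9, math.inf, n_above=1.0)
        surface = linear_array_layout(
            2, tip_radius=2e-3)  # source + detector fiber, 500 μm apart
        surface.fiber_positions[1] = (500e-6, 0.0)
        source = FiberSource(200e-6, 220e-6, 0.22, 1.462)
        return EngineConfig(stack, source, n, seed=index, surface=surface,
                            trace=TraceSpec(1000))
    if spec.name == "sfdi":
        mua, musp = point["mua_cm"], point["musp_cm"]
        stack = one_layer_stack(mua, musp, 0.9, math.inf)
        if point["subset"] == "perpendicular":
            det = DetectorSet(top=RadialDetector(
                log_edges(150e-3, 4000), cos_min=math.cos(math.radians(10))))
        else:
            det = DetectorSet(cartesian=CartesianXDetector(
                symmetric_log_edges(150e-3, 8000),
                tilt_deg=20.0, acceptance_deg=10.0))
        return EngineConfig(stack, Pencil(), n, seed=index, detectors=det)
    raise ValueError(f"unknown dataset '{spec.name}'")


def _config_hash(config: EngineConfig) -> str:
    from .config import dump_config

    payload = json.dumps(dump_config(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_dataset(spec: DatasetSpec, out_dir, n_packets: Optional[int] = None,
                seed: int = 0, fmt: str = "npz") -> list[Path]:
    """Enumerate and run a dataset; one result container per configuration.

    Completed configurations (matched by content hash in the filename) are
    skipped, so an interrupted run can resume.  Partial/foreign files never
    shadow a result: the hash covers the full config including N and seed.
    """
    if fmt not in ("npz", "h5"):
        raise ValueError("fmt must be 'npz' or 'h5'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, config in enumerate(enumerate_dataset(spec)):
        if n_packets is not None:
            config.n_packets = int(n_packets)
        config.seed = (seed + i) % (2**31 - 1)
        name = f"{spec.name}-{i:04d}-{_config_hash(config)}.{fmt}"
        path = out_dir / name
        if path.exists():
            logger.info("skipping completed %s", name)
            paths.append(path)
            continue
        t0 = time.perf_counter()
        result = run(config)
        # write-then-rename: an interrupted run never leaves a partial file
        # under the final name for the resume logic to pick up
        tmp = path.with_name(".partial-" + path.name)
        if fmt == "npz":
            result.save_npz(tmp)
        else:
            result.save_hdf5(tmp)
        tmp.replace(path)
        logger.info(
            "%s: N=%d R=%.5f T=%.5f A=%.5f Rsp=%.5f (%.2fs)",
            name, config.n_packets, result.total_reflectance,
            result.total_transmittance, result.absorbed_fraction,
            result.specular_reflectance, time.perf_counter() - t0,
        )
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# validation harness
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Cross-engine relative errors, (engineA − engineB)/engineA."""

    combos: list
    rel_err_r: np.ndarray
    rel_err_t: np.ndarray
    energy_residual_a: np.ndarray
    energy_residual_b: np.ndarray
    seeds: list
    n_packets: int

    @property
    def max_abs_rel_error(self) -> float:
        return float(np.max(np.abs(np.concatenate(
            [self.rel_err_r, self.rel_err_t]))))


def compare_engines(combos_cm: Sequence = BENCHMARK_COMBOS_CM,
                    n_packets: int = 10**6, seed: int = 0,
                    dz: float = 25e-6,
                    boundary_mode: str = "split") -> ValidationReport:
    """Layered vs. voxel engine on the two-layer benchmark geometry.

    Each (μa, μs', g) combination is run through both engines with
    independent seeds; relative differences are (layered − voxel)/layered.
    """
    rel_r, rel_t, res_a, res_b, seeds = [], [], [], [], []
    for i, (mua, musp, g) in enumerate(combos_cm):
        stack = two_layer_benchmark(mua, musp, g)
        seed_a = (seed * 1000 + 2 * i) % (2**31 - 1)
        seed_b = (seed * 1000 + 2 * i + 1) % (2**31 - 1)
        cfg_a = EngineConfig(stack, Pencil(), n_packets, seed=seed_a,
                             boundary_mode=boundary_mode)
        volume = layered_to_voxel(stack, dz)
        cfg_b = EngineConfig(volume, Pencil(), n_packets, seed=seed_b,
                             boundary_mode=boundary_mode)
        a = run_layered(cfg_a)
        b = run_voxel(cfg_b)
        rel_r.append((a.total_reflectance - b.total_reflectance)
                     / a.total_reflectance)
        rel_t.append((a.total_transmittance - b.total_transmittance)
                     / a.total_transmittance)
        res_a.append(a.energy_balance_residual())
        res_b.append(b.energy_balance_residual())
        seeds.append((seed_a, seed_b))
        logger.info(
            "combo (%.2f, %.2f, %.2f): R %.5f vs %.5f, T %.5f vs %.5f",
            mua, musp, g, a.total_reflectance, b.total_reflectance,
            a.total_transmittance, b.total_transmittance,
        )
    return ValidationReport(
        combos=list(combos_cm),
        rel_err_r=np.array(rel_r), rel_err_t=np.array(rel_t),
        energy_residual_a=np.array(res_a), energy_residual_b=np.array(res_b),
        seeds=seeds, n_packets=n_packets,
    )


def rng_bias_experiment(config: EngineConfig, n_packets: int,
                        rng_a: str = "xoshiro", rng_b: str = "ran3",
                        seed: int = 0) -> dict:
    """Signed relative difference of total R and T between two RNGs.

    Runs the same configuration with each generator and reports
    (R_a − R_b)/R_a together with the Monte Carlo standard errors and the
    z score of the absolute difference.
    """
    import copy

    results = {}
    for tag, kind, s in (("a", rng_a, seed), ("b", rng_b, seed + 1)):
        cfg = copy.copy(config)
        cfg.n_packets = int(n_packets)
        cfg.rng = kind
        cfg.seed = s % (2**31 - 1)
        results[tag] = run(cfg)
    a, b = results["a"], results["b"]
    sig_r = math.hypot(a.reflectance_stderr(), b.reflectance_stderr())
    sig_t = math.hypot(a.transmittance_stderr(), b.transmittance_stderr())
    dr = a.total_reflectance - b.total_reflectance
    dt = a.total_transmittance - b.total_transmittance
    return {
        "rng_a": rng_a,
        "rng_b": rng_b,
        "n_packets": int(n_packets),
        "R_a": a.total_reflectance,
        "R_b": b.total_reflectance,
        "T_a": a.total_transmittance,
        "T_b": b.total_transmittance,
        "rel_diff_R": dr / a.total_reflectance,
        "rel_diff_T": dt / a.total_transmittance if a.total_transmittance else np.nan,
        "sigma_R": sig_r,
        "sigma_T": sig_t,
        "z_R": dr / sig_r if sig_r else np.nan,
        "z_T": dt / sig_t if sig_t else np.nan,
    }


def fixture_configs(n_packets: int = 100_000) -> dict[str, EngineConfig]:
    """Small named configurations exercised by the validation suite."""
    stack = two_layer_benchmark(*BENCHMARK_COMBOS_CM[0])
    configs = {
        "two-layer-pencil": EngineConfig(stack, Pencil(), n_packets, seed=11),
        "one-layer-gaussian": EngineConfig(
            one_layer_stack(2.5, 30.0, 0.9, 1e-3), GaussianBeam(100e-6),
            n_packets, seed=12,
            detectors=DetectorSet(top=_radial_5mm(1.0), bottom=_radial_5mm(1.0)),
        ),
        "semi-infinite-fiber": EngineConfig(
            one_layer_stack(2.5, 30.0, 0.9, math.inf, n_above=1.462),
            FiberSource(200e-6, 220e-6, 0.22, 1.462), n_packets, seed=13,
            detectors=DetectorSet(top=RadialDetector.from_na(
                linear_edges(5e-3, 500), 1.0, 1.462)),
        ),
        "six-around-one-probe": EngineConfig(
            one_layer_stack(2.5, 30.0, 0.9, math.inf),
            FiberSource(200e-6, 220e-6, 0.22, 1.462), n_packets, seed=14,
            surface=six_around_one_layout(),
        ),
        "voxel-two-layer-aw": EngineConfig(
            layered_to_voxel(two_layer_benchmark(*BENCHMARK_COMBOS_CM[0]),
                             20e-6),
            Pencil(), n_packets, seed=15, stepping="aw",
        ),
        "voxel-skin-vessel-mbl": EngineConfig(
            build_skin_vessel_volume(0.5e-3), Pencil(), n_packets, seed=16,
            stepping="mbl",
            fluence=FluenceGridSpec(origin=(-0.525e-3, -0.525e-3, 0.0),
                                    voxel_size=(50e-6,) * 3, shape=(21, 21, 20)),
        ),
    }
    return configs
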