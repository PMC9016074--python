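"""Declarative JSON configuration for simulations.

Quantities may be plain numbers (interpreted as SI: metres, 1/m) or tagged
mappings ``{"value": 2.5, "unit": "1/cm"}``; tagged values are converted on
load.  ``dump_config`` always emits plain SI numbers, so a load → dump →
load round trip is the identity.
"""

from __future__ import annotations

import json
import math
from typing import Optional

import numpy as np

from .detectors import (
    CartesianXDetector,
    FiberArrayDetectorSpec,
    FluenceGridSpec,
    RadialDetector,
    linear_edges,
    log_edges,
    symmetric_log_edges,
)
from .engine import DetectorSet, EngineConfig, Roulette
from .geometry import (
    BoundingMedium,
    FiberProbeLayout,
    FiberSource,
    GaussianBeam,
    IsotropicPoint,
    Layer,
    LayerStack,
    Pencil,
    RectangularSource,
    UniformBeam,
    VoxelMaterial,
    VoxelVolume,
    linear_array_layout,
    six_around_one_layout,
)
from .materials import get_material
from .phase import (
    GegenbauerKernel,
    HenyeyGreenstein,
    MiePhaseFunction,
    ModifiedHenyeyGreenstein,
    PowerOfCosines,
    TabulatedPhaseFunction,
)
from .trace import TraceSpec

__all__ = ["as_si", "load_config", "dump_config", "load_config_file",
           "dump_config_file", "ConfigError"]

SCHEMA_VERSION = 1

_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6,
                 "nm": 1e-9}
_INV_LENGTH_UNITS = {"1/m": 1.0, "1/cm": 1e2, "1/mm": 1e3, "1/um": 1e6,
                     "1/µm": 1e6}
_UNITS = {**_LENGTH_UNITS, **_INV_LENGTH_UNITS}


class ConfigError(ValueError):
    """Raised for malformed simulation configurations."""


def as_si(value) -> float:
    """A plain number is already SI; a tagged mapping is converted."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, dict) and "value" in value:
        unit = value.get("unit", None)
        if unit is None:
            return float(value["value"])
        if unit not in _UNITS:
            raise ConfigError(f"unknown unit tag '{unit}'")
        return float(value["value"]) * _UNITS[unit]
    raise ConfigError(f"cannot interpret {value!r} as a quantity")


# ---------------------------------------------------------------------------
# phase functions
# ---------------------------------------------------------------------------

def _load_phase(d):
    if d is None:
        return None
    if not isinstance(d, dict) or "family" not in d:
        raise ConfigError("phase_function must be a mapping with a 'family'")
    fam = d["family"].lower()
    if fam == "hg":
        return HenyeyGreenstein(float(d["g"]))
    if fam == "mhg":
        return ModifiedHenyeyGreenstein(float(d["g"]), float(d["beta"]))
    if fam == "gk":
        return GegenbauerKernel(float(d["g"]), float(d["alpha"]))
    if fam == "pc":
        return PowerOfCosines(float(d["n"]))
    if fam == "mie":
        n_sphere = d["n_sphere"]
        n_medium = d["n_medium"]
        wavelength = as_si(d["wavelength"])
        if isinstance(n_sphere, str):
            n_sphere = get_material(n_sphere).refractive_index(wavelength)
        if isinstance(n_medium, str):
            n_medium = get_material(n_medium).refractive_index(wavelength)
        return MiePhaseFunction(
            as_si(d["diameter"]), float(n_sphere), float(n_medium),
            wavelength, int(d.get("n_angles", 1801)),
        )
    if fam == "tabulated":
        if "file" in d:
            return TabulatedPhaseFunction.from_text(d["file"])
        return TabulatedPhaseFunction(d["cos_theta"], d["p"])
    raise ConfigError(f"unknown phase-function family '{d['family']}'")


def _dump_phase(pf):
    if pf is None:
        return None
    if isinstance(pf, MiePhaseFunction):
        return {"family": "mie", "diameter": pf.diameter,
                "n_sphere": pf.n_sphere, "n_medium": pf.n_medium,
                "wavelength": pf.wavelength,
                "n_angles": int(pf.cos_grid.size)}
    if isinstance(pf, TabulatedPhaseFunction):
        return {"family": "tabulated", "cos_theta": pf.cos_grid.tolist(),
                "p": pf.values.tolist()}
    if isinstance(pf, HenyeyGreenstein):
        return {"family": "hg", "g": pf.g}
    if isinstance(pf, ModifiedHenyeyGreenstein):
        return {"family": "mhg", "g": pf.g, "beta": pf.beta}
    if isinstance(pf, GegenbauerKernel):
        return {"family": "gk", "g": pf.g, "alpha": pf.alpha}
    if isinstance(pf, PowerOfCosines):
        return {"family": "pc", "n": pf.n}
    raise ConfigError(f"cannot serialize phase function {pf!r}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _index_of(d, key, default=None):
    """A refractive index may be a number or a material name + wavelength."""
    v = d.get(key, default)
    if v is None:
        raise ConfigError(f"missing refractive index '{key}'")
    if isinstance(v, str):
        wavelength = as_si(d.get("wavelength", 500e-9))
        return get_material(v).refractive_index(wavelength)
    if isinstance(v, dict) and "n" in v:
        return float(v["n"])
    return float(v)


def _load_geometry(d):
    kind = d.get("type")
    if kind == "layered":
        layers = []
        for ld in d["layers"]:
            layers.append(Layer(
                mua=as_si(ld["mua"]),
                mus=as_si(ld["mus"]),
                n=_index_of(ld, "n"),
                thickness=(math.inf if ld.get("thickness") in ("inf", None)
                           else as_si(ld["thickness"])),
                phase_function=_load_phase(ld.get("phase_function")),
            ))
        return LayerStack.from_layers(
            layers, n_above=_index_of(d, "n_above", 1.0),
            n_below=_index_of(d, "n_below", 1.0),
        )
    if kind == "voxel":
        shape = tuple(int(v) for v in d["shape"])
        voxel_size = tuple(as_si(v) for v in np.broadcast_to(
            np.array(d["voxel_size"], dtype=object), (3,)))
        labels = _build_labels(d["labels"], shape)
        materials = {
            int(k): VoxelMaterial(
                mua=as_si(m["mua"]), mus=as_si(m["mus"]),
                n=_index_of(m, "n"),
                phase_function=_load_phase(m.get("phase_function")),
            )
            for k, m in d["materials"].items()
        }
        origin = d.get("origin", [None, None, 0.0])
        origin = tuple(None if v is None else as_si(v) for v in origin)
        return VoxelVolume(
            labels, voxel_size, materials, origin=origin,
            n_above=_index_of(d, "n_above", 1.0),
            n_below=_index_of(d, "n_below", 1.0),
        )
    raise ConfigError(f"unknown geometry type '{kind}'")


def _build_labels(d, shape):
    nx, ny, nz = shape
    kind = d.get("kind", "array")
    if kind == "array":
        arr = np.asarray(d["data"], dtype=np.int32)
        if arr.shape != shape:
            raise ConfigError("label array shape does not match 'shape'")
        return arr
    if kind == "uniform":
        return np.full(shape, int(d.get("label", 0)), dtype=np.int32)
    if kind == "z_slabs":
        # boundaries_k: first voxel index of each subsequent slab
        labels = np.zeros(shape, dtype=np.int32)
        bounds = [int(b) for b in d["boundaries_k"]]
        vals = [int(v) for v in d["labels"]]
        if len(vals) != len(bounds) + 1:
            raise ConfigError("z_slabs needs len(labels) == len(boundaries_k)+1")
        prev = 0
        for b, v in zip(bounds + [nz], vals):
            labels[:, :, prev:b] = v
            prev = b
        return labels
    raise ConfigError(f"unknown label builder '{kind}'")


def _dump_geometry(g):
    if isinstance(g, LayerStack):
        return {
            "type": "layered",
            "n_above": g.n_above,
            "n_below": g.n_below,
            "layers": [
                {
                    "mua": layer.mua, "mus": layer.mus, "n": layer.n,
                    "thickness": ("inf" if math.isinf(layer.thickness)
                                  else layer.thickness),
                    "phase_function": _dump_phase(layer.phase_function),
                }
                for layer in g.layers
            ],
        }
    if isinstance(g, VoxelVolume):
        return {
            "type": "voxel",
            "shape": list(g.shape),
            "voxel_size": list(g.voxel_size),
            "origin": list(g.origin),
            "n_above": g.n_above,
            "n_below": g.n_below,
            "labels": {"kind": "array", "data": g.labels.tolist()},
            "materials": {
                str(k): {
                    "mua": m.mua, "mus": m.mus, "n": m.n,
                    "phase_function": _dump_phase(m.phase_function),
                }
                for k, m in g.materials.items()
            },
        }
    raise ConfigError(f"cannot serialize geometry {g!r}")


# ---------------------------------------------------------------------------
# sources, layouts, detectors
# ---------------------------------------------------------------------------

def _load_source(d):
    kind = d.get("type")
    if kind in ("pencil", "line"):
        return Pencil()
    if kind == "isotropic":
        return IsotropicPoint(tuple(as_si(v) for v in d["position"]))
    if kind == "gaussian_beam":
        return GaussianBeam(as_si(d["fwhm"]))
    if kind == "uniform_beam":
        return UniformBeam(as_si(d["diameter"]))
    if kind == "rectangular":
        return RectangularSource(as_si(d["width_x"]), as_si(d["width_y"]))
    if kind == "fiber":
        return FiberSource(
            core_diameter=as_si(d["core_diameter"]),
            cladding_diameter=as_si(d["cladding_diameter"]),
            na=float(d["na"]),
            n_core=_index_of(d, "n_core"),
            position=tuple(as_si(v) for v in d.get("position", (0.0, 0.0))),
        )
    raise ConfigError(f"unknown source type '{kind}'")


def _dump_source(s):
    if isinstance(s, Pencil):
        return {"type": "pencil"}
    if isinstance(s, IsotropicPoint):
        return {"type": "isotropic", "position": list(s.position)}
    if isinstance(s, GaussianBeam):
        return {"type": "gaussian_beam", "fwhm": s.fwhm}
    if isinstance(s, UniformBeam):
        return {"type": "uniform_beam", "diameter": s.diameter}
    if isinstance(s, RectangularSource):
        return {"type": "rectangular", "width_x": s.width_x, "width_y": s.width_y}
    if isinstance(s, FiberSource):
        return {"type": "fiber", "core_diameter": s.core_diameter,
                "cladding_diameter": s.cladding_diameter, "na": s.na,
                "n_core": s.n_core, "position": list(s.position)}
    raise ConfigError(f"cannot serialize source {s!r}")


def _load_surface(d):
    if d is None:
        return None
    kind = d.get("type")
    if kind == "six_around_one":
        return six_around_one_layout(
            core_diameter=as_si(d.get("core_diameter", 200e-6)),
            cladding_diameter=as_si(d.get("cladding_diameter", 220e-6)),
            na=float(d.get("na", 0.22)),
            n_core=_index_of(d, "n_core", 1.462),
            tip_radius=(as_si(d["tip_radius"]) if "tip_radius" in d else None),
            reflectivity=float(d.get("reflectivity", 0.6)),
        )
    if kind == "linear_array":
        return linear_array_layout(
            n_fibers=int(d.get("n_fibers", 6)),
            core_diameter=as_si(d.get("core_diameter", 200e-6)),
            cladding_diameter=as_si(d.get("cladding_diameter", 220e-6)),
            na=float(d.get("na", 0.22)),
            n_core=_index_of(d, "n_core", 1.462),
            tip_radius=(as_si(d["tip_radius"]) if "tip_radius" in d else None),
            reflectivity=float(d.get("reflectivity", 0.6)),
        )
    if kind == "fiber_probe":
        return FiberProbeLayout(
            fiber_positions=np.array(
                [[as_si(v) for v in xy] for xy in d["fibers"]]),
            core_radius=as_si(d["core_radius"]),
            cladding_radius=as_si(d["cladding_radius"]),
            na=float(d["na"]),
            n_core=_index_of(d, "n_core"),
            tip_radius=as_si(d["tip_radius"]),
            reflectivity=float(d.get("reflectivity", 0.6)),
            n_outside=float(d.get("n_outside", 1.0)),
            reflection=d.get("reflection", "specular"),
        )
    raise ConfigError(f"unknown surface layout type '{kind}'")


def _dump_surface(s):
    if s is None:
        return None
    return {
        "type": "fiber_probe",
        "fibers": s.fiber_positions.tolist(),
        "core_radius": s.core_radius,
        "cladding_radius": s.cladding_radius,
        "na": s.na,
        "n_core": s.n_core,
        "tip_radius": s.tip_radius,
        "reflectivity": s.reflectivity,
        "n_outside": s.n_outside,
        "reflection": s.reflection,
    }


def _load_edges(d):
    kind = d.get("kind", "linear")
    if kind == "linear":
        return linear_edges(as_si(d["r_max"]), int(d["n_bins"]),
                            as_si(d.get("r_min", 0.0)))
    if kind == "log":
        return log_edges(as_si(d["r_max"]), int(d["n_bins"]),
                         as_si(d.get("r_first", 10e-6)))
    if kind == "explicit":
        return np.array([as_si(v) for v in d["edges"]])
    raise ConfigError(f"unknown edge layout '{kind}'")


def _load_radial(d):
    if d is None:
        return None
    edges = _load_edges(d.get("edges", d))
    if "na" in d:
        return RadialDetector.from_na(edges, float(d["na"]),
                                      float(d.get("n_exterior", 1.0)))
    return RadialDetector(edges, float(d.get("cos_min", 0.0)))


def _load_detectors(d):
    if d is None:
        return DetectorSet()
    det = DetectorSet()
    det.top = _load_radial(d.get("top"))
    det.bottom = _load_radial(d.get("bottom"))
    if "cartesian" in d and d["cartesian"] is not None:
        cd = d["cartesian"]
        if "x_edges" in cd:
            x_edges = np.array([as_si(v) for v in cd["x_edges"]])
        elif cd.get("spacing", "linear") == "log":
            x_edges = symmetric_log_edges(
                as_si(cd["x_max"]), int(cd["n_bins"]),
                as_si(cd.get("x_first", 10e-6)))
        else:
            x_edges = np.linspace(-as_si(cd["x_max"]), as_si(cd["x_max"]),
                                  int(cd["n_bins"]) + 1)
        det.cartesian = CartesianXDetector(
            x_edges, float(cd.get("tilt_deg", 0.0)),
            float(cd.get("acceptance_deg", 90.0)))
    if "fibers" in d and d["fibers"] is not None:
        fd = d["fibers"]
        det.fibers = FiberArrayDetectorSpec(
            centers=np.array([[as_si(v) for v in xy] for xy in fd["centers"]]),
            core_radius=as_si(fd["core_radius"]),
            na=float(fd["na"]),
            n_medium=float(fd.get("n_medium", 1.0)),
        )
    return det


def _dump_detectors(det: DetectorSet):
    out = {}
    for name, acc in (("top", det.top), ("bottom", det.bottom)):
        if acc is not None:
            out[name] = {
                "edges": {"kind": "explicit", "edges": acc.r_edges.tolist()},
                "cos_min": acc.cos_min,
            }
    if det.cartesian is not None:
        out["cartesian"] = {
            "x_edges": det.cartesian.x_edges.tolist(),
            "tilt_deg": det.cartesian.tilt_deg,
            "acceptance_deg": det.cartesian.acceptance_deg,
        }
    if det.fibers is not None:
        out["fibers"] = {
            "centers": det.fibers.centers.tolist(),
            "core_radius": det.fibers.core_radius,
            "na": det.fibers.na,
            "n_medium": det.fibers.n_medium,
        }
    return out or None


def _load_fluence(d):
    if d is None:
        return None
    return FluenceGridSpec(
        origin=tuple(as_si(v) for v in d["origin"]),
        voxel_size=tuple(as_si(v) for v in d["voxel_size"]),
        shape=tuple(int(v) for v in d["shape"]),
        mode=d.get("mode", "energy_deposition"),
    )


def _dump_fluence(f):
    if f is None:
        return None
    return {"origin": list(f.origin), "voxel_size": list(f.voxel_size),
            "shape": list(f.shape), "mode": f.mode}


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def load_config(d: dict) -> EngineConfig:
    """Build an :class:`EngineConfig` from a configuration mapping."""
    if not isinstance(d, dict):
        raise ConfigError("configuration must be a mapping")
    version = int(d.get("version", SCHEMA_VERSION))
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported config version {version}")
    try:
        geometry = _load_geometry(d["geometry"])
        source = _load_source(d["source"])
    except KeyError as e:
        raise ConfigError(f"missing required config section: {e}") from None
    rd = d.get("roulette", {})
    cfg = EngineConfig(
        geometry=geometry,
        source=source,
        n_packets=int(d.get("n_packets", 10000)),
        seed=int(d.get("seed", 0)),
        surface=_load_surface(d.get("surface")),
        detectors=_load_detectors(d.get("detectors")),
        fluence=_load_fluence(d.get("fluence")),
        trace=(TraceSpec(int(d["trace"].get("capacity", 1000)))
               if d.get("trace") else None),
        stepping=d.get("stepping", "aw"),
        boundary_mode=d.get("boundary_mode", "sample"),
        roulette=Roulette(
            threshold=float(rd.get("threshold", 1e-4)),
            m=float(rd.get("m", 10.0)),
            enabled=bool(rd.get("enabled", True)),
        ),
        rng=d.get("rng", "xoshiro"),
        lut_size=int(d.get("lut_size", 4096)),
    )
    cfg.validate()
    return cfg


def dump_config(cfg: EngineConfig) -> dict:
    """Serialize a config to a plain-SI JSON-compatible mapping."""
    return {
        "version": SCHEMA_VERSION,
        "n_packets": cfg.n_packets,
        "seed": cfg.seed,
        "rng": cfg.rng,
        "stepping": cfg.stepping,
        "boundary_mode": cfg.boundary_mode,
        "lut_size": cfg.lut_size,
        "roulette": {"threshold": cfg.roulette.threshold,
                     "m": cfg.roulette.m, "enabled": cfg.roulette.enabled},
        "geometry": _dump_geometry(cfg.geometry),
        "source": _dump_source(cfg.source),
        "surface": _dump_surface(cfg.surface),
        "detectors": _dump_detectors(cfg.detectors),
        "fluence": _dump_fluence(cfg.fluence),
        "trace": ({"capacity": cfg.trace.capacity} if cfg.trace else None),
    }


def load_config_file(path) -> EngineConfig:
    with open(path) as f:
        return load_config(json.load(f))


def dump_config_file(cfg: EngineConfig, path):
    with open(path, "w") as f:
        json.dump(dump_config(cfg), f, indent=1)
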